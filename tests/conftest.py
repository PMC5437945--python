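import numpy as np
import pandas as pd
import pytest

from leafmorph.efd import EllipticalFourierFeaturizer
from leafmorph.procrustes import GeneralizedProcrustesAlignment
from leafmorph.synth import default_species_specs, synth_dataset

DATASET_SEED = 11


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic template: 8 species in 4 classes, 3 vines, 10 nodes."""
    specs = default_species_specs(seed=DATASET_SEED)
    return synth_dataset(specs, vines_per_species=3, nodes_per_vine=10, seed=DATASET_SEED + 1)


@pytest.fixture(scope="session")
def default_traits(default_dataset):
    """Landmark and EFD trait matrices of the default dataset."""
    table, outlines, truth = default_dataset
    meta = table.metadata()
    gpa_est = GeneralizedProcrustesAlignment()
    lm = pd.DataFrame(
        gpa_est.fit_transform(table.configurations),
        index=meta.index,
        columns=gpa_est.get_feature_names_out(),
    )
    feat = EllipticalFourierFeaturizer(n_harmonics=20, n_resample=500)
    efd = pd.DataFrame(
        feat.fit_transform(outlines), index=meta.index, columns=feat.get_feature_names_out()
    )
    return meta, lm, efd


def random_polygon(rng, n_vertices=20, resample=None):
    """Simple star-shaped polygon with random radii (guaranteed non-self-intersecting)."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # enforce distinct angles
    while np.any(np.diff(ang) < 1e-3):
        ang = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    r = rng.uniform(0.5, 1.5, n_vertices)
    pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    if resample:
        from leafmorph.efd import resample_contour

        pts = resample_contour(pts, resample)
    return pts
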