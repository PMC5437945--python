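# leafmorph

Comparative morphometrics of lobed leaves, built around the two standard ways
of quantifying a leaf collected along a vine:

* **vascular landmarks** — 15 homologous points at the petiolar junction, vein
  bases, lobe tips, sinuses, and apex, superimposed by generalized Procrustes
  analysis (GPA, full Procrustes, reflection allowed); and
* **elliptical Fourier descriptors (EFDs)** — the harmonic coefficients
  (A, B, C, D per rank, 20 ranks by default) of the closed blade outline,
  normalized against the first-harmonic ellipse so that A1 = 1, B1 = C1 = 0.

Both trait blocks are projected into covariance-PCA morphospaces (with
"eigenleaf" reconstructions along each component), fed to leave-one-out
linear discriminant analysis to ask how well **species identity** (ignoring
node) and **heteroblastic node position** (ignoring species) can be predicted
from landmarks, EFDs, or both together, and cross-correlated trait-by-trait
with Spearman's rho, whose matrix doubles as a distance matrix (d = 1 − rho)
for hierarchical clustering of traits. After normalization the B and C
harmonic coefficients carry the asymmetric part of shape variance: reflecting
an outline negates them and leaves A and D untouched.

A parametric generator of lobed, *Passiflora*-like leaves supplies fully
labeled datasets — species with distinct mean shapes grouped into classes,
several vines per species, a monotone heteroblastic gradient along the nodes
(later nodes more deeply lobed), and species-independent signed left–right
asymmetry — so every stage of the pipeline is testable without any external
data. Landmarks and outlines of a synthetic leaf are mutually consistent by
construction: the outline is a periodic cubic curve through the blade
landmarks.

## Worked example

```python
import pandas as pd
from leafmorph import (
    default_species_specs, synth_dataset,
    GeneralizedProcrustesAlignment, EllipticalFourierFeaturizer,
    loo_predict, node_rank_rho,
)

specs = default_species_specs(seed=1)            # 8 species in 4 classes
table, outlines, truth = synth_dataset(specs, vines_per_species=3,
                                       nodes_per_vine=10, seed=2)
meta = table.metadata()

gpa = GeneralizedProcrustesAlignment()           # reflect allowed, full Procrustes
lm = pd.DataFrame(gpa.fit_transform(table.configurations),
                  index=meta.index, columns=gpa.get_feature_names_out())

efd = EllipticalFourierFeaturizer(n_harmonics=20)
ef = pd.DataFrame(efd.fit_transform(outlines),
                  index=meta.index, columns=efd.get_feature_names_out())

res = loo_predict(lm, meta["species"])           # leave-one-out LDA
print("species LOO accuracy:", (res.predicted == res.actual).mean())

res_node = loo_predict(lm, meta["node_base1"])
rho, p = node_rank_rho(res_node.actual.astype(float),
                       res_node.predicted.astype(float))
print(f"node rank correlation: rho={rho:.3f}, p={p:.2e}")
```

Output (240 leaves):

```
species LOO accuracy: 0.9291666666666667
node rank correlation: rho=0.971, p=2.33e-150
```

Species are recovered at ~93% despite the node-to-node shape gradient, and
predicted node position tracks true node position strongly — while the raw
per-node accuracy is much lower (~60%), because adjacent nodes are confused
with each other. This is the expected signature of heteroblasty: node effects
are ordered and gradual, species effects are categorical.

The same analysis runs end-to-end from the command line:

```sh
leafmorph run --seed 1 --out my_run       # synthesize + full analysis
leafmorph synth --seed 1 --out data/      # just write a synthetic dataset
leafmorph gpa data/landmarks.csv          # individual stages
leafmorph efd data/outlines/
```

Every run directory contains the Procrustes-adjusted coordinates, a
normalized-EFD `.nef` file, PCA scores/loadings/variance tables, eigenleaf
shapes, confusion matrices for species and node under all three feature sets,
feature-set comparison tables, the trait correlation matrices with their
clustering (Newick + merge table), a replication summary, and a SHA-256
manifest; identical config and seed give identical outputs.

Real data can be ingested instead of synthesized: landmark tables in a wide
CSV (`x1..x15, y1..y15`) or long TSV layout, node numbering converted from
scan order (tip = 1) to heteroblastic order (base = 1) at ingest, binary leaf
masks traced by Moore-neighbor boundary following, and NEF harmonic files
read and written losslessly.

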