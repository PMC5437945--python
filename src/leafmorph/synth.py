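"""Parametric generator of lobed, *Passiflora*-like leaves.

Each synthetic leaf is defined by a small set of interpretable parameters
(midvein length, lobe lengths and angles, sinus depths, vein width,
left-right asymmetry, serration amplitude) from which two mutually consistent
representations are constructed:

* a homologous 15-landmark configuration, with the same anatomical roles as
  the landmarks of the real dataset: paired proximal vein bases at the
  petiolar junction (1-2 right, 5-6 left), distal vein bases (4 right,
  3 left), proximal lobe tips (7 right, 15 left), proximal sinuses (8, 14),
  distal lobe tips (9 right, 13 left), distal sinuses (10, 12), and the leaf
  apex (11);
* a closed blade outline passing exactly through the nine blade landmarks
  (tips, sinuses, apex), built by periodic cubic interpolation, optionally
  decorated with a mirror-symmetric serration ripple.

A dataset generator composes species-level mean parameters, a monotone
heteroblastic gradient along the nodes of each vine (higher nodes more
lobed), per-leaf Gaussian noise, and species-independent asymmetry, mirroring
the replication structure of a multi-species, multi-vine leaf collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import LeafRecord, LandmarkTable

__all__ = [
    "LeafParams",
    "SpeciesSpec",
    "synth_leaf",
    "synth_dataset",
    "default_species_specs",
    "DEFAULT_GRADIENT",
]

_GRADIENT_PARAMS = ("distal_sinus_depth", "proximal_sinus_depth", "distal_lobe_len")

#: Default per-node heteroblastic shift: each successive node (base-1 numbering)
#: deepens the sinuses and lengthens the distal lobes, i.e. later nodes are
#: more pronouncedly lobed.
DEFAULT_GRADIENT: dict[str, float] = {
    "distal_sinus_depth": 0.02,
    "proximal_sinus_depth": 0.015,
    "distal_lobe_len": 0.01,
}


@dataclass
class LeafParams:
    """Generative parameters of a single leaf.

    Lengths are in arbitrary blade-length units; angles are radians measured
    from the midvein; sinus depths are the fraction by which the sinus point
    is drawn in from the line of adjacent lobe tips; ``asymmetry`` scales the
    left-side lobe lengths and angles by ``(1 + asymmetry)`` and the right
    side by ``(1 - asymmetry)``.
    """

    midvein_len: float = 1.0
    distal_lobe_len: float = 0.75
    proximal_lobe_len: float = 0.55
    distal_lobe_angle: float = 0.55
    proximal_lobe_angle: float = 1.05
    distal_sinus_depth: float = 0.35
    proximal_sinus_depth: float = 0.25
    vein_half_width: float = 0.02
    asymmetry: float = 0.0
    serration_amp: float = 0.0
    n_outline_points: int = 500

    def validate(self) -> "LeafParams":
        for name in ("midvein_len", "distal_lobe_len", "proximal_lobe_len", "vein_half_width"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("distal_sinus_depth", "proximal_sinus_depth"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("distal_lobe_angle", "proximal_lobe_angle"):
            v = getattr(self, name)
            if not 0.0 < v < np.pi / 2:
                raise ValueError(f"{name} must be in (0, pi/2) radians")
        if not -1.0 < self.asymmetry < 1.0:
            raise ValueError("asymmetry must be in (-1, 1)")
        if (1.0 + abs(self.asymmetry)) * max(self.distal_lobe_angle, self.proximal_lobe_angle) >= np.pi / 2:
            raise ValueError("asymmetry pushes a lobe angle beyond pi/2")
        if self.serration_amp < 0:
            raise ValueError("serration_amp must be >= 0")
        if self.n_outline_points < 64:
            raise ValueError("n_outline_points must be >= 64")
        return self

    numeric_fields = (
        "midvein_len", "distal_lobe_len", "proximal_lobe_len",
        "distal_lobe_angle", "proximal_lobe_angle",
        "distal_sinus_depth", "proximal_sinus_depth",
        "vein_half_width", "asymmetry", "serration_amp",
    )


def _polar(theta: float, r: float, side: int) -> np.ndarray:
    """Point at angle ``theta`` from the midvein (+y axis), radius r; side=+1 right."""
    return np.array([side * r * np.sin(theta), r * np.cos(theta)])


def _side_landmarks(p: LeafParams, side: int) -> dict[int, np.ndarray]:
    """Blade and vein landmarks for one half of the leaf.

    ``side=+1`` is the right half (landmarks 1, 2, 4, 7, 8, 9, 10); ``side=-1``
    the left half (landmarks 5, 6, 3, 15, 14, 13, 12).  Asymmetry scales the
    left-side lobe lengths and angles by ``(1 + asymmetry)`` and the right side
    by ``(1 - asymmetry)``, so the left-right mean — the symmetric component of
    the shape — is preserved and the perturbation is purely asymmetric to
    first order.
    """
    f = 1.0 - p.asymmetry if side > 0 else 1.0 + p.asymmetry
    th_d = p.distal_lobe_angle * f
    th_p = p.proximal_lobe_angle * f
    l_d = p.distal_lobe_len * f
    l_p = p.proximal_lobe_len * f
    m = p.midvein_len
    w = p.vein_half_width

    tip_d = _polar(th_d, l_d, side)
    tip_p = _polar(th_p, l_p, side)
    sin_d = _polar(th_d / 2.0, (1.0 - p.distal_sinus_depth) * (m + l_d) / 2.0, side)
    sin_p = _polar((th_d + th_p) / 2.0, (1.0 - p.proximal_sinus_depth) * (l_d + l_p) / 2.0, side)

    # proximal vein base pair straddles the vein direction at the petiolar junction
    u_p = np.array([side * np.sin(th_p), np.cos(th_p)])
    n_p = np.array([u_p[1], -u_p[0]]) * side  # outward normal
    base_outer = w * n_p
    base_inner = -w * n_p

    # distal vein base: distal side of the junction of the distal vein with the midvein
    junction = np.array([0.0, 0.35 * m])
    base_d = junction + w * np.array([side * np.cos(th_d), np.sin(th_d)])

    if side > 0:
        return {1: base_outer, 2: base_inner, 4: base_d,
                7: tip_p, 8: sin_p, 9: tip_d, 10: sin_d}
    return {6: base_outer * np.array([1, 1]), 5: base_inner, 3: base_d,
            15: tip_p, 14: sin_p, 13: tip_d, 12: sin_d}


def synth_leaf(params: LeafParams, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Construct one leaf: (15, 2) landmark configuration and closed outline.

    The outline interpolates periodically (cubic, chord-length parameterized)
    through the nine blade landmarks plus a basal anchor point, sampled at
    ``params.n_outline_points`` uniform parameter values starting at the apex.
    With ``asymmetry = 0`` the outline is mirror-symmetric about the midvein
    to interpolation round-off.  The construction is deterministic: the seed
    is accepted for interface symmetry with the dataset generator.
    """
    p = params.validate()
    lm: dict[int, np.ndarray] = {11: np.array([0.0, p.midvein_len])}
    lm.update(_side_landmarks(p, +1))
    lm.update(_side_landmarks(p, -1))
    landmarks = np.stack([lm[i] for i in range(1, 16)])

    base_anchor = np.array([0.0, -0.08 * p.midvein_len])
    # counterclockwise from the apex: left side down, base, right side up
    knots = np.stack([
        lm[11], lm[12], lm[13], lm[14], lm[15], base_anchor,
        lm[7], lm[8], lm[9], lm[10], lm[11],
    ])
    seg = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(t, knots, bc_type="periodic")
    u = np.linspace(0.0, t[-1], p.n_outline_points, endpoint=False)
    outline = spline(u)

    if p.serration_amp > 0:
        # radial ripple about the leaf base; cosine in the (apex-anchored)
        # parameter is even under mirror reversal, preserving symmetry
        phase = np.cos(2.0 * np.pi * 24 * u / t[-1])
        outline = outline * (1.0 + p.serration_amp * phase)[:, None]

    return landmarks, outline


@dataclass
class SpeciesSpec:
    """Species-level generative template.

    ``mean`` holds the species mean parameters; ``sd`` maps parameter names to
    the between-leaf standard deviation; ``gradient`` maps parameter names to
    the additive per-node heteroblastic shift (monotone along the vine by
    construction, since the shift is linear in node index).
    """

    name: str
    class_label: str
    mean: LeafParams
    sd: dict[str, float] = field(default_factory=dict)
    gradient: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GRADIENT))

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("standard deviations must be >= 0")
        unknown = set(self.sd) | set(self.gradient)
        unknown -= set(LeafParams.numeric_fields)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")

    def params_at_node(self, node_base1: int, noise: np.ndarray | None = None,
                       noise_scale: float = 1.0) -> LeafParams:
        vals = {k: getattr(self.mean, k) for k in LeafParams.numeric_fields}
        for k, g in self.gradient.items():
            vals[k] = vals[k] + g * (node_base1 - 1)
        if noise is not None:
            for j, k in enumerate(LeafParams.numeric_fields):
                vals[k] = vals[k] + noise_scale * self.sd.get(k, 0.0) * noise[j]
        return _clip_params(vals, self.mean.n_outline_points)


def _clip_params(vals: dict[str, float], n_outline_points: int) -> LeafParams:
    """Clamp sampled parameters into the generator's validity region."""
    out = dict(vals)
    for k in ("midvein_len", "distal_lobe_len", "proximal_lobe_len"):
        out[k] = max(out[k], 0.05)
    out["vein_half_width"] = max(out["vein_half_width"], 1e-3)
    for k in ("distal_sinus_depth", "proximal_sinus_depth"):
        out[k] = float(np.clip(out[k], 0.0, 0.9))
    for k in ("distal_lobe_angle", "proximal_lobe_angle"):
        out[k] = float(np.clip(out[k], 0.08, 1.40))
    out["asymmetry"] = float(np.clip(out["asymmetry"], -0.5, 0.5))
    out["serration_amp"] = max(out["serration_amp"], 0.0)
    # keep the asymmetry-perturbed angles inside (0, pi/2)
    max_angle = max(out["distal_lobe_angle"], out["proximal_lobe_angle"])
    if (1.0 + abs(out["asymmetry"])) * max_angle >= np.pi / 2:
        cap = np.pi / 2 / max_angle - 1.0 - 1e-6
        out["asymmetry"] = float(np.sign(out["asymmetry"]) * cap)
    return LeafParams(n_outline_points=n_outline_points, **out).validate()


def default_sd(mean: LeafParams, scale: float = 0.03) -> dict[str, float]:
    """Between-leaf SDs proportional to each parameter's magnitude (floor 0.005)."""
    return {
        k: max(scale * abs(getattr(mean, k)), 0.005)
        for k in LeafParams.numeric_fields
        if k not in ("asymmetry", "serration_amp")
    }


def default_species_specs(
    n_species: int = 8,
    n_classes: int = 4,
    separation: float = 3.0,
    seed: int = 0,
    noise_scale: float = 0.03,
) -> list[SpeciesSpec]:
    """Build the default species template: ``n_species`` species in ``n_classes``
    shape classes, with species means separated by ``separation`` between-leaf
    SDs along random directions in parameter space (class archetypes are
    separated twice as far), and a shared heteroblastic gradient.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    base = LeafParams()
    sd = default_sd(base, noise_scale)
    varying = list(sd.keys())

    def shifted(mult: float, origin: dict[str, float]) -> dict[str, float]:
        direction = rng.normal(size=len(varying))
        direction /= np.linalg.norm(direction)
        return {
            k: origin[k] + mult * separation * sd[k] * direction[j]
            for j, k in enumerate(varying)
        }

    base_vals = {k: getattr(base, k) for k in varying}
    class_labels = [chr(ord("A") + i) for i in range(n_classes)]
    archetypes = {lbl: shifted(2.0, base_vals) for lbl in class_labels}

    specs = []
    for s in range(n_species):
        lbl = class_labels[s % n_classes]
        vals = shifted(1.0, archetypes[lbl])
        mean = _clip_params(
            {**{k: getattr(base, k) for k in LeafParams.numeric_fields}, **vals},
            base.n_outline_points,
        )
        specs.append(
            SpeciesSpec(name=f"species_{s + 1:02d}", class_label=lbl, mean=mean, sd=dict(sd))
        )
    return specs


def synth_dataset(
    specs: list[SpeciesSpec],
    vines_per_species: int = 3,
    nodes_per_vine: int | tuple[int, int] = 10,
    noise: float = 1.0,
    seed: int = 0,
    asymmetry_sd: float = 0.05,
) -> tuple[LandmarkTable, list[np.ndarray], pd.DataFrame]:
    """Generate a full multi-species, multi-vine leaf dataset.

    One leaf per node per vine.  Per-leaf parameters are the species mean plus
    the node gradient plus ``noise``-scaled Gaussian deviates; asymmetry is
    drawn signed-normal with SD ``asymmetry_sd`` independently of species
    (set 0 for perfectly symmetric leaves).  ``nodes_per_vine`` may be a fixed
    count or an inclusive ``(lo, hi)`` range sampled per vine.  A single seed
    drives a per-leaf spawned RNG stream, so generation is deterministic and
    order-independent.

    Returns the landmark table, the matching outlines, and a ground-truth
    table holding every sampled parameter value.
    """
    if not specs:
        raise ValueError("empty species spec list")
    if len(specs) < 2:
        raise ValueError("need at least 2 species")
    if isinstance(nodes_per_vine, int):
        lo = hi = nodes_per_vine
    else:
        lo, hi = nodes_per_vine
    if not (2 <= lo <= hi <= 30):
        raise ValueError("nodes_per_vine must lie within [2, 30]")

    root = np.random.SeedSequence(seed)
    records: list[LeafRecord] = []
    configs: list[np.ndarray] = []
    outlines: list[np.ndarray] = []
    truth_rows: list[dict] = []

    vine_counter = 0
    for spec in specs:
        for v in range(vines_per_species):
            vine_counter += 1
            vine_id = f"{spec.name}_v{v + 1}"
            vine_ss = root.spawn(1)[0]
            vine_rng = np.random.default_rng(vine_ss)
            n_nodes = int(vine_rng.integers(lo, hi + 1))
            leaf_streams = vine_ss.spawn(n_nodes)
            for node in range(1, n_nodes + 1):
                rng = np.random.default_rng(leaf_streams[node - 1])
                z = rng.standard_normal(len(LeafParams.numeric_fields))
                p = spec.params_at_node(node, noise=z, noise_scale=noise)
                if asymmetry_sd > 0:
                    # signed: either side of a leaf may be the larger one
                    p = replace(p, asymmetry=rng.normal(0.0, asymmetry_sd))
                    p = _clip_params(
                        {k: getattr(p, k) for k in LeafParams.numeric_fields},
                        p.n_outline_points,
                    )
                landmarks, outline = synth_leaf(p)
                leaf_id = f"{vine_id}_n{node:02d}"
                records.append(
                    LeafRecord(
                        leaf_id=leaf_id,
                        species=spec.name,
                        species_class=spec.class_label,
                        vine_id=vine_id,
                        node_base1=node,
                    )
                )
                configs.append(landmarks)
                outlines.append(outline)
                truth_rows.append(
                    {"leaf_id": leaf_id, "species": spec.name,
                     "species_class": spec.class_label, "vine_id": vine_id,
                     "node_base1": node,
                     **{k: getattr(p, k) for k in LeafParams.numeric_fields}}
                )

    table = LandmarkTable(records=records, configurations=np.stack(configs))
    truth = pd.DataFrame(truth_rows).set_index("leaf_id")
    return table, outlines, truth
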