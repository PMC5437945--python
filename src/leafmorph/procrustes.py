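"""Generalized Procrustes analysis of 2-D landmark configurations.

Full Procrustes superimposition: every configuration is centered and scaled
to unit centroid size, then rotated (and, optionally, reflected — matching
superimposition with reflection allowed) onto an iteratively re-estimated
mean shape.  Shape differences that remain after superimposition are the
residual full-Procrustes distances used downstream for PCA morphospaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_LANDMARKS",
    "centroid_size",
    "align_pair",
    "gpa",
    "SimilarityTransform",
    "ProcrustesResult",
    "GeneralizedProcrustesAlignment",
]

N_LANDMARKS = 15


def _as_config(points: np.ndarray, n_landmarks: int | None = None) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("configuration must be a (k, 2) array")
    if n_landmarks is not None and pts.shape[0] != n_landmarks:
        raise ValueError(f"expected {n_landmarks} landmarks, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite landmark coordinate")
    return pts


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared deviations of the points from their centroid."""
    pts = _as_config(config)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return cs


@dataclass
class SimilarityTransform:
    """Map ``p -> scale * p @ rotation + translation`` (rotation may reflect)."""

    rotation: np.ndarray      # (2, 2) orthogonal
    scale: float
    translation: np.ndarray   # (2,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, float) @ self.rotation + self.translation

    @property
    def reflects(self) -> bool:
        return bool(np.linalg.det(self.rotation) < 0)


def _optimal_rotation(ref_unit: np.ndarray, mov_unit: np.ndarray, allow_reflection: bool):
    """Best orthogonal map R (applied as mov @ R) onto ref; both centered, unit size.

    Returns (R, sum_of_singular_values) where the latter is the full-Procrustes
    correlation; the minimized squared distance is 1 - s^2 with optimal scaling.
    On a tie between the reflecting and non-reflecting optimum the
    determinant +1 solution is returned.
    """
    M = mov_unit.T @ ref_unit
    U, S, Vt = np.linalg.svd(M)
    R = U @ Vt
    s = float(S.sum())
    if not allow_reflection and np.linalg.det(R) < 0:
        D = np.diag([1.0, -1.0])
        R = U @ D @ Vt
        s = float(S[0] - S[1])
    return R, s


def align_pair(
    A: np.ndarray, B: np.ndarray, allow_reflection: bool = True
) -> tuple[SimilarityTransform, float]:
    """Superimpose configuration B onto A.

    Returns the similarity transform (translation + scale + orthogonal map,
    reflection permitted only when ``allow_reflection``) minimizing the summed
    squared distances of transformed B to A, together with the full-Procrustes
    distance between the two shapes (computed with both configurations
    centered and scaled to unit centroid size, B optimally scaled).
    """
    A = _as_config(A)
    B = _as_config(B)
    if A.shape != B.shape:
        raise ValueError("configurations must have the same number of landmarks")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    sa, sb = centroid_size(A), centroid_size(B)
    Au, Bu = Ac / sa, Bc / sb
    R, s = _optimal_rotation(Au, Bu, allow_reflection)

    # optimal scale mapping raw B onto raw A: beta = s * |A| / |B|
    beta = s * sa / sb
    translation = ca - beta * cb @ R
    # residual norm computed directly (sqrt(1 - s^2) loses precision near 0)
    dist = float(np.linalg.norm(Au - s * Bu @ R))
    return SimilarityTransform(rotation=R, scale=beta, translation=translation), dist


@dataclass
class ProcrustesResult:
    aligned: np.ndarray            # (n, k, 2), centered, superimposed on the mean
    mean_shape: np.ndarray         # (k, 2), centroid (0, 0), centroid size 1
    centroid_sizes: np.ndarray     # (n,) sizes of the raw inputs
    residual_distances: np.ndarray # (n,) full-Procrustes distance to the mean
    iterations: int
    converged: bool


def _index_signature(coords: np.ndarray) -> float:
    """Landmark-index-weighted coordinate sum; sign-sensitive to axis flips.

    Weights depend on the landmark label, not only the point cloud, so the
    signature distinguishes a labeled configuration from its reflection even
    when the shape itself is mirror-symmetric (reflection then permutes the
    labels).  Falls back to quadratic weights if the linear sum is degenerate.
    """
    k = coords.shape[0]
    for w in (np.arange(1, k + 1, dtype=float), np.arange(1, k + 1, dtype=float) ** 2):
        v = float(np.sum(w * coords))
        if abs(v) > 1e-9:
            return v
    return 0.0


def _canonical_orientation(mean: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Rotation (optionally with reflection) fixing the mean's orientation.

    The mean of a GPA depends on the arbitrary orientation of the inputs; this
    picks a deterministic frame: principal axes of the mean shape, each axis
    oriented so its index-weighted coordinate sum is non-negative.  Single-axis
    flips are reflections and are only applied when reflection is allowed;
    otherwise only a 180-degree rotation (both axes) is available.
    """
    cov = mean.T @ mean
    _, V = np.linalg.eigh(cov)
    V = V[:, ::-1]  # major axis first
    if np.linalg.det(V) < 0:
        V[:, 1] = -V[:, 1]
    rotated = mean @ V
    sx = _index_signature(rotated[:, 0])
    sy = _index_signature(rotated[:, 1])
    flip = np.eye(2)
    if allow_reflection:
        if sx < 0:
            flip[0, 0] = -1.0
        if sy < 0:
            flip[1, 1] = -1.0
    else:
        if sx < 0:
            flip = -np.eye(2)
    return V @ flip


def gpa(
    configs,
    allow_reflection: bool = True,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ProcrustesResult:
    """Generalized (full) Procrustes analysis.

    All configurations are centered and scaled to unit centroid size; the mean
    is initialized from the first configuration and alternately re-estimated
    and re-unit-sized while every configuration is re-superimposed onto it,
    until the mean moves less than ``tol`` (Frobenius norm) or ``max_iter`` is
    reached (then ``converged=False``; no exception).  The converged mean is
    put in a canonical orientation so the result does not depend on how the
    inputs happened to be rotated, scaled, or (when reflection is allowed)
    flipped.
    """
    arrs = [_as_config(c) for c in configs]
    if len(arrs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = arrs[0].shape[0]
    if any(a.shape[0] != k for a in arrs):
        raise ValueError("all configurations must have the same number of landmarks")

    sizes = np.array([centroid_size(a) for a in arrs])
    unit = np.stack([(a - a.mean(axis=0)) / s for a, s in zip(arrs, sizes)])

    mean = unit[0].copy()
    mean /= np.sqrt(np.sum(mean**2))
    aligned = unit.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(arrs)):
            R, s = _optimal_rotation(mean, unit[i], allow_reflection)
            aligned[i] = s * unit[i] @ R  # optimal rotation and scale onto mean
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        nrm = np.sqrt(np.sum(new_mean**2))
        if nrm <= 0:
            raise ValueError("degenerate mean shape during GPA")
        new_mean /= nrm
        move = float(np.sqrt(np.sum((new_mean - mean) ** 2)))
        mean = new_mean
        if move < tol:
            converged = True
            break

    Rc = _canonical_orientation(mean, allow_reflection)
    mean = mean @ Rc
    aligned = aligned @ Rc

    resid = np.empty(len(arrs))
    for i in range(len(arrs)):
        R, s = _optimal_rotation(mean, unit[i], allow_reflection)
        resid[i] = np.linalg.norm(mean - s * unit[i] @ R)

    return ProcrustesResult(
        aligned=aligned,
        mean_shape=mean,
        centroid_sizes=sizes,
        residual_distances=resid,
        iterations=it,
        converged=converged,
    )


class GeneralizedProcrustesAlignment:
    """Estimator interface over :func:`gpa`.

    ``fit`` runs the generalized Procrustes analysis on a stack of
    configurations; ``transform`` superimposes configurations (the training
    ones by default, or new ones) onto the fitted mean shape and returns
    flattened coordinate traits in x1..xk, y1..yk column order.

    Parameters
    ----------
    allow_reflection : bool
        Permit improper (reflecting) superimpositions (default True).
    tol, max_iter : float, int
        Convergence tolerance on the mean (Frobenius movement) and iteration cap.

    Attributes
    ----------
    mean_shape_ : (k, 2) ndarray — consensus shape, centroid (0,0), unit size.
    aligned_ : (n, k, 2) ndarray — training configurations after superimposition.
    centroid_sizes_, residual_distances_ : per-configuration size and
        full-Procrustes distance to the mean.
    n_iter_, converged_ : iteration count and convergence flag.
    """

    def __init__(self, allow_reflection: bool = True, tol: float = 1e-10, max_iter: int = 200):
        self.allow_reflection = allow_reflection
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "allow_reflection": self.allow_reflection,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "GeneralizedProcrustesAlignment":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _stack(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # flattened x1..xk, y1..yk rows
            k = X.shape[1] // 2
            X = np.stack([np.column_stack([r[:k], r[k:]]) for r in X])
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("expected (n, k, 2) configurations or (n, 2k) flat rows")
        return X

    def fit(self, X, y=None) -> "GeneralizedProcrustesAlignment":
        X = self._stack(X)
        res = gpa(list(X), self.allow_reflection, self.tol, self.max_iter)
        self.mean_shape_ = res.mean_shape
        self.aligned_ = res.aligned
        self.centroid_sizes_ = res.centroid_sizes
        self.residual_distances_ = res.residual_distances
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        self.n_landmarks_ = res.mean_shape.shape[0]
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "mean_shape_"):
            raise RuntimeError("fit the alignment before calling transform")
        if X is None:
            aligned = self.aligned_
        else:
            X = self._stack(X)
            out = []
            for cfg in X:
                cs = centroid_size(cfg)
                u = (cfg - cfg.mean(axis=0)) / cs
                R, s = _optimal_rotation(self.mean_shape_, u, self.allow_reflection)
                out.append(s * u @ R)
            aligned = np.stack(out)
        n, k, _ = aligned.shape
        return np.concatenate([aligned[:, :, 0], aligned[:, :, 1]], axis=1)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        k = getattr(self, "n_landmarks_", N_LANDMARKS)
        return np.array([f"x{i}" for i in range(1, k + 1)] + [f"y{i}" for i in range(1, k + 1)])
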