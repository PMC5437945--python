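"""Elliptical Fourier analysis of closed leaf outlines.

A closed contour is treated as a pair of periodic signals ``x(t)``, ``y(t)``
parameterized by arc length ``t`` over one traversal of perimeter ``T``.  Its
elliptical Fourier descriptors (EFDs) are the coefficients of the truncated
Fourier series

.. math::

    x(t) = A_0 + \\sum_n A_n \\cos(2\\pi n t/T) + B_n \\sin(2\\pi n t/T)

    y(t) = C_0 + \\sum_n C_n \\cos(2\\pi n t/T) + D_n \\sin(2\\pi n t/T)

computed in closed form for a polygonal contour (piecewise-linear ``x``, ``y``),
with arbitrary segment lengths ``dt_p``.  When the contour is a pixel chain the
segment lengths are 1 or sqrt(2) and the formulas reduce to the classical
chain-code expressions.

Normalization removes size, rotation, translation, and starting-point phase
using the first-harmonic ellipse, so that ``A1 = 1`` and ``B1 = C1 = 0``;
``D1`` keeps its sign, encoding first-harmonic chirality.  After
normalization the B and C coefficients carry the asymmetric part of shape
variation: reflecting a contour about the normalization axis negates every
``B_n`` and ``C_n`` and preserves every ``A_n`` and ``D_n``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HarmonicCoefficients",
    "NormalizationInfo",
    "trace_boundary",
    "resample_contour",
    "contour_perimeter",
    "efd_coefficients",
    "normalize_efd",
    "reconstruct_contour",
    "mean_coefficients",
    "harmonic_contribution",
    "EllipticalFourierFeaturizer",
]


# --------------------------------------------------------------------------
# containers


@dataclass
class HarmonicCoefficients:
    """EFD coefficient series for one contour.

    Arrays ``A, B, C, D`` hold the coefficients of harmonic ranks
    ``1..n_harmonics``.  ``A0``/``C0`` are the centroid offsets of the
    arc-length parameterization (discarded on normalization).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    A0: float = 0.0
    C0: float = 0.0
    T: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.A)
        if n < 1 or any(len(v) != n for v in (self.B, self.C, self.D)):
            raise ValueError("A, B, C, D must be equal-length, nonempty arrays")
        if not all(np.all(np.isfinite(v)) for v in (self.A, self.B, self.C, self.D)):
            raise ValueError("non-finite harmonic coefficient")
        if self.normalized:
            if abs(self.A[0] - 1.0) > 1e-9 or abs(self.B[0]) > 1e-9 or abs(self.C[0]) > 1e-9:
                raise ValueError("normalized coefficients must satisfy A1=1, B1=C1=0")

    @property
    def n_harmonics(self) -> int:
        return len(self.A)

    def stacked(self) -> np.ndarray:
        """Coefficients as an (n_harmonics, 4) array in A, B, C, D column order."""
        return np.column_stack([self.A, self.B, self.C, self.D])

    def trait_vector(self) -> np.ndarray:
        """Flatten to the trait layout A1..An, B1..Bn, C1..Cn, D1..Dn."""
        return np.concatenate([self.A, self.B, self.C, self.D])

    @classmethod
    def from_trait_vector(
        cls, values: np.ndarray, n_harmonics: int, normalized: bool = True
    ) -> "HarmonicCoefficients":
        values = np.asarray(values, dtype=float)
        if values.shape != (4 * n_harmonics,):
            raise ValueError("trait vector length must be 4 * n_harmonics")
        A, B, C, D = values.reshape(4, n_harmonics)
        return cls(A=A, B=B, C=C, D=D, normalized=normalized)

    def trait_names(self) -> list[str]:
        n = self.n_harmonics
        return [f"{ltr}{k}" for ltr in "ABCD" for k in range(1, n + 1)]


@dataclass
class NormalizationInfo:
    """Parameters removed by EFD normalization."""

    theta1: float  # starting-point phase, radians
    psi1: float    # first-ellipse orientation, radians
    scale: float   # semi-major axis magnitude E of the first harmonic

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("normalization scale must be positive")


# --------------------------------------------------------------------------
# contour utilities


def _as_contour(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("contour must be an (K, 2) array with K >= 3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("contour contains non-finite coordinates")
    # drop an explicit closing point and any zero-length segments
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    keep = seg > 0
    pts = pts[keep]
    if pts.shape[0] < 3:
        raise ValueError("contour degenerate after removing zero-length segments")
    return pts


def contour_perimeter(points: np.ndarray) -> float:
    pts = _as_contour(points)
    closed = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def signed_area(points: np.ndarray) -> float:
    pts = _as_contour(points)
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def resample_contour(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polyline at ``n_points`` equal arc-length steps."""
    pts = _as_contour(points)
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    ti = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(ti, t, closed[:, 0])
    y = np.interp(ti, t, closed[:, 1])
    return np.column_stack([x, y])


# --------------------------------------------------------------------------
# boundary tracing

# Moore neighborhood in image (row, col) offsets, clockwise starting at W
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a single foreground component.

    Moore-neighbor tracing with Jacob's stopping criterion.  The trace starts
    at the top-most, then left-most boundary pixel and is returned in math
    coordinates ``(x = col, y = height - 1 - row)``, oriented counterclockwise
    (positive signed area).  Pixel centers are vertices; no subpixel
    interpolation is performed.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValueError("empty foreground: mask has no true pixels")
    if n_fg < 4:
        raise ValueError(f"foreground too small to trace ({n_fg} pixels, need >= 4)")
    from scipy import ndimage

    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        sizes = np.bincount(labels.ravel())[1:]
        raise ValueError(
            f"mask has {n_comp} 8-connected components (sizes {sorted(sizes.tolist(), reverse=True)}); expected exactly 1"
        )

    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    rows, cols = np.nonzero(padded)
    r0 = rows.min()
    c0 = cols[rows == r0].min()
    start = (int(r0), int(c0))

    # the pixel west of the start is background (scan order), so the initial
    # backtrack neighbor is W.  Trace state = (current pixel, backtrack pixel);
    # the trace closes when the initial state recurs (Jacob's criterion).
    boundary: list[tuple[int, int]] = []
    state0 = (start, (start[0], start[1] - 1))
    current, back = state0
    max_steps = 8 * padded.size
    for _ in range(max_steps):
        boundary.append(current)
        b_idx = _MOORE.index((back[0] - current[0], back[1] - current[1]))
        nxt = None
        for k in range(1, 9):
            idx = (b_idx + k) % 8
            dr, dc = _MOORE[idx]
            cand = (current[0] + dr, current[1] + dc)
            if padded[cand]:
                nxt = cand
                prev_idx = (idx - 1) % 8
                back = (current[0] + _MOORE[prev_idx][0], current[1] + _MOORE[prev_idx][1])
                break
        if nxt is None:  # pragma: no cover - excluded by size precondition
            break
        current = nxt
        if (current, back) == state0:
            break
    else:  # pragma: no cover - safety net
        raise RuntimeError("boundary trace failed to terminate")

    # drop consecutive duplicates (can occur on 1-pixel-wide spurs)
    pts_rc = [boundary[0]]
    for p in boundary[1:]:
        if p != pts_rc[-1]:
            pts_rc.append(p)
    if len(pts_rc) > 1 and pts_rc[-1] == pts_rc[0]:
        pts_rc.pop()

    arr = np.array(pts_rc, dtype=float) - 1.0  # undo padding
    xy = np.column_stack([arr[:, 1], (h - 1) - arr[:, 0]])
    if xy.shape[0] >= 3 and signed_area(xy) < 0:
        xy = np.vstack([xy[:1], xy[1:][::-1]])  # reverse, keep start pixel first
    return xy


# --------------------------------------------------------------------------
# forward transform


def efd_coefficients(contour: np.ndarray, n_harmonics: int) -> HarmonicCoefficients:
    """Closed-form EFD coefficients of a polygonal contour.

    Uses the line-integral expressions over the K polygon segments with
    ``dt_p`` equal to segment length and ``T`` the perimeter:

        A_n = T/(2 n^2 pi^2) * sum_p (dx_p/dt_p) [cos(2 pi n t_p / T) - cos(2 pi n t_{p-1} / T)]

    and analogously with sin for B_n and with dy for C_n, D_n.  The offsets
    A0, C0 are the arc-length means of x(t), y(t).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = _as_contour(contour)
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)              # (K, 2)
    dt = np.linalg.norm(d, axis=1)           # (K,)
    if np.any(dt == 0):
        raise ValueError("zero-length segment in contour")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]

    n = np.arange(1, n_harmonics + 1)[:, None]          # (N, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T              # (N, K+1)
    dcos = np.cos(phi[:, 1:]) - np.cos(phi[:, :-1])     # (N, K)
    dsin = np.sin(phi[:, 1:]) - np.sin(phi[:, :-1])

    coef = T / (2.0 * (n.ravel() ** 2) * np.pi**2)      # (N,)
    vx = d[:, 0] / dt                                   # (K,)
    vy = d[:, 1] / dt

    A = coef * (dcos @ vx)
    B = coef * (dsin @ vx)
    C = coef * (dcos @ vy)
    D = coef * (dsin @ vy)

    # offsets: arc-length means of the piecewise-linear x(t), y(t)
    midx = 0.5 * (closed[:-1, 0] + closed[1:, 0])
    midy = 0.5 * (closed[:-1, 1] + closed[1:, 1])
    A0 = float(np.sum(midx * dt) / T)
    C0 = float(np.sum(midy * dt) / T)

    return HarmonicCoefficients(A=A, B=B, C=C, D=D, A0=A0, C0=C0, T=float(T), normalized=False)


# --------------------------------------------------------------------------
# normalization


def _rotate_start(stacked: np.ndarray, theta: float) -> np.ndarray:
    """Apply the start-point phase rotation by n*theta to each rank's 2x2 block."""
    n_h = stacked.shape[0]
    out = np.empty_like(stacked)
    ranks = np.arange(1, n_h + 1)
    c = np.cos(ranks * theta)
    s = np.sin(ranks * theta)
    A, B, C, D = stacked.T
    out[:, 0] = A * c + B * s
    out[:, 1] = -A * s + B * c
    out[:, 2] = C * c + D * s
    out[:, 3] = -C * s + D * c
    return out


def _rotate_space(stacked: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the coordinate frame by -psi: [[cos, sin], [-sin, cos]] on the left."""
    c, s = np.cos(psi), np.sin(psi)
    A, B, C, D = stacked.T
    out = np.empty_like(stacked)
    out[:, 0] = c * A + s * C
    out[:, 1] = c * B + s * D
    out[:, 2] = -s * A + c * C
    out[:, 3] = -s * B + c * D
    return out


def _candidate(stacked: np.ndarray, theta: float) -> tuple[np.ndarray, float, float]:
    rot = _rotate_start(stacked, theta)
    a1s, _, c1s, _ = rot[0]
    psi = float(np.arctan2(c1s, a1s))
    norm = _rotate_space(rot, psi)
    E = float(np.hypot(a1s, c1s))
    return norm / E, psi, E


def normalize_efd(
    coeffs: HarmonicCoefficients,
) -> tuple[HarmonicCoefficients, NormalizationInfo]:
    """Normalize EFDs against the first-harmonic ellipse.

    The starting-point phase ``theta1 = 0.5 atan2(2(A1 B1 + C1 D1),
    A1^2 + C1^2 - B1^2 - D1^2)`` is removed by rotating each rank-n block by
    ``n * theta1``; the ellipse orientation ``psi1 = atan2(C1*, A1*)`` is
    removed by a spatial rotation; all coefficients are divided by the
    semi-major magnitude ``E = sqrt(A1*^2 + C1*^2)``; offsets are discarded.

    ``theta1`` is defined modulo pi (the start point may sit at either end of
    the semi-major axis).  The branch is fixed from shape content so that the
    result is invariant to where the traversal started: among even ranks,
    scanned in the order A2, D2, A4, D4, ..., then B2, C2, ..., the first
    coefficient exceeding 1e-9 in magnitude is made positive.  Rank-1
    coefficients (including the chirality sign of D1) are identical on both
    branches.
    """
    if coeffs.normalized:
        raise ValueError("coefficients are already normalized")
    stacked = coeffs.stacked()
    a1, b1, c1, d1 = stacked[0]
    energy = a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1
    if energy <= (1e-12 * coeffs.T) ** 2:
        raise ValueError("degenerate first harmonic; cannot normalize")
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)

    cand0, psi0, e0 = _candidate(stacked, theta)
    cand1, psi1_, e1 = _candidate(stacked, theta + np.pi)

    chosen, psi, E, th = cand0, psi0, e0, float(theta)
    n_h = stacked.shape[0]
    if n_h >= 2:
        even = np.arange(2, n_h + 1, 2) - 1  # 0-based indices of even ranks
        # scan A, D of even ranks first, then B, C
        scan = [(i, col) for col in (0, 3) for i in even] + [
            (i, col) for col in (1, 2) for i in even
        ]
        for i, col in scan:
            v = cand0[i, col]
            if abs(v) > 1e-9:
                if v < 0:
                    chosen, psi, E, th = cand1, psi1_, e1, float(theta + np.pi)
                break

    out = HarmonicCoefficients(
        A=chosen[:, 0],
        B=chosen[:, 1],
        C=chosen[:, 2],
        D=chosen[:, 3],
        A0=0.0,
        C0=0.0,
        T=coeffs.T,
        normalized=True,
    )
    # clamp the analytic zeros so the normalized invariant holds exactly
    out.A[0] = 1.0
    out.B[0] = 0.0
    out.C[0] = 0.0
    return out, NormalizationInfo(theta1=th, psi1=float(psi), scale=float(E))


# --------------------------------------------------------------------------
# reconstruction and group statistics


def reconstruct_contour(
    coeffs: HarmonicCoefficients, n_use: int | None = None, n_points: int = 200
) -> np.ndarray:
    """Evaluate the truncated Fourier series at ``n_points`` uniform t values."""
    if n_use is None:
        n_use = coeffs.n_harmonics
    if not 1 <= n_use <= coeffs.n_harmonics:
        raise ValueError(
            f"n_use={n_use} outside available harmonic range 1..{coeffs.n_harmonics}"
        )
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, n_use + 1)[:, None]
    ang = 2.0 * np.pi * n * t[None, :]
    cosang, sinang = np.cos(ang), np.sin(ang)
    x = coeffs.A0 + coeffs.A[:n_use] @ cosang + coeffs.B[:n_use] @ sinang
    y = coeffs.C0 + coeffs.C[:n_use] @ cosang + coeffs.D[:n_use] @ sinang
    return np.column_stack([x, y])


def mean_coefficients(group: list[HarmonicCoefficients]) -> HarmonicCoefficients:
    """Arithmetic per-coefficient mean of a group of normalized EFD series."""
    if not group:
        raise ValueError("empty group")
    n = group[0].n_harmonics
    if any(g.n_harmonics != n for g in group):
        raise ValueError("mixed n_harmonics in group")
    states = {g.normalized for g in group}
    if len(states) > 1:
        raise ValueError("mixed normalization states in group")
    if not states.pop():
        raise ValueError("mean_coefficients expects normalized coefficients")
    stack = np.stack([g.stacked() for g in group])
    m = stack.mean(axis=0)
    out = HarmonicCoefficients(
        A=m[:, 0], B=m[:, 1], C=m[:, 2], D=m[:, 3],
        T=float(np.mean([g.T for g in group])), normalized=False,
    )
    # the mean of normalized series still has A1=1, B1=C1=0 exactly
    out.normalized = True
    return out


def harmonic_contribution(
    mean: HarmonicCoefficients, rank: int, amplification: float, n_points: int = 200
) -> np.ndarray:
    """Reconstruct with one harmonic rank's coefficients amplified.

    ``amplification = 1`` reproduces the plain reconstruction; larger factors
    exaggerate the shape features carried by that rank (lobing for low ranks,
    serration-scale detail for high ranks).
    """
    if not 1 <= rank <= mean.n_harmonics:
        raise ValueError(f"rank {rank} outside 1..{mean.n_harmonics}")
    amp = replace(mean)
    amp.A = mean.A.copy()
    amp.B = mean.B.copy()
    amp.C = mean.C.copy()
    amp.D = mean.D.copy()
    i = rank - 1
    for arr in (amp.A, amp.B, amp.C, amp.D):
        arr[i] *= amplification
    amp.normalized = False  # amplification may break the A1=1 invariant
    return reconstruct_contour(amp, n_use=amp.n_harmonics, n_points=n_points)


# --------------------------------------------------------------------------
# estimator


class EllipticalFourierFeaturizer:
    """Transform closed contours into normalized EFD trait vectors.

    Parameters
    ----------
    n_harmonics : int
        Number of harmonic ranks retained (default 20).
    n_resample : int or None
        Contours are resampled to this many equal arc-length points before
        analysis (default 500); ``None`` disables resampling.

    The output of :meth:`transform` is an ``(n_samples, 4 * n_harmonics)``
    array in A1..An, B1..Bn, C1..Cn, D1..Dn column order; trait names are
    available from :meth:`get_feature_names_out`.
    """

    def __init__(self, n_harmonics: int = 20, n_resample: int | None = 500):
        self.n_harmonics = n_harmonics
        self.n_resample = n_resample

    def get_params(self, deep: bool = True) -> dict:
        return {"n_harmonics": self.n_harmonics, "n_resample": self.n_resample}

    def set_params(self, **params) -> "EllipticalFourierFeaturizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "EllipticalFourierFeaturizer":
        self.n_features_out_ = 4 * self.n_harmonics
        return self

    def transform_one(self, contour: np.ndarray) -> HarmonicCoefficients:
        pts = np.asarray(contour, dtype=float)
        if self.n_resample is not None:
            pts = resample_contour(pts, self.n_resample)
        raw = efd_coefficients(pts, self.n_harmonics)
        norm, _ = normalize_efd(raw)
        return norm

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        return np.stack([self.transform_one(c).trait_vector() for c in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        n = self.n_harmonics
        return np.array([f"{ltr}{k}" for ltr in "ABCD" for k in range(1, n + 1)])
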