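import numpy as np
import pytest
from scipy.integrate import quad

from conftest import random_polygon
from leafmorph.efd import (
    HarmonicCoefficients,
    efd_coefficients,
    harmonic_contribution,
    mean_coefficients,
    normalize_efd,
    reconstruct_contour,
    resample_contour,
    signed_area,
    trace_boundary,
)
from leafmorph.synth import LeafParams, synth_leaf


def quadrature_efd(points, n_harmonics, epsabs=1e-12, epsrel=1e-10):
    """Independent oracle: direct Fourier integrals of the arc-length
    parameterization, a_n = (2/T) \\int x(t) cos(2 pi n t / T) dt, evaluated by
    adaptive quadrature with the polygon vertices as breakpoints."""
    pts = np.asarray(points, float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    T = t[-1]

    def coord(s, axis):
        s = np.clip(s, 0.0, T)
        return np.interp(s, t, closed[:, axis])

    out = np.zeros((n_harmonics, 4))
    breaks = t[1:-1]
    for n in range(1, n_harmonics + 1):
        w = 2 * np.pi * n / T
        for j, (axis, trig) in enumerate(
            [(0, np.cos), (0, np.sin), (1, np.cos), (1, np.sin)]
        ):
            val, _ = quad(
                lambda s: coord(s, axis) * trig(w * s),
                0.0, T, points=breaks, limit=20 * len(breaks),
                epsabs=epsabs, epsrel=epsrel,
            )
            out[n - 1, j] = 2.0 / T * val
    return out


class TestForwardTransform:
    def test_circle_analytic(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        R = 2.0
        circ = np.column_stack([3 + R * np.cos(t), -1 + R * np.sin(t)])
        c = efd_coefficients(circ, 10)
        assert c.A[0] == pytest.approx(R, abs=1e-3 * R)
        assert c.D[0] == pytest.approx(R, abs=1e-3 * R)
        assert abs(c.B[0]) < 1e-3 * R and abs(c.C[0]) < 1e-3 * R
        assert np.abs(c.stacked()[1:]).max() < 1e-3 * R
        assert c.A0 == pytest.approx(3.0, abs=1e-6)
        assert c.C0 == pytest.approx(-1.0, abs=1e-6)

    def test_random_polygons_match_quadrature_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(2):
            poly = random_polygon(rng, n_vertices=20)
            ours = efd_coefficients(poly, 8).stacked()
            oracle = quadrature_efd(poly, 8)
            scale = np.abs(oracle).max()
            np.testing.assert_allclose(ours, oracle, atol=1e-6 * scale, rtol=1e-6)

    def test_unit_square_matches_quadrature_oracle(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        ours = efd_coefficients(sq, 12).stacked()
        oracle = quadrature_efd(sq, 12)
        np.testing.assert_allclose(ours, oracle, atol=1e-9, rtol=1e-6)

    def test_zero_length_segment_rejected(self):
        bad = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1]])
        # duplicate points are cleaned; a fully degenerate contour errors
        efd_coefficients(bad, 2)
        with pytest.raises(ValueError):
            efd_coefficients(np.zeros((4, 2)), 2)


class TestNormalization:
    def test_ellipse_normalized_first_harmonic(self):
        """Normalized EFDs of a 2:1 ellipse: A1 = 1 exactly; D1 equals the
        value fixed by the arc-length parameterization (computed independently
        by quadrature: the semi-axis ratio 0.5 is NOT the arc-length value)."""
        t = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
        ell = np.column_stack([2 * np.cos(t), np.sin(t)])
        th = 37 * np.pi / 180
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = 5.0 * ell @ R.T + np.array([7.0, -3.0])
        norm, info = normalize_efd(efd_coefficients(moved, 10))
        assert norm.A[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(norm.B[0]) < 1e-9 and abs(norm.C[0]) < 1e-9
        oracle = quadrature_efd(resample_contour(ell, 2048), 1)[0]
        assert norm.D[0] == pytest.approx(oracle[3] / oracle[0], abs=1e-4)
        assert info.scale == pytest.approx(5.0 * oracle[0], rel=1e-3)

    def test_circle_normalized(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        circ = np.column_stack([np.cos(t), np.sin(t)])
        norm, _ = normalize_efd(efd_coefficients(circ, 5))
        assert norm.A[0] == pytest.approx(1.0)
        assert abs(norm.D[0]) == pytest.approx(1.0, abs=1e-3)

    def test_similarity_and_start_point_invariance(self):
        rng = np.random.default_rng(3)
        poly = random_polygon(rng, resample=600)
        base, _ = normalize_efd(efd_coefficients(poly, 15))
        for k in range(5):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            moved = rng.uniform(0.2, 5) * poly @ R.T + rng.normal(0, 10, 2)
            moved = np.roll(moved, rng.integers(len(moved)), axis=0)
            alt, _ = normalize_efd(efd_coefficients(moved, 15))
            np.testing.assert_allclose(alt.stacked(), base.stacked(), atol=1e-8)

    def test_start_shift_by_third(self):
        rng = np.random.default_rng(9)
        poly = random_polygon(rng, resample=600)
        base, _ = normalize_efd(efd_coefficients(poly, 15))
        shifted = np.roll(poly, len(poly) // 3, axis=0)
        alt, _ = normalize_efd(efd_coefficients(shifted, 15))
        np.testing.assert_allclose(alt.stacked(), base.stacked(), atol=1e-8)

    def test_mirror_negates_b_and_c(self):
        rng = np.random.default_rng(4)
        poly = random_polygon(rng, resample=500)
        base, _ = normalize_efd(efd_coefficients(poly, 12))
        mirrored = (poly * np.array([1.0, -1.0]))[::-1]  # keep counterclockwise
        alt, _ = normalize_efd(efd_coefficients(mirrored, 12))
        np.testing.assert_allclose(alt.A, base.A, atol=1e-8)
        np.testing.assert_allclose(alt.D, base.D, atol=1e-8)
        np.testing.assert_allclose(alt.B, -base.B, atol=1e-8)
        np.testing.assert_allclose(alt.C, -base.C, atol=1e-8)

    def test_degenerate_first_harmonic_rejected(self):
        c = HarmonicCoefficients(A=[0.0, 1], B=[0, 0], C=[0, 0], D=[0, 1], T=1.0)
        with pytest.raises(ValueError, match="(?i)degenerate"):
            normalize_efd(c)


class TestReconstruction:
    def test_single_harmonic_is_ellipse(self):
        c = HarmonicCoefficients(A=[1.0], B=[0.0], C=[0.0], D=[0.5], normalized=True)
        pts = reconstruct_contour(c, n_use=1, n_points=360)
        assert np.abs(pts[:, 0]).max() == pytest.approx(1.0, abs=1e-6)
        assert np.abs(pts[:, 1]).max() == pytest.approx(0.5, abs=1e-6)

    def test_rms_error_nonincreasing_in_n_use(self):
        _, outline = synth_leaf(LeafParams(asymmetry=0.05))
        target = resample_contour(outline, 720)
        coeffs = efd_coefficients(target, 20)
        errs = []
        for n_use in range(1, 21):
            rec = reconstruct_contour(coeffs, n_use=n_use, n_points=720)
            errs.append(np.sqrt(np.mean(np.sum((rec - target) ** 2, axis=1))))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_convergence_on_smooth_contour(self):
        _, outline = synth_leaf(LeafParams())
        target = resample_contour(outline, 720)
        coeffs = efd_coefficients(target, 40)
        rec = reconstruct_contour(coeffs, n_use=40, n_points=720)
        rms = np.sqrt(np.mean(np.sum((rec - target) ** 2, axis=1)))
        assert rms < 0.005 * coeffs.T

    def test_n_use_out_of_range(self):
        c = HarmonicCoefficients(A=[1.0], B=[0.0], C=[0.0], D=[0.5])
        with pytest.raises(ValueError):
            reconstruct_contour(c, n_use=2)


class TestGroupStatistics:
    def _norm_leaf(self, **kw):
        _, outline = synth_leaf(LeafParams(**kw))
        c, _ = normalize_efd(efd_coefficients(resample_contour(outline, 400), 10))
        return c

    def test_mean_of_one_is_identity(self):
        c = self._norm_leaf()
        m = mean_coefficients([c])
        np.testing.assert_allclose(m.stacked(), c.stacked())

    def test_mean_is_arithmetic(self):
        a = HarmonicCoefficients(A=[1.0], B=[0.0], C=[0.0], D=[0.4], normalized=True)
        b = HarmonicCoefficients(A=[1.0], B=[0.0], C=[0.0], D=[0.6], normalized=True)
        assert mean_coefficients([a, b]).D[0] == pytest.approx(0.5)

    def test_mean_with_mirror_cancels_bc(self):
        c = self._norm_leaf(asymmetry=0.12)
        mirror = HarmonicCoefficients(
            A=c.A.copy(), B=-c.B, C=-c.C, D=c.D.copy(), T=c.T, normalized=True
        )
        m = mean_coefficients([c, mirror])
        np.testing.assert_allclose(m.B, 0.0, atol=1e-12)
        np.testing.assert_allclose(m.C, 0.0, atol=1e-12)
        np.testing.assert_allclose(m.A, c.A)

    def test_mixed_harmonic_counts_rejected(self):
        a = HarmonicCoefficients(A=[1.0], B=[0.0], C=[0.0], D=[0.5], normalized=True)
        b = HarmonicCoefficients(A=[1, 0.0], B=[0, 0.0], C=[0, 0.0], D=[0.5, 0], normalized=True)
        with pytest.raises(ValueError):
            mean_coefficients([a, b])


class TestHarmonicContribution:
    def _mean(self):
        coeffs = []
        for depth in (0.2, 0.35, 0.5):
            _, outline = synth_leaf(LeafParams(distal_sinus_depth=depth))
            c, _ = normalize_efd(efd_coefficients(resample_contour(outline, 400), 10))
            coeffs.append(c)
        return mean_coefficients(coeffs)

    def test_amplification_one_is_identity(self):
        m = self._mean()
        np.testing.assert_allclose(
            harmonic_contribution(m, rank=3, amplification=1.0, n_points=200),
            reconstruct_contour(m, n_points=200),
        )

    def test_amplification_zero_omits_rank(self):
        m = self._mean()
        zeroed = HarmonicCoefficients(
            A=m.A.copy(), B=m.B.copy(), C=m.C.copy(), D=m.D.copy(), T=m.T
        )
        for arr in (zeroed.A, zeroed.B, zeroed.C, zeroed.D):
            arr[2] = 0.0
        np.testing.assert_allclose(
            harmonic_contribution(m, rank=3, amplification=0.0, n_points=100),
            reconstruct_contour(zeroed, n_points=100),
        )

    def test_larger_amplification_moves_farther(self):
        from scipy.spatial.distance import directed_hausdorff

        m = self._mean()
        plain = reconstruct_contour(m, n_points=300)

        def hausdorff(a, b):
            return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])

        d2 = hausdorff(harmonic_contribution(m, 2, 2.0, 300), plain)
        d5 = hausdorff(harmonic_contribution(m, 2, 5.0, 300), plain)
        assert d5 > d2

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError):
            harmonic_contribution(self._mean(), rank=11, amplification=2.0)


class TestTraceBoundary:
    def test_solid_square(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:7, 2:6] = True
        b = trace_boundary(mask)
        assert len(b) == 12  # 4x4 block has 12 perimeter pixels
        assert signed_area(b) > 0  # counterclockwise in math coordinates
        # start pixel: top-most then left-most = image row 3, col 2
        np.testing.assert_allclose(b[0], [2.0, 10 - 1 - 3.0])

    def test_rotated_mask_gives_rotated_contour(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:12, 5:10] = True
        mask[6:9, 10:13] = True
        b1 = trace_boundary(mask)
        b2 = trace_boundary(np.rot90(mask).copy())
        assert len(b1) == len(b2)
        # rotating the image by 90 deg maps math (x, y) -> (y, N-1-x)... compare
        # via rotation-invariant signature: sorted pairwise centroid distances
        d1 = np.sort(np.linalg.norm(b1 - b1.mean(axis=0), axis=1))
        d2 = np.sort(np.linalg.norm(b2 - b2.mean(axis=0), axis=1))
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_too_small_component(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError, match="(?i)small|pixels"):
            trace_boundary(mask)

    def test_multi_component_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        with pytest.raises(ValueError, match="components"):
            trace_boundary(mask)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="(?i)empty"):
            trace_boundary(np.zeros((5, 5), dtype=bool))
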