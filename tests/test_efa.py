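"""Elliptic Fourier transform, normalisation and reconstruction."""

import numpy as np
import pytest

from morphodisp import (
    EFDSet,
    Outline,
    coefficient_matrix,
    compute_efd,
    normalize_efd,
    reconstruct,
    resample_outline,
)
from morphodisp.efa import feature_columns
from .conftest import (
    circle_points,
    efd_integral_oracle,
    random_smooth_outline,
    similarity_transform,
)


class TestComputeEfd:
    def test_circle_matches_closed_form(self, circle):
        # closed-form Fourier series of a unit circle: (1, 0, 0, 1), rest 0
        e = compute_efd(circle, 5)
        np.testing.assert_allclose(e.coeffs[0], [1, 0, 0, 1], atol=1e-3)
        assert np.abs(e.coeffs[1:]).max() < 1e-3
        np.testing.assert_allclose(e.dc, [0, 0], atol=1e-9)

    def test_ellipse_first_harmonic(self, ellipse):
        # exact values under arc-length parameterization differ from the
        # equal-angle series (2, 0, 0, 1); the cross terms vanish exactly
        # and the aspect structure agrees with (2, 0, 0, 1) at the 10% level
        e = compute_efd(ellipse, 8)
        a1, b1, c1, d1 = e.coeffs[0]
        assert abs(b1) < 1e-9 and abs(c1) < 1e-9
        assert a1 == pytest.approx(2.0, rel=0.1)
        assert d1 == pytest.approx(1.0, rel=0.1)
        np.testing.assert_allclose(
            e.coeffs, efd_integral_oracle(ellipse, 8), atol=1e-6
        )

    def test_translation_changes_only_dc(self, rng):
        o = random_smooth_outline(rng)
        e = compute_efd(o, 10)
        e2 = compute_efd(Outline("t", o.points + [10.0, -5.0]), 10)
        np.testing.assert_allclose(e2.coeffs, e.coeffs, atol=1e-9)
        np.testing.assert_allclose(e2.dc - e.dc, [10.0, -5.0], atol=1e-9)

    def test_linearity_in_coordinates(self, rng):
        o = random_smooth_outline(rng)
        e = compute_efd(o, 10)
        e3 = compute_efd(Outline("s", o.points * 3.0), 10)
        np.testing.assert_allclose(e3.coeffs, 3.0 * e.coeffs, rtol=1e-12)

    def test_matches_integration_oracle_on_random_outlines(self, rng):
        for _ in range(10):
            o = random_smooth_outline(rng)
            e = compute_efd(o, 10)
            np.testing.assert_allclose(
                e.coeffs, efd_integral_oracle(o, 10), atol=1e-6
            )

    def test_exact_harmonic_count_and_determinism(self, circle):
        e1 = compute_efd(circle, 7)
        e2 = compute_efd(circle, 7)
        assert e1.n_harmonics == 7
        np.testing.assert_array_equal(e1.coeffs, e2.coeffs)


class TestNormalize:
    def test_invariance_under_similarity_transforms(self, rng):
        # 100 random rotate/scale/translate/start-roll copies of 10 outlines
        for _ in range(10):
            o = random_smooth_outline(rng)
            ref = normalize_efd(compute_efd(o, 10)).coeffs
            for _ in range(10):
                q = similarity_transform(o.points, rng)
                got = normalize_efd(compute_efd(Outline("t", q), 10)).coeffs
                np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_first_harmonic_canonical_form(self, rng):
        n = normalize_efd(compute_efd(random_smooth_outline(rng), 10))
        a1, b1, c1, d1 = n.coeffs[0]
        assert a1 == pytest.approx(1.0, abs=1e-9)
        assert abs(b1) < 1e-9 and abs(c1) < 1e-9
        assert abs(d1) <= 1.0 + 1e-9

    def test_scale_information_removed(self, rng):
        o = random_smooth_outline(rng)
        n1 = normalize_efd(compute_efd(o, 10))
        n3 = normalize_efd(compute_efd(Outline("s", o.points * 3.0), 10))
        np.testing.assert_allclose(n3.coeffs, n1.coeffs, atol=1e-9)
        assert n3.scale == pytest.approx(3.0 * n1.scale, rel=1e-9)

    def test_circle_normalises_to_unit_first_harmonic(self, circle):
        n = normalize_efd(compute_efd(circle, 5))
        np.testing.assert_allclose(np.abs(n.coeffs[0]), [1, 0, 0, 1], atol=1e-3)
        assert np.abs(n.coeffs[1:]).max() < 1e-3

    def test_idempotence(self, rng):
        n = normalize_efd(compute_efd(random_smooth_outline(rng), 10))
        again = normalize_efd(
            EFDSet("x", n.coeffs, n.dc, n.perimeter)
        )
        np.testing.assert_allclose(again.coeffs, n.coeffs, atol=1e-9)

    def test_resampled_restart_robustness(self, rng):
        # re-digitising from another starting point perturbs coefficients
        # only through polygon-chord discretization
        o = random_smooth_outline(rng, n=200)
        ref = normalize_efd(compute_efd(o, 10)).coeffs
        q = similarity_transform(o.points, rng)
        re = resample_outline(Outline("t", q), 200)
        got = normalize_efd(compute_efd(re, 10)).coeffs
        np.testing.assert_allclose(got, ref, atol=5e-3)


class TestReconstruct:
    def test_one_harmonic_ellipse_is_exact(self):
        e = EFDSet("ell", np.array([[2.0, 0.0, 0.0, 1.0]]), np.zeros(2), 2 * np.pi)
        rec = reconstruct(e, n_points=100, harmonics_used=1)
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        np.testing.assert_allclose(
            rec.points, np.column_stack([2 * np.cos(t), np.sin(t)]), atol=1e-6
        )

    def test_rms_error_non_increasing_in_harmonics(self):
        from morphodisp import default_paper_design, render_archetype

        o = render_archetype(default_paper_design().groups[0].archetype, 200)
        e = compute_efd(o, 20)
        prev = np.inf
        for h in range(1, 21):
            rec = reconstruct(e, n_points=200, harmonics_used=h)
            rms = float(np.sqrt(((rec.points - o.points) ** 2).sum(axis=1).mean()))
            assert rms <= prev + 1e-12
            prev = rms

    def test_full_series_converges_to_original(self, rng):
        from scipy.spatial.distance import directed_hausdorff

        o = random_smooth_outline(rng, n=400)
        e = compute_efd(o, 40)
        rec = reconstruct(e, n_points=800)
        hd = max(
            directed_hausdorff(rec.points, o.points)[0],
            directed_hausdorff(o.points, rec.points)[0],
        )
        assert hd < 0.01 * e.perimeter


class TestCoefficientMatrix:
    def _nefds(self, rng, n=3, harmonics=20):
        out = []
        for i in range(n):
            o = random_smooth_outline(rng)
            nefd = normalize_efd(compute_efd(o, harmonics))
            nefd.specimen_id = f"sp{i}"
            out.append(nefd)
        return out

    def test_shape_and_first_column(self, rng):
        nefds = self._nefds(rng)
        m = coefficient_matrix(nefds)
        assert m.shape == (3, 3 + 77)
        assert list(m.columns[3:]) == feature_columns(20)
        for row, nefd in zip(m.itertuples(), nefds):
            assert row.d1 == nefd.coeffs[0, 3]

    def test_identical_outlines_identical_rows(self, circle):
        a = normalize_efd(compute_efd(circle, 5))
        b = normalize_efd(compute_efd(circle, 5))
        b.specimen_id = "other"
        m = coefficient_matrix([a, b])
        np.testing.assert_array_equal(
            m.iloc[0, 3:].to_numpy(float), m.iloc[1, 3:].to_numpy(float)
        )

    def test_mixed_harmonic_counts_rejected(self, rng, circle):
        a = normalize_efd(compute_efd(circle, 5))
        b = normalize_efd(compute_efd(random_smooth_outline(rng), 6))
        with pytest.raises(ValueError, match="mixed harmonic counts"):
            coefficient_matrix([a, b])
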