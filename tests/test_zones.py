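"""Zone quantification, Welch testing, PCA, and the zone scan."""

import numpy as np
import pytest
from scipy import stats as sps

from ramanff.errors import ValidationError
from ramanff.spectra import SampleMeta, Spectrum, SpectrumSet, WavenumberGrid
from ramanff.zones import (
    Zone,
    group_difference_report,
    loading_extrema,
    pca_decompose,
    quantify_zone,
    scan_zones,
    welch_t_test,
)


class TestQuantifyZone:
    def test_flat_value_returned_exactly(self):
        grid = WavenumberGrid(600, 1800)
        sp = Spectrum(grid, np.full(grid.n_points, 0.0289))
        assert quantify_zone(sp, Zone(993, 1165)) == pytest.approx(0.0289, abs=1e-15)

    def test_linear_ramp_gives_midpoint(self):
        grid = WavenumberGrid(600, 699)
        a, b = 0.2, 0.8
        sp = Spectrum(grid, np.linspace(a, b, grid.n_points))
        assert quantify_zone(sp, Zone(600, 699)) == pytest.approx((a + b) / 2, abs=1e-12)

    def test_invariant_to_points_outside_zone(self):
        grid = WavenumberGrid(600, 1800)
        rng = np.random.default_rng(0)
        base = rng.random(grid.n_points)
        other = base.copy()
        other[:300] += 5.0  # 600-899, outside the zone
        z = Zone(1000, 1100)
        q1 = quantify_zone(Spectrum(grid, base), z)
        q2 = quantify_zone(Spectrum(grid, other), z)
        assert q1 == pytest.approx(q2, abs=1e-15)


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0 and p == 1

    def test_matches_scipy_reference(self):
        x, y = np.array([1.0, 2, 3]), np.array([2.0, 3, 4])
        t, p = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_random_instances_match_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 30))
            y = rng.normal(loc=rng.normal(), size=rng.integers(2, 30))
            t, p = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(1, 1, size=12)
        t1, p1 = welch_t_test(x, y)
        t2, p2 = welch_t_test(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        assert welch_t_test([1.0, 1], [2.0, 2])[1] == 0
        assert welch_t_test([1.0, 1], [1.0, 1]) == (0.0, 1.0)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            welch_t_test([1.0], [1.0, 2])


class TestPCA:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(2)
        pattern = rng.random(20)
        coeffs = rng.normal(size=8)[:, None]
        mat = coeffs * pattern
        res = pca_decompose(mat, 2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        mat = rng.random((4, 3))
        res = pca_decompose(mat, 3)
        centered = mat - mat.mean(axis=0)
        cov = centered.T @ centered / (mat.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(3):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(res.loadings[k], v, atol=1e-8)
        np.testing.assert_allclose(
            res.explained_variance_fraction, evals / evals.sum(), atol=1e-8
        )

    def test_scores_centered_and_reconstruction_exact(self):
        rng = np.random.default_rng(4)
        mat = rng.random((10, 6))
        res = pca_decompose(mat, 6)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        centered = mat - mat.mean(axis=0)
        recon = res.scores @ res.loadings
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_loading_rows_unit_norm(self):
        res = pca_decompose(np.random.default_rng(5).random((6, 9)), 3)
        np.testing.assert_allclose(np.linalg.norm(res.loadings, axis=1), 1, atol=1e-10)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValidationError):
            pca_decompose(np.ones((3, 5)), 4)


class TestLoadingExtrema:
    def _pca_with_loading(self, loading):
        loading = np.asarray(loading, float)
        from ramanff.zones import PCAResult

        norm = np.linalg.norm(loading)
        return PCAResult(
            scores=np.zeros((2, 1)),
            loadings=(loading / norm if norm else loading)[None, :],
            explained_variance_fraction=np.array([1.0]),
            wavenumbers=np.arange(1000, 1000 + loading.size, dtype=float),
        )

    def test_single_peak_found(self):
        loading = np.exp(-0.5 * ((np.arange(50) - 25) / 3.0) ** 2)
        pca = self._pca_with_loading(loading)
        np.testing.assert_array_equal(loading_extrema(pca, 0), [1025])

    def test_flat_loading_empty(self):
        assert loading_extrema(self._pca_with_loading(np.ones(30)), 0).size == 0

    def test_negative_extrema_also_anchor(self):
        x = np.arange(60)
        loading = np.exp(-0.5 * ((x - 15) / 2.5) ** 2) - np.exp(-0.5 * ((x - 45) / 2.5) ** 2)
        got = loading_extrema(self._pca_with_loading(loading), 0)
        np.testing.assert_array_equal(got, [1015, 1045])


def _quant_set(values):
    """SpectrumSet whose zone quantifications are directly controllable."""
    grid = WavenumberGrid(600, 700)
    samples, spectra = [], []
    for i, (v, lab) in enumerate(values):
        samples.append(SampleMeta(f"s{i}", group_pcos=lab))
        spectra.append([Spectrum(grid, np.full(grid.n_points, v))])
    return SpectrumSet(samples, spectra)


class TestScanAndReport:
    def test_micro_case_matches_hand_computation(self):
        # two samples per group with constant spectra: quantification = value
        ds = _quant_set([(1.0, "PCOS"), (2.0, "PCOS"), (4.0, "nonPCOS"), (6.0, "nonPCOS")])
        stats, per_sample = group_difference_report(
            ds, ds.labels("pcos"), [Zone(620, 680)]
        )
        s = stats[0]
        assert (s.mean_pos, s.mean_neg) == (1.5, 5.0)
        assert s.sd_pos == pytest.approx(np.sqrt(0.5))
        t_ref, p_ref = sps.ttest_ind([1.0, 2.0], [4.0, 6.0], equal_var=False)
        assert s.t_stat == pytest.approx(t_ref) and s.p_value == pytest.approx(p_ref)
        np.testing.assert_array_equal(per_sample["620-680"], [1, 2, 4, 6])

    def test_missing_labels_excluded_with_warning(self):
        ds = _quant_set([(1.0, "PCOS"), (2.0, "PCOS"), (4.0, "nonPCOS"), (6.0, "nonPCOS"), (9.0, "NA")])
        with pytest.warns(UserWarning, match="excluding 1"):
            stats, _ = group_difference_report(ds, ds.labels("pcos"), [Zone(620, 680)])
        assert stats[0].n_pos == 2 and stats[0].n_neg == 2

    def test_scan_deterministic_and_tie_broken(self):
        # dyadic constants make every zone's quantification bitwise equal,
        # so all candidate zones tie exactly on p
        ds = _quant_set([(1.0, "PCOS"), (1.5, "PCOS"), (2.0, "nonPCOS"), (3.0, "nonPCOS")])
        anchors = np.array([600.0, 640.0, 700.0])
        # ties broken by wider zone first, then lower lo
        out1 = scan_zones(ds, ds.labels("pcos"), anchors, min_width=30, max_zones=1)
        out2 = scan_zones(ds, ds.labels("pcos"), anchors, min_width=30, max_zones=1)
        assert out1[0].zone == Zone(600, 700)
        assert out1 == out2

    def test_no_candidate_wide_enough_warns_empty(self):
        ds = _quant_set([(1.0, "PCOS"), (1.1, "PCOS"), (2.0, "nonPCOS"), (2.1, "nonPCOS")])
        with pytest.warns(UserWarning, match="min_width"):
            out = scan_zones(ds, ds.labels("pcos"), np.array([600.0, 610.0]), min_width=50)
        assert out == []

    def test_permuted_labels_rarely_reach_extreme_significance(self, small_pcos_cohort):
        """Label permutation null: the scan's top p < 0.001 in <= 5% of runs."""
        from ramanff.zones import pca_decompose, loading_extrema

        pp = small_pcos_cohort
        pca = pca_decompose(pp.intensity_matrix(), 3, pp.grid.wavenumbers)
        anchors = loading_extrema(pca, 0)
        rng = np.random.default_rng(123)
        labels = pp.labels("pcos")
        hits = 0
        n_perm = 100
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            top = scan_zones(pp, perm, anchors, max_zones=1)
            if top and top[0].p_value < 0.001:
                hits += 1
        assert hits / n_perm <= 0.05
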