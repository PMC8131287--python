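"""WHAM estimator: histograms, self-consistent solution, PMF, bootstrap."""

import numpy as np
import pytest

from reusbind.constants import KB
from reusbind.restraints import UmbrellaWindow
from reusbind.toy_system import ToySystem, sample_biased_exact
from reusbind.wham import (
    WHAM,
    HistogramSet,
    PMFProfile,
    bootstrap_uncertainty,
    build_histograms,
    check_symmetry,
    delta_g_reus,
    overlap_matrix,
    pmf_from_wham,
    solve_wham,
)

BETA = 1.0 / (KB * 298.15)


def _three_window_problem(n=3000):
    """Small exact-sampled umbrella problem used across solver tests."""
    flat = ToySystem(well_depth=2.0, well_width=1.5, axial_range=(-6.0, 6.0))
    windows = [
        UmbrellaWindow(-2.0, 1.0, 0),
        UmbrellaWindow(0.0, 1.0, 1),
        UmbrellaWindow(2.0, 1.0, 2),
    ]
    series = [
        sample_biased_exact(flat, w.energy, n, seed=500 + w.label) for w in windows
    ]
    edges = np.arange(-6.0, 6.0 + 1e-9, 0.25)
    return flat, windows, series, build_histograms(series, windows, edges)


class TestBuildHistograms:
    def test_counts_conserved_per_window(self, system, ladder):
        series = [
            sample_biased_exact(system, w.energy, 500, seed=w.label)
            for w in ladder[:4]
        ]
        edges = np.linspace(-14.0, 15.0, 100)
        hist = build_histograms(series, ladder[:4], edges)
        np.testing.assert_array_equal(hist.sample_totals, [500] * 4)
        assert np.array_equal(hist.counts.sum(axis=1), hist.sample_totals)

    def test_single_bin_concentration(self):
        w = UmbrellaWindow(0.0, 1.0)
        hist = build_histograms(
            [np.full(50, 0.05)], [w], np.array([-1.0, 0.0, 0.1, 1.0])
        )
        assert hist.counts[0, 1] == 50
        assert hist.counts[0, [0, 2]].sum() == 0

    def test_sample_outside_edges_raises(self):
        w = UmbrellaWindow(0.0, 1.0)
        with pytest.raises(ValueError):
            build_histograms([np.array([2.0])], [w], np.array([-1.0, 0.0, 1.0]))

    def test_empty_window_raises(self):
        w = UmbrellaWindow(0.0, 1.0)
        with pytest.raises(ValueError):
            build_histograms([np.array([])], [w], np.array([-1.0, 0.0, 1.0]))

    def test_disjoint_windows_flagged(self):
        ws = [UmbrellaWindow(-0.5, 1.0, 0), UmbrellaWindow(0.5, 1.0, 1)]
        hist = build_histograms(
            [np.full(10, -0.5), np.full(10, 0.5)],
            ws,
            np.array([-1.0, 0.0, 1.0]),
        )
        ov = overlap_matrix(hist)
        assert ov[0, 1] == 0.0
        with pytest.raises(ValueError, match="disconnected"):
            WHAM(hist).fit()


class TestSolveWHAM:
    def test_single_window_zero_bias_degenerate(self):
        counts = np.array([[10, 30, 60]])
        bias = np.zeros((1, 3))
        hist = HistogramSet(np.array([0.0, 1.0, 2.0, 3.0]), counts, bias)
        wfe, probs = solve_wham(hist, beta=BETA)
        assert wfe.f[0] == 0.0
        np.testing.assert_allclose(probs, [0.1, 0.3, 0.6], atol=1e-12)

    def test_duplicate_window_equals_pooled(self):
        """Splitting one window's data into two identical windows leaves the
        solution unchanged."""
        flat, windows, series, hist = _three_window_problem(n=1500)
        w_dup = windows + [UmbrellaWindow(2.0, 1.0, 3)]
        half = len(series[2]) // 2
        series_dup = series[:2] + [series[2][:half], series[2][half:]]
        edges = hist.edges
        hist_dup = build_histograms(series_dup, w_dup, edges)
        p1 = WHAM(hist).fit(tol=1e-10).probabilities
        p2 = WHAM(hist_dup).fit(tol=1e-10).probabilities
        np.testing.assert_allclose(p1, p2, atol=2e-3)

    def test_window_reordering_invariance(self):
        flat, windows, series, hist = _three_window_problem(n=1500)
        order = [2, 0, 1]
        hist_perm = build_histograms(
            [series[i] for i in order], [windows[i] for i in order], hist.edges
        )
        p1 = WHAM(hist).fit(tol=1e-10).probabilities
        p2 = WHAM(hist_perm).fit(tol=1e-10).probabilities
        np.testing.assert_allclose(p1, p2, rtol=1e-7, atol=1e-12)

    def test_gauge_f0_zero(self):
        _, _, _, hist = _three_window_problem(n=1000)
        wfe, _ = solve_wham(hist, beta=BETA)
        assert wfe.f[0] == 0.0

    def test_scf_agrees_with_direct_likelihood_minimization(self):
        """Self-consistent iteration vs BFGS minimization of the WHAM
        negative log-likelihood: all f_m agree to < 1e-6 kcal/mol."""
        _, _, _, hist = _three_window_problem(n=3000)
        f_scf = WHAM(hist).fit(tol=1e-10).f
        f_ml = WHAM(hist).fit(method="ml").f
        assert np.max(np.abs(f_scf - f_ml)) < 1e-6

    def test_nonconvergence_raises(self):
        _, _, _, hist = _three_window_problem(n=500)
        with pytest.raises(RuntimeError, match="converge"):
            WHAM(hist).fit(tol=1e-12, max_iter=3)


class TestPMF:
    def test_uniform_probabilities_flat(self):
        pmf = pmf_from_wham(np.full(5, 0.2), BETA, np.arange(5.0))
        np.testing.assert_allclose(pmf.free_energy, 0.0, atol=1e-12)

    def test_two_bin_log_identity(self):
        z = 0.4
        pmf = pmf_from_wham(
            np.array([np.exp(-1.0) * z, z]), BETA, np.array([0.0, 1.0])
        )
        # dF = kT between the two bins
        assert pmf.free_energy[0] - pmf.free_energy[1] == pytest.approx(
            1.0 / BETA
        )
        assert pmf.free_energy.min() == 0.0

    def test_empty_bins_masked(self):
        pmf = pmf_from_wham(np.array([0.5, 0.0, 0.5]), BETA, np.arange(3.0))
        assert not pmf.mask[1]
        assert np.isnan(pmf.free_energy[1])

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            pmf_from_wham(np.zeros(3), BETA, np.arange(3.0))


class TestDeltaG:
    def _flat_pmf(self):
        c = np.linspace(-10.0, 10.0, 101)
        return PMFProfile(c, np.zeros_like(c), np.ones_like(c, dtype=bool))

    def test_flat_profile_zero_both_modes(self):
        pmf = self._flat_pmf()
        for mode in ("depth", "integrated"):
            assert delta_g_reus(
                pmf, (-2, 2), (6, 10), mode=mode, beta=BETA
            ) == pytest.approx(0.0)

    def test_depth_of_single_well(self):
        c = np.linspace(-10.0, 10.0, 201)
        F = 5.0 * (1.0 - np.exp(-(c**2)))  # well depth 5 vs plateau
        pmf = PMFProfile(c, F - F.min(), np.ones_like(c, dtype=bool))
        dg = delta_g_reus(pmf, (-2, 2), [(-10, -7), (7, 10)], mode="depth")
        assert dg == pytest.approx(-5.0, abs=1e-6)

    def test_integrated_matches_quadrature(self, system):
        """Integrated-mode dG on the exact binned toy PMF equals the direct
        ratio of Boltzmann integrals."""
        from reusbind.oracles import binned_pmf_exact, delta_g_reus_quadrature

        edges = np.arange(-13.0, 14.0 + 1e-9, 0.1)
        probs, F = binned_pmf_exact(system, edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        pmf = PMFProfile(centers, F, np.ones_like(F, dtype=bool))
        dg = delta_g_reus(
            pmf, (-3, 3), [(-13, -10), (11, 14)], mode="integrated",
            beta=system.beta,
        )
        dg_quad = delta_g_reus_quadrature(
            system, (-3, 3), [(-13, -10), (11, 14)], mode="integrated"
        )
        assert dg == pytest.approx(dg_quad, abs=0.02)

    def test_empty_region_raises(self):
        pmf = self._flat_pmf()
        with pytest.raises(ValueError):
            delta_g_reus(pmf, (20.0, 30.0), (6.0, 10.0))


class TestSymmetry:
    def test_even_profile_scores_zero(self):
        c = np.linspace(-5.0, 5.0, 101)
        pmf = PMFProfile(c, c**2, np.ones_like(c, dtype=bool))
        assert check_symmetry(pmf, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_one_sided_shift(self):
        c = np.linspace(-5.0, 5.0, 101)
        F = np.where(c > 0, 1.3, 0.0)
        F[c == 0] = 0.0
        pmf = PMFProfile(c, F, np.ones_like(c, dtype=bool))
        assert check_symmetry(pmf, 0.0) == pytest.approx(1.3, rel=0.02)

    def test_one_sided_profile_raises(self):
        c = np.linspace(1.0, 5.0, 20)
        pmf = PMFProfile(c, np.zeros_like(c), np.ones_like(c, dtype=bool))
        with pytest.raises(ValueError):
            check_symmetry(pmf, 0.0)


class TestBootstrap:
    def test_single_block_resamples_are_identical(self):
        series = [np.arange(30.0)]
        stderr, vals = bootstrap_uncertainty(
            series, lambda s: float(np.mean(s[0])), n_boot=2, block=30, seed=0
        )
        assert stderr == 0.0

    def test_gaussian_mean_stderr_matches_closed_form(self, rng):
        n = 2000
        series = [rng.normal(0.0, 1.0, n)]
        stderr, _ = bootstrap_uncertainty(
            series, lambda s: float(np.mean(s[0])), n_boot=60, block=1, seed=1
        )
        assert stderr == pytest.approx(1.0 / np.sqrt(n), rel=0.30)

    def test_sqrt_n_scaling(self, rng):
        base = rng.normal(0.0, 1.0, 8000)
        small, _ = bootstrap_uncertainty(
            [base[:2000]], lambda s: float(np.mean(s[0])), n_boot=60, block=10,
            seed=2,
        )
        large, _ = bootstrap_uncertainty(
            [base], lambda s: float(np.mean(s[0])), n_boot=60, block=10, seed=3
        )
        assert small / large == pytest.approx(2.0, rel=0.5)

    def test_block_longer_than_series_raises(self):
        with pytest.raises(ValueError):
            bootstrap_uncertainty(
                [np.arange(10.0)], lambda s: 0.0, n_boot=2, block=11
            )
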