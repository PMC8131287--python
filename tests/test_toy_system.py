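"""Toy-system potential, Langevin sampler and exact-sampling oracle."""

import numpy as np
import pytest
from scipy import stats

from reusbind.constants import KCAL_PER_MOL_AKMA
from reusbind.restraints import UmbrellaWindow, umbrella_bias
from reusbind.toy_system import (
    ToySystem,
    TrajectorySamples,
    analytic_pmf,
    biased_axial_density,
    generate_unbound_positions,
    read_trajectory,
    sample_biased_exact,
    simulate_trajectory,
    write_trajectory,
)


class TestAnalyticPMF:
    def test_anchoring_and_plateau(self, system):
        # bound pose anchored at zero; far plateau reads the well depth
        assert analytic_pmf(system, 0.0) == pytest.approx(0.0)
        assert analytic_pmf(system, 12.0) == pytest.approx(
            system.well_depth, abs=1e-6
        )

    def test_out_of_range_raises(self, system):
        with pytest.raises(ValueError):
            analytic_pmf(system, 15.0)
        with pytest.raises(ValueError):
            analytic_pmf(system, -13.5)

    def test_matches_2d_quadrature_marginal(self, system):
        """Separable potential: the marginal -kT ln density from full (z, r)
        quadrature equals the analytic axial PMF up to a constant."""
        z = np.linspace(-12.0, 13.0, 41)
        r = np.linspace(0.0, 25.0, 4001)
        radial = np.exp(-system.beta * system.radial_stiffness * r**2) * r
        radial_integral = np.trapezoid(radial, r) * 2 * np.pi
        dens = np.exp(-system.beta * system.axial_potential(z)) * radial_integral
        pmf_quad = -system.kbt * np.log(dens)
        pmf_quad -= pmf_quad.min()
        expected = analytic_pmf(system, z)
        assert np.max(np.abs(pmf_quad - (expected - expected.min()))) < 1e-6


class TestLangevinSampler:
    def test_harmonic_variance_matches_gaussian(self):
        """Pure harmonic axial bias a*z^2: Var(z) = kT/(2a) within 3 SE."""
        flat = ToySystem(well_depth=0.0)
        a = 2.0
        traj = simulate_trajectory(
            flat,
            umbrella_bias(0.0, a),
            n_steps=400_000,
            seed=42,
            sample_stride=100,
        )
        var_expected = flat.kbt / (2 * a)
        n_eff = len(traj.zeta)  # stride 100 x dt 0.002 = 0.2 ps apart
        # variance-of-variance for correlated samples: inflate SE by 3x margin
        se = var_expected * np.sqrt(2.0 / n_eff) * 3.0
        assert abs(np.var(traj.zeta) - var_expected) < 3 * se

    def test_equipartition_free_particle(self):
        """No potential: mean kinetic energy per dof = kT/2 within 3 SE."""
        free = ToySystem(
            well_depth=0.0, radial_stiffness=0.0, wall_stiffness=0.0
        )
        traj = simulate_trajectory(free, None, n_steps=100_000, seed=7,
                                   sample_stride=50)
        ke_dof = 0.5 * free.mass * traj.velocities**2 / KCAL_PER_MOL_AKMA
        mean_ke = ke_dof.mean()
        target = 0.5 * free.kbt
        se = ke_dof.std() / np.sqrt(ke_dof.size / 3)  # conservative n_eff
        assert abs(mean_ke - target) < 3 * se

    def test_seed_determinism(self, system):
        w = umbrella_bias(1.0, 2.0)
        a = simulate_trajectory(system, w, n_steps=2000, seed=9)
        b = simulate_trajectory(system, w, n_steps=2000, seed=9)
        assert np.array_equal(a.zeta, b.zeta)
        assert np.array_equal(a.velocities, b.velocities)
        c = simulate_trajectory(system, w, n_steps=2000, seed=10)
        assert not np.array_equal(a.zeta, c.zeta)

    def test_step_size_too_large_raises(self, system):
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError):
                simulate_trajectory(system, None, n_steps=2000, dt=50.0, seed=0)

    def test_distribution_matches_exact_density(self, system):
        """Boltzmann consistency: thinned Langevin zeta samples pass a KS
        test against the exact biased marginal the oracle sampler uses."""
        w = UmbrellaWindow(center=-2.0, stiffness=1.385)
        traj = simulate_trajectory(
            system,
            umbrella_bias(w.center, w.stiffness),
            n_steps=300_000,
            seed=3,
            sample_stride=600,  # ~1.2 ps apart: decorrelated
            x0=np.array([0.0, 0.0, -2.0]),
        )
        grid, dens = biased_axial_density(system, w.energy)
        cdf_grid = np.concatenate(
            [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))]
        )
        cdf_grid /= cdf_grid[-1]
        res = stats.kstest(traj.zeta, lambda x: np.interp(x, grid, cdf_grid))
        assert res.pvalue > 0.01


class TestExactSampler:
    def test_gaussian_moments_flat_landscape(self):
        """Zero potential + umbrella k(z-d)^2: mean d, variance kT/(2k)."""
        flat = ToySystem(well_depth=0.0)
        k, d = 2.5, 3.0
        z = sample_biased_exact(flat, lambda x: k * (x - d) ** 2, 200_000, seed=5)
        assert np.mean(z) == pytest.approx(d, abs=0.01)
        assert np.var(z) == pytest.approx(flat.kbt / (2 * k), rel=0.02)

    def test_single_draw_inside_support(self, system):
        z = sample_biased_exact(system, None, 1, seed=0)
        lo, hi = system.axial_range
        assert z.shape == (1,) and lo <= z[0] <= hi

    def test_chisquare_against_grid_density(self, system):
        """Histogram of draws from the two-sided well matches the grid
        density (chi-square, alpha = 0.01)."""
        n = 50_000
        z = sample_biased_exact(system, None, n, seed=12)
        grid, dens = biased_axial_density(system, None)
        edges = np.linspace(*system.axial_range, 41)
        counts, _ = np.histogram(z, bins=edges)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))]
        )
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, grid, cdf))
        keep = probs * n >= 5  # merge-less: drop near-empty tail bins
        res = stats.chisquare(
            counts[keep], probs[keep] / probs[keep].sum() * counts[keep].sum()
        )
        assert res.pvalue > 0.01

    def test_invalid_n(self, system):
        with pytest.raises(ValueError):
            sample_biased_exact(system, None, 0, seed=0)


class TestUnboundPositions:
    def test_uniform_annulus_extents(self):
        pos = generate_unbound_positions(2.0, 4.0, 10.0, 50_000, seed=2)
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert r.min() > 2.0 - 1e-9 and r.max() < 4.0 + 1e-9
        assert pos[:, 2].min() >= 0.0 and pos[:, 2].max() <= 10.0
        # uniform in area: mean r^2 = (r_lo^2 + r_hi^2)/2
        assert np.mean(r**2) == pytest.approx((4.0 + 16.0) / 2, rel=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_unbound_positions(4.0, 2.0, 10.0, 10)
        with pytest.raises(ValueError):
            generate_unbound_positions(0.0, 2.0, 10.0, 0)


def test_trajectory_text_roundtrip(tmp_path, system):
    traj = simulate_trajectory(system, None, n_steps=500, seed=1, sample_stride=50)
    path = tmp_path / "traj.dat"
    write_trajectory(path, traj, header="test run")
    back = read_trajectory(path)
    assert np.array_equal(back.step, traj.step)
    assert np.all(np.diff(back.step) > 0)
    np.testing.assert_allclose(back.zeta, traj.zeta, rtol=1e-6)
    np.testing.assert_allclose(back.bias_energy, traj.bias_energy, atol=1e-6)
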