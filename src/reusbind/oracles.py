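"""Exact (quadrature) reference values for the toy system.

Everything the stochastic pipeline estimates has an exact counterpart on the
toy potential: the marginal PMF is known analytically, the region-integrated
pulling free energy follows from 1-D Boltzmann integrals, and the
restraint-on TI leg from a ratio of partition functions
(:func:`reusbind.corrections.ti_restraint_on_quadrature`).  The assembled
binding free-energy oracle prices the volume term at the *measured* V_eff:
the Eq.-style effective volume is by construction an extremum statistic of
the finite unbound sample (the underlying radial density has unbounded
support), so it has no sample-size-independent true value; holding it fixed
isolates the stochastic estimators (WHAM, TI) against exact integrals.
"""

from __future__ import annotations

import numpy as np

from .corrections import (
    restraint_off_correction,
    ti_restraint_on_quadrature,
)
from .restraints import UmbrellaWindow
from .toy_system import ToySystem

__all__ = [
    "pmf_quadrature",
    "binned_pmf_exact",
    "delta_g_reus_quadrature",
    "binding_free_energy_quadrature",
]


def pmf_quadrature(
    system: ToySystem, z_grid: np.ndarray, n_radial: int = 2001, r_max: float = 30.0
) -> np.ndarray:
    """Marginal PMF by honest 2-D quadrature over (z, r), min-anchored.

    Integrates the full Boltzmann density exp(-beta [U_ax(z) + U_rad(r)])
    with the cylindrical measure 2 pi r dr at every z; separability makes
    this equal to the analytic axial PMF up to the anchoring constant, which
    is what the oracle is for.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    r = np.linspace(0.0, r_max, n_radial)
    radial = np.exp(-system.beta * system.radial_stiffness * r**2) * 2.0 * np.pi * r
    radial_integral = np.trapezoid(radial, r)
    dens = np.exp(-system.beta * system.axial_potential(z_grid)) * radial_integral
    pmf = -system.kbt * np.log(dens)
    return pmf - pmf.min()


def binned_pmf_exact(system: ToySystem, edges: np.ndarray, oversample: int = 32):
    """Exact bin-integrated probabilities and PMF on WHAM's bin grid.

    Returns (probabilities, free_energy) with the same binning the WHAM
    route uses, so comparisons isolate statistical error from binning.
    """
    edges = np.asarray(edges, dtype=float)
    probs = np.empty(len(edges) - 1)
    for b in range(len(edges) - 1):
        z = np.linspace(edges[b], edges[b + 1], oversample)
        probs[b] = np.trapezoid(
            np.exp(-system.beta * system.axial_potential(z)), z
        )
    probs /= probs.sum()
    F = -system.kbt * np.log(probs)
    return probs, F - F.min()


def delta_g_reus_quadrature(
    system: ToySystem,
    bound_region: tuple[float, float],
    unbound_region,
    mode: str = "integrated",
    n_points: int = 20001,
) -> float:
    """Exact pulling free energy by 1-D quadrature over the axial density.

    integrated: -kT ln[ <e^{-beta F}>_bound / <e^{-beta F}>_unbound ] with
    uniform averages over the regions (ratio of Boltzmann integrals divided
    by region lengths); depth: PMF minimum in the bound region minus the
    mean PMF over the unbound region(s).
    """
    regions = (
        [unbound_region]
        if isinstance(unbound_region[0], (int, float))
        else list(unbound_region)
    )

    def region_grid(lo, hi):
        return np.linspace(lo, hi, n_points)

    zb = region_grid(*bound_region)
    fb = system.axial_potential(zb) + system.well_depth
    if mode == "integrated":
        num = np.trapezoid(np.exp(-system.beta * fb), zb) / (zb[-1] - zb[0])
        den_terms = []
        length = 0.0
        for lo, hi in regions:
            zu = region_grid(lo, hi)
            fu = system.axial_potential(zu) + system.well_depth
            den_terms.append(np.trapezoid(np.exp(-system.beta * fu), zu))
            length += hi - lo
        den = sum(den_terms) / length
        return float(-system.kbt * np.log(num / den))
    if mode == "depth":
        means = []
        for lo, hi in regions:
            zu = region_grid(lo, hi)
            fu = system.axial_potential(zu) + system.well_depth
            means.append(np.trapezoid(fu, zu) / (hi - lo))
        return float(fb.min() - np.mean(means))
    raise ValueError(f"unknown mode {mode!r}")


def binding_free_energy_quadrature(
    system: ToySystem,
    bound_region: tuple[float, float],
    unbound_region,
    v_eff: float,
    bound_restraint: UmbrellaWindow,
    mode: str = "integrated",
) -> float:
    """Exact assembled dG_bind for the toy cycle at the measured V_eff.

    Sum of the quadrature pulling free energy, the volume correction at
    ``v_eff``, and the exact restraint-on free energy; the oracle the full
    stochastic pipeline (REUS -> WHAM -> corrections) must reproduce within
    its bootstrap error.
    """
    dg_reus = delta_g_reus_quadrature(system, bound_region, unbound_region, mode)
    dg_off = restraint_off_correction(v_eff, system.temperature)
    dg_on = ti_restraint_on_quadrature(system, bound_restraint)
    return dg_reus + dg_off + dg_on
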