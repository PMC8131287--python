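"""Analytically solvable stand-in for a solvated host-guest system.

The "guest" is a point particle of mass ~100 amu moving in a separable
cylindrical binding potential

    U(x, y, z) = U_ax(z) + U_rad(x, y)

with a single Gaussian binding well on the axis,

    U_ax(z)  = -well_depth * exp(-z^2 / (2 well_width^2)) + soft walls,
    U_rad    = radial_stiffness * (x^2 + y^2),

so the marginal potential of mean force along the axial reaction coordinate
zeta = z is known in closed form (separability makes the radial Boltzmann
integral a z-independent constant).  The well bottom at z = 0 plays the role
of the bound pose inside the host cavity; the flat region |z| >> well_width
plays the role of the unbound guest still confined laterally by the
cylindrical restraint.

Sampling is provided by two independent routes:

* :func:`simulate_trajectory` -- underdamped Langevin dynamics (BAOAB
  splitting with an exact Ornstein-Uhlenbeck friction substep), the same
  propagator class as the MD engine it stands in for;
* :func:`sample_biased_exact` -- i.i.d. draws from the exact 1-D biased
  marginal density by inverse-CDF on a fine grid, used as the oracle that the
  dynamics and the WHAM machinery are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import KB, KCAL_PER_MOL_AKMA, T_DEFAULT

__all__ = [
    "ToySystem",
    "ParticleState",
    "TrajectorySamples",
    "analytic_pmf",
    "simulate_trajectory",
    "sample_biased_exact",
    "generate_unbound_positions",
    "write_trajectory",
    "read_trajectory",
]

BiasTerm = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class ToySystem:
    """Separable cylindrical binding potential with analytic marginal PMF.

    Parameters
    ----------
    well_depth : float
        Depth of the axial Gaussian binding well, kcal/mol (> 0 binds).
    well_width : float
        Gaussian width of the well, A.
    axial_range : (float, float)
        Axial span covered by the reaction coordinate, A; soft harmonic walls
        act outside this interval.
    radial_stiffness : float
        Harmonic confinement perpendicular to the axis, kcal/mol/A^2.
    temperature : float
        Target temperature, K.
    mass : float
        Particle mass, amu (guest-sized by default).
    wall_stiffness : float
        Stiffness of the soft axial walls, kcal/mol/A^2.
    """

    well_depth: float = 5.0
    well_width: float = 1.0
    axial_range: tuple[float, float] = (-13.0, 14.0)
    radial_stiffness: float = 1.0
    temperature: float = T_DEFAULT
    mass: float = 100.0
    wall_stiffness: float = 10.0
    kB: float = field(default=KB)

    def __post_init__(self) -> None:
        if self.well_depth < 0:
            raise ValueError("well_depth must be >= 0")
        if self.well_width <= 0:
            raise ValueError("well_width must be > 0")
        lo, hi = self.axial_range
        if not lo < 0.0 < hi:
            raise ValueError("axial_range must bracket the bound pose z = 0")
        if self.temperature <= 0 or self.mass <= 0:
            raise ValueError("temperature and mass must be > 0")

    # -- thermodynamics -------------------------------------------------
    @property
    def kbt(self) -> float:
        return self.kB * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kbt

    # -- potential terms ------------------------------------------------
    def axial_potential(self, z):
        """U_ax(z), kcal/mol (well + soft walls), vectorized."""
        z = np.asarray(z, dtype=float)
        lo, hi = self.axial_range
        u = -self.well_depth * np.exp(-(z**2) / (2.0 * self.well_width**2))
        u = u + np.where(z > hi, self.wall_stiffness * (z - hi) ** 2, 0.0)
        u = u + np.where(z < lo, self.wall_stiffness * (z - lo) ** 2, 0.0)
        return u

    def axial_force(self, z):
        """-dU_ax/dz, kcal/mol/A."""
        z = np.asarray(z, dtype=float)
        lo, hi = self.axial_range
        f = -self.well_depth * z / self.well_width**2 * np.exp(
            -(z**2) / (2.0 * self.well_width**2)
        )
        f = f - np.where(z > hi, 2.0 * self.wall_stiffness * (z - hi), 0.0)
        f = f - np.where(z < lo, 2.0 * self.wall_stiffness * (z - lo), 0.0)
        return f

    def potential(self, x: np.ndarray) -> np.ndarray:
        """Total potential at positions ``x`` of shape (n, 3), kcal/mol."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.axial_potential(x[:, 2]) + self.radial_stiffness * (
            x[:, 0] ** 2 + x[:, 1] ** 2
        )

    def force(self, x: np.ndarray) -> np.ndarray:
        """Total force at positions ``x`` of shape (n, 3), kcal/mol/A."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        f = np.empty_like(x)
        f[:, 0] = -2.0 * self.radial_stiffness * x[:, 0]
        f[:, 1] = -2.0 * self.radial_stiffness * x[:, 1]
        f[:, 2] = self.axial_force(x[:, 2])
        return f

    def maxwell_velocities(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Maxwell-Boltzmann velocities, A/ps, shape (n, 3)."""
        sigma = np.sqrt(self.kbt * KCAL_PER_MOL_AKMA / self.mass)
        return rng.normal(0.0, sigma, size=(n, 3))


@dataclass
class ParticleState:
    """Generalized coordinates and momenta of the single-particle guest."""

    position: np.ndarray  # (3,), A
    momentum: np.ndarray  # (3,), amu*A/ps

    def kinetic_energy(self, mass: float) -> float:
        """K(p) = |p|^2 / (2m), kcal/mol; never negative."""
        p = np.asarray(self.momentum, dtype=float)
        return float(p @ p) / (2.0 * mass) / KCAL_PER_MOL_AKMA


@dataclass
class TrajectorySamples:
    """Structure-of-arrays trajectory record.

    ``step`` is strictly increasing; ``zeta`` is the axial reaction
    coordinate (A), ``radial`` the perpendicular distance from the axis (A),
    ``bias_energy`` the total bias energy at the sample (kcal/mol).
    Positions/velocities are retained for restart and diagnostics.
    """

    step: np.ndarray
    zeta: np.ndarray
    radial: np.ndarray
    bias_energy: np.ndarray
    positions: np.ndarray | None = None
    velocities: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.step)


def analytic_pmf(system: ToySystem, z):
    """Exact marginal PMF along the reaction coordinate, anchored to 0.

    Because the potential is separable the marginal free energy along z is
    U_ax(z) plus a constant; the constant is fixed so the global minimum
    (the bound pose at z = 0) sits at zero, hence the unbound plateau reads
    ``well_depth``.

    Raises
    ------
    ValueError
        If any ``z`` lies outside ``system.axial_range``.
    """
    z = np.asarray(z, dtype=float)
    lo, hi = system.axial_range
    if np.any(z < lo) or np.any(z > hi):
        raise ValueError(f"z outside axial_range [{lo}, {hi}]")
    out = system.axial_potential(z) + system.well_depth
    return out if out.ndim else float(out)


def _combine_bias(bias: Sequence[BiasTerm] | BiasTerm | None) -> list[BiasTerm]:
    if bias is None:
        return []
    if callable(bias):
        return [bias]
    return list(bias)


def _propagate(
    system: ToySystem,
    x: np.ndarray,
    v: np.ndarray,
    bias_terms: list[BiasTerm],
    n_steps: int,
    dt: float,
    friction: float,
    rng: np.random.Generator,
    record_stride: int = 0,
):
    """BAOAB Langevin propagation of an ensemble of independent walkers.

    ``x``/``v`` have shape (n, 3) and are updated in place over ``n_steps``.
    The O-substep uses the exact Ornstein-Uhlenbeck update, so the scheme is
    stable for any friction and samples configurations with O(dt^2) bias.
    Returns recorded (steps, positions, velocities, bias_energy) when
    ``record_stride`` > 0, else ``None``; recording happens every
    ``record_stride`` steps, starting at step ``record_stride``.
    """
    if dt <= 0 or friction <= 0:
        raise ValueError("dt and friction must be > 0")
    m = system.mass
    c1 = np.exp(-friction * dt)
    sigma_v = np.sqrt(system.kbt * KCAL_PER_MOL_AKMA / m * (1.0 - c1**2))
    scale = KCAL_PER_MOL_AKMA / m  # force (kcal/mol/A) -> acceleration (A/ps^2)

    def total_force(pos):
        f = system.force(pos)
        e_bias = np.zeros(pos.shape[0])
        for term in bias_terms:
            e_t, f_t = term(pos)
            e_bias += e_t
            f += f_t
        return f, e_bias

    f, e_bias = total_force(x)
    rec_steps, rec_x, rec_v, rec_e = [], [], [], []
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * scale * f
        x += 0.5 * dt * v
        v *= c1
        v += sigma_v * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        f, e_bias = total_force(x)
        v += 0.5 * dt * scale * f
        if record_stride and step % record_stride == 0:
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    "non-finite coordinates encountered (step size too large?)"
                )
            rec_steps.append(step)
            rec_x.append(x.copy())
            rec_v.append(v.copy())
            rec_e.append(e_bias.copy())
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite coordinates encountered")
    if record_stride:
        return (
            np.array(rec_steps),
            np.array(rec_x),
            np.array(rec_v),
            np.array(rec_e),
        )
    return None


def simulate_trajectory(
    system: ToySystem,
    bias: Sequence[BiasTerm] | BiasTerm | None,
    n_steps: int,
    dt: float = 0.002,
    friction: float = 1.0,
    seed: int = 0,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    sample_stride: int = 10,
) -> TrajectorySamples:
    """Langevin trajectory of the biased toy system.

    Samples the Boltzmann density of ``U + bias`` at ``system.temperature``
    in the long-time limit; deterministic for a given ``seed``.  ``bias`` is
    ``None``, one callable, or a sequence of callables mapping positions
    (n, 3) to (energy (n,), force (n, 3)) -- see :mod:`reusbind.restraints`
    for umbrella and cylindrical bias factories.
    """
    rng = np.random.default_rng(seed)
    terms = _combine_bias(bias)
    x = np.zeros((1, 3)) if x0 is None else np.atleast_2d(np.asarray(x0, float)).copy()
    v = system.maxwell_velocities(1, rng) if v0 is None else np.atleast_2d(
        np.asarray(v0, float)
    ).copy()
    steps, xs, vs, es = _propagate(
        system, x, v, terms, n_steps, dt, friction, rng, record_stride=sample_stride
    )
    pos = xs[:, 0, :]
    return TrajectorySamples(
        step=steps,
        zeta=pos[:, 2].copy(),
        radial=np.hypot(pos[:, 0], pos[:, 1]),
        bias_energy=es[:, 0].copy(),
        positions=pos,
        velocities=vs[:, 0, :],
    )


def biased_axial_density(
    system: ToySystem,
    bias_z: Callable[[np.ndarray], np.ndarray] | None,
    grid_points: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D biased marginal density on a uniform grid over axial_range.

    Returns (grid, density) with the density normalized to integrate to one
    by the trapezoid rule.  ``bias_z`` maps zeta -> bias energy (kcal/mol).
    """
    lo, hi = system.axial_range
    grid = np.linspace(lo, hi, grid_points)
    energy = system.axial_potential(grid)
    if bias_z is not None:
        energy = energy + np.asarray(bias_z(grid), dtype=float)
    energy = energy - energy.min()
    dens = np.exp(-system.beta * energy)
    norm = np.trapezoid(dens, grid)
    if not np.isfinite(norm) or norm <= 0.0:
        raise ValueError("density normalization failed (underflow everywhere)")
    return grid, dens / norm


def sample_biased_exact(
    system: ToySystem,
    bias_z: Callable[[np.ndarray], np.ndarray] | None,
    n: int,
    seed: int = 0,
    grid_points: int = 4096,
) -> np.ndarray:
    """I.i.d. draws of zeta from the exact biased marginal density.

    Inverse-CDF sampling by linear interpolation on a ``grid_points`` grid;
    the independent oracle against which the Langevin sampler and WHAM are
    checked.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    grid, dens = biased_axial_density(system, bias_z, grid_points)
    mids = 0.5 * (dens[1:] + dens[:-1]) * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(mids)])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def generate_unbound_positions(
    r_lo: float, r_hi: float, h: float, n: int, seed: int = 0
) -> np.ndarray:
    """Uniform positions inside an annular cylinder (axis = z).

    Radii in [r_lo, r_hi], axial extent [0, h].  Fixture for the effective
    volume estimator, whose uniform-annulus limit is pi (r_hi^2 - r_lo^2) h.
    """
    if not 0 <= r_lo < r_hi:
        raise ValueError("need 0 <= r_lo < r_hi")
    if h <= 0:
        raise ValueError("h must be > 0")
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.uniform(r_lo**2, r_hi**2, n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    z = rng.uniform(0.0, h, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


# -- trajectory text format --------------------------------------------

def write_trajectory(path, samples: TrajectorySamples, header: str = "") -> None:
    """Whitespace-delimited text: step, zeta(A), radial(A), bias(kcal/mol)."""
    data = np.column_stack(
        [samples.step, samples.zeta, samples.radial, samples.bias_energy]
    )
    lines = ["# " + h for h in header.splitlines() if h]
    lines.append("# step zeta_A radial_A bias_kcal_per_mol")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, data, fmt="%d %.8g %.8g %.8g")


def read_trajectory(path) -> TrajectorySamples:
    data = np.atleast_2d(np.loadtxt(path, comments="#"))
    return TrajectorySamples(
        step=data[:, 0].astype(int),
        zeta=data[:, 1],
        radial=data[:, 2],
        bias_energy=data[:, 3],
    )
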