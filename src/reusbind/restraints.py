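"""Reaction coordinate, umbrella potentials and confinement restraints.

Conventions follow the CHARMM umbrella form without the 1/2 factor,

    V_m(zeta) = k_m (zeta - d_m)^2,

and a flat-bottom cylindrical restraint that is exactly zero within a radius
r0 of the host axis and grows harmonically outside -- it confines the guest
laterally without exerting any force inside the cylinder.  The reaction
coordinate zeta is the *signed* projection onto the host axis of the vector
from the portal-oxygen reference COM to the guest COM (signedness is required
for window centers on both sides of the host, e.g. -13 ... +14 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .toy_system import ToySystem, TrajectorySamples, _propagate

__all__ = [
    "UmbrellaWindow",
    "CylindricalRestraint",
    "ReactionCoordinateSpec",
    "umbrella_energy",
    "cylindrical_energy",
    "compute_reaction_coordinate",
    "build_window_ladder",
    "steered_pull",
    "assign_snapshots_to_ladder",
    "umbrella_bias",
    "cylindrical_bias",
]

#: Default umbrella stiffness, kcal/mol/A^2.  Calibrated a priori with
#: :func:`reusbind.reus.predict_exchange_acceptance` so that the default
#: 32-window ladder on the default toy system attains the 20-30% neighbor
#: exchange acceptance observed for well-tuned window ladders.
DEFAULT_UMBRELLA_STIFFNESS = 1.385


@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic umbrella: center ``d_m`` (A), stiffness ``k_m``
    (kcal/mol/A^2, no 1/2 factor), integer label ``m``."""

    center: float
    stiffness: float
    label: int = 0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("umbrella stiffness must be > 0")

    def energy(self, zeta):
        return umbrella_energy(self, zeta)


def umbrella_energy(window: UmbrellaWindow, zeta):
    """V_m(zeta) = k_m (zeta - d_m)^2, kcal/mol (vectorized in zeta)."""
    zeta = np.asarray(zeta, dtype=float)
    out = window.stiffness * (zeta - window.center) ** 2
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CylindricalRestraint:
    """Flat-bottom cylinder about ``axis`` through ``origin``.

    Zero energy for perpendicular distance rho <= radius; outside,
    stiffness * (rho - radius)^2.  Defaults are the production values
    (7.5 A, 5 kcal/mol/A^2).
    """

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 7.5
    stiffness: float = 5.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.stiffness < 0:
            raise ValueError("stiffness must be >= 0")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if not np.isclose(n, 1.0):
            object.__setattr__(self, "axis", tuple(a / n))

    def perpendicular_distance(self, position) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(position, dtype=float))
        a = np.asarray(self.axis)
        rel = pos - np.asarray(self.origin)
        along = rel @ a
        perp = rel - np.outer(along, a)
        return np.linalg.norm(perp, axis=1)

    def energy(self, position):
        return cylindrical_energy(self, position)


def cylindrical_energy(restraint: CylindricalRestraint, position):
    """Flat-bottom restraint energy at ``position`` (vectorized), kcal/mol."""
    rho = restraint.perpendicular_distance(position)
    exc = np.maximum(rho - restraint.radius, 0.0)
    out = restraint.stiffness * exc**2
    return float(out[0]) if np.asarray(position).ndim == 1 else out


@dataclass(frozen=True)
class ReactionCoordinateSpec:
    """COM-to-COM axial projection defining zeta.

    ``guest_selection`` indexes the guest heavy atoms, ``reference_selection``
    the portal (carbonyl-oxygen) reference atoms; ``axis`` is the host
    principal axis (normalized on construction).
    """

    guest_selection: tuple[int, ...]
    reference_selection: tuple[int, ...]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not self.guest_selection or not self.reference_selection:
            raise ValueError("selections must be non-empty")
        if set(self.guest_selection) & set(self.reference_selection):
            raise ValueError("selections must be disjoint")
        a = np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "axis", tuple(a / np.linalg.norm(a)))


def _com(coordinates: np.ndarray, masses: np.ndarray, idx) -> np.ndarray:
    idx = list(idx)
    m = masses[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass in selection")
    return (coordinates[idx] * m[:, None]).sum(axis=0) / total


def compute_reaction_coordinate(
    spec: ReactionCoordinateSpec, coordinates, masses
) -> float:
    """Signed projection of (COM_guest - COM_reference) on the axis, A."""
    coords = np.asarray(coordinates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.shape[0] <= max(max(spec.guest_selection), max(spec.reference_selection)):
        raise ValueError("coordinates do not cover the selections")
    rel = _com(coords, masses, spec.guest_selection) - _com(
        coords, masses, spec.reference_selection
    )
    return float(rel @ np.asarray(spec.axis))


def build_window_ladder(
    span: tuple[float, float] = (-13.0, 14.0),
    n_windows: int = 32,
    dense_region: tuple[float, float] | None = (-3.0, 3.0),
    dense_spacing: float = 0.5,
    stiffness: float | Sequence[float] = DEFAULT_UMBRELLA_STIFFNESS,
) -> list[UmbrellaWindow]:
    """Window ladder covering ``span`` with a densified bound region.

    The dense region is tiled at exactly ``dense_spacing``; the remaining
    windows are split between the two flanks proportionally to flank length
    (rounded symmetrically) and spread uniformly, with the first and last
    centers pinned to the span endpoints.  Labels are 0..n-1 in order of
    increasing center.
    """
    lo, hi = span
    if hi <= lo:
        raise ValueError("span must be increasing")
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if dense_region is None:
        centers = np.linspace(lo, hi, n_windows)
    else:
        dlo, dhi = dense_region
        if not (lo <= dlo < dhi <= hi):
            raise ValueError("dense_region must lie inside span")
        n_dense_intervals = int(round((dhi - dlo) / dense_spacing))
        dense = dlo + dense_spacing * np.arange(n_dense_intervals + 1)
        if abs(dense[-1] - dhi) > 1e-9:
            raise ValueError("dense_region length must be a multiple of dense_spacing")
        remaining = n_windows - len(dense)
        left_len = dlo - lo
        right_len = hi - dhi
        if remaining < (left_len > 0) + (right_len > 0):
            raise ValueError(
                f"n_windows={n_windows} infeasible: dense region already uses "
                f"{len(dense)} windows"
            )
        n_left = int(round(remaining * left_len / (left_len + right_len)))
        n_right = remaining - n_left
        left = np.linspace(lo, dlo, n_left + 1)[:-1] if n_left else np.empty(0)
        right = np.linspace(dhi, hi, n_right + 1)[1:] if n_right else np.empty(0)
        centers = np.concatenate([left, dense, right])
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers are not strictly increasing")
    ks = np.broadcast_to(np.asarray(stiffness, dtype=float), centers.shape)
    return [
        UmbrellaWindow(center=float(c), stiffness=float(k), label=i)
        for i, (c, k) in enumerate(zip(centers, ks))
    ]


# -- bias factories for the Langevin propagator ------------------------

def umbrella_bias(centers, stiffness, lam=1.0):
    """Bias term applying per-walker umbrellas to the axial coordinate.

    ``centers``/``stiffness``/``lam`` broadcast against the walker axis, so a
    single callable can drive one walker per umbrella window (REUS) or per
    coupling value (TI).
    """
    centers = np.asarray(centers, dtype=float)
    stiffness = np.asarray(stiffness, dtype=float)
    lam = np.asarray(lam, dtype=float)

    def term(x: np.ndarray):
        dz = x[:, 2] - centers
        e = lam * stiffness * dz**2
        f = np.zeros_like(x)
        f[:, 2] = -2.0 * lam * stiffness * dz
        return e, f

    return term


def cylindrical_bias(restraint: CylindricalRestraint):
    """Bias term for the flat-bottom cylindrical restraint (axis = z only)."""
    if tuple(restraint.axis) != (0.0, 0.0, 1.0):
        raise NotImplementedError("dynamics bias supports the z axis only")
    ox, oy = restraint.origin[0], restraint.origin[1]

    def term(x: np.ndarray):
        dx = x[:, 0] - ox
        dy = x[:, 1] - oy
        rho = np.hypot(dx, dy)
        exc = np.maximum(rho - restraint.radius, 0.0)
        e = restraint.stiffness * exc**2
        f = np.zeros_like(x)
        with np.errstate(invalid="ignore", divide="ignore"):
            coef = np.where(rho > 0, -2.0 * restraint.stiffness * exc / rho, 0.0)
        f[:, 0] = coef * dx
        f[:, 1] = coef * dy
        return e, f

    return term


# -- steered pulling for initial configurations ------------------------

@dataclass
class PullSnapshot:
    zeta: float
    position: np.ndarray
    velocity: np.ndarray


def steered_pull(
    system: ToySystem,
    start: float = -13.0,
    end: float = 14.0,
    stiffness: float = 5.0,
    n_steps: int = 20000,
    dt: float = 0.002,
    friction: float = 1.0,
    seed: int = 0,
    cylindrical: CylindricalRestraint | None = None,
    record_stride: int = 20,
) -> list[PullSnapshot]:
    """Drag a harmonic restraint linearly from ``start`` to ``end``.

    Returns snapshots (zeta, position, velocity) recorded every
    ``record_stride`` steps, from which per-window initial configurations are
    picked by :func:`assign_snapshots_to_ladder`.
    """
    if start == end:
        raise ValueError("start and end must differ")
    rng = np.random.default_rng(seed)
    x = np.array([[0.0, 0.0, float(start)]])
    v = system.maxwell_velocities(1, rng)
    extra = [cylindrical_bias(cylindrical)] if cylindrical is not None else []
    snapshots: list[PullSnapshot] = []
    # moving restraint: re-anchor the umbrella center each segment
    n_segments = n_steps // record_stride
    for seg in range(1, n_segments + 1):
        frac = seg / n_segments
        center = start + (end - start) * frac
        bias = [umbrella_bias(center, stiffness)] + extra
        _propagate(system, x, v, bias, record_stride, dt, friction, rng)
        snapshots.append(
            PullSnapshot(zeta=float(x[0, 2]), position=x[0].copy(), velocity=v[0].copy())
        )
    return snapshots


def assign_snapshots_to_ladder(
    snapshots: Sequence[PullSnapshot], ladder: Sequence[UmbrellaWindow]
) -> list[PullSnapshot]:
    """Nearest-zeta snapshot for each window center, in ladder order."""
    zetas = np.array([s.zeta for s in snapshots])
    return [snapshots[int(np.argmin(np.abs(zetas - w.center)))] for w in ladder]
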