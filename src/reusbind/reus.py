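"""Replica-exchange umbrella sampling on the toy system.

M replicas run Langevin dynamics in parallel, each under one umbrella window
of the ladder plus the cylindrical restraint.  Every ``steps_per_cycle``
steps, neighboring windows (m, m+1) attempt to exchange their umbrella
potentials via the Metropolis criterion

    accept with prob. min(1, e^{-Delta}),
    Delta = beta [V_m(zeta_j) - V_m(zeta_i) - V_{m+1}(zeta_j) + V_{m+1}(zeta_i)],

where replica i currently holds window m and replica j window m+1.  Exchanges
swap window *labels* between replicas (momenta are untouched: the umbrella is
momentum-independent), and sweeps alternate even/odd neighbor pairs so every
pair is attempted every other cycle.  Output series are sorted by window
label, which is what WHAM consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .restraints import (
    CylindricalRestraint,
    PullSnapshot,
    UmbrellaWindow,
    cylindrical_bias,
    umbrella_bias,
)
from .toy_system import ToySystem, _propagate, biased_axial_density

__all__ = [
    "REUSConfig",
    "ReplicaEnsembleState",
    "ExchangeRecord",
    "REUSResult",
    "exchange_delta",
    "metropolis_accept",
    "attempt_neighbor_exchanges",
    "run_reus",
    "acceptance_rates",
    "replica_trace",
    "predict_exchange_acceptance",
    "calibrate_ladder_stiffness",
]


@dataclass(frozen=True)
class REUSConfig:
    """Run control: ``steps_per_cycle`` dynamics steps between exchange
    sweeps (the 2 ps of the production protocol, scaled to the toy clock),
    ``n_cycles`` sweeps, parity alternation of attempted neighbor pairs."""

    steps_per_cycle: int = 20
    n_cycles: int = 20000
    dt: float = 0.002
    friction: float = 1.0
    seed: int = 0
    parity_alternation: bool = True
    burn_in_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.steps_per_cycle < 1:
            raise ValueError("steps_per_cycle must be >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")


@dataclass
class ReplicaEnsembleState:
    """Permutation between replicas and window labels plus per-replica
    configuration; ``window_of_replica`` is a bijection at all times."""

    window_of_replica: np.ndarray  # (M,) int
    positions: np.ndarray  # (M, 3)
    velocities: np.ndarray  # (M, 3)
    step: int = 0

    @property
    def replica_of_window(self) -> np.ndarray:
        inv = np.empty_like(self.window_of_replica)
        inv[self.window_of_replica] = np.arange(len(self.window_of_replica))
        return inv

    def check_bijection(self) -> bool:
        return np.array_equal(
            np.sort(self.window_of_replica), np.arange(len(self.window_of_replica))
        )


@dataclass(frozen=True)
class ExchangeRecord:
    """One attempted neighbor exchange (window pair m, m+1)."""

    step: int
    pair_lo: int
    pair_hi: int
    replica_lo: int
    replica_hi: int
    delta: float
    accepted: bool


def exchange_delta(
    v_m: Callable[[float], float],
    v_m1: Callable[[float], float],
    zeta_i: float,
    zeta_j: float,
    beta: float,
) -> float:
    """Metropolis exponent Delta for swapping windows m and m+1.

    Replica i holds window m at ``zeta_i``; replica j holds window m+1 at
    ``zeta_j``.  Antisymmetric under (i <-> j).
    """
    d = beta * (v_m(zeta_j) - v_m(zeta_i) - v_m1(zeta_j) + v_m1(zeta_i))
    d = float(d)
    if not np.isfinite(d):
        raise ValueError("non-finite exchange exponent")
    return d


def metropolis_accept(delta: float, uniform_draw: float) -> bool:
    """Accept iff Delta <= 0, else with probability e^{-Delta}."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    return delta <= 0.0 or uniform_draw < np.exp(-delta)


def attempt_neighbor_exchanges(
    state: ReplicaEnsembleState,
    ladder: Sequence[UmbrellaWindow],
    parity: int,
    rng: np.random.Generator,
    beta: float | None = None,
) -> list[ExchangeRecord]:
    """One exchange sweep over neighbor pairs (m, m+1) with m of ``parity``.

    Accepted swaps exchange the umbrella potentials between the two replicas
    (window labels swap; coordinates and momenta stay); the permutation
    remains a bijection.
    """
    if beta is None:
        beta = state._beta
    records: list[ExchangeRecord] = []
    rep_of_win = state.replica_of_window
    for m in range(parity % 2, len(ladder) - 1, 2):
        i = int(rep_of_win[m])
        j = int(rep_of_win[m + 1])
        zeta_i = float(state.positions[i, 2])
        zeta_j = float(state.positions[j, 2])
        delta = exchange_delta(
            ladder[m].energy, ladder[m + 1].energy, zeta_i, zeta_j, beta
        )
        accepted = metropolis_accept(delta, float(rng.random()))
        if accepted:
            state.window_of_replica[i] = m + 1
            state.window_of_replica[j] = m
            rep_of_win[m], rep_of_win[m + 1] = j, i
        records.append(
            ExchangeRecord(
                step=state.step,
                pair_lo=m,
                pair_hi=m + 1,
                replica_lo=i,
                replica_hi=j,
                delta=delta,
                accepted=accepted,
            )
        )
    return records


@dataclass
class REUSResult:
    """Window-sorted zeta series, full exchange log, and bookkeeping needed
    to reconstruct per-replica window trajectories."""

    zeta_by_window: np.ndarray  # (M, n_records)
    records: list[ExchangeRecord]
    initial_permutation: np.ndarray  # window_of_replica at t = 0
    ladder: list[UmbrellaWindow]
    config: REUSConfig
    snapshots: dict[int, list[PullSnapshot]] = field(default_factory=dict)
    positions_by_window: dict[int, np.ndarray] = field(default_factory=dict)

    def exchange_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": r.step,
                    "pair_lo": r.pair_lo,
                    "pair_hi": r.pair_hi,
                    "delta": r.delta,
                    "accepted": int(r.accepted),
                }
                for r in self.records
            ]
        )

    def window_series(self, discard_burn_in: bool = True) -> list[np.ndarray]:
        """Per-window zeta series (list over window labels)."""
        n = self.zeta_by_window.shape[1]
        start = int(self.config.burn_in_fraction * n) if discard_burn_in else 0
        return [self.zeta_by_window[m, start:] for m in range(len(self.ladder))]


def run_reus(
    system: ToySystem,
    ladder: Sequence[UmbrellaWindow],
    cylindrical: CylindricalRestraint | None,
    config: REUSConfig,
    initial: Sequence[PullSnapshot] | None = None,
    snapshot_windows: Sequence[int] = (),
) -> REUSResult:
    """Run the replica-exchange simulation.

    ``initial`` supplies one starting configuration per window (typically
    from :func:`reusbind.restraints.steered_pull`); when omitted, replicas
    start at their window centers on the axis.  ``snapshot_windows`` lists
    window labels whose occupant's full 3-D position is recorded every cycle
    (used for the unbound-replica volume estimate and for TI bound poses).
    Deterministic for a fixed config seed.
    """
    ladder = list(ladder)
    M = len(ladder)
    if M < 2:
        raise ValueError("need at least 2 windows")
    centers = np.array([w.center for w in ladder])
    stiffs = np.array([w.stiffness for w in ladder])
    rng = np.random.default_rng(config.seed)

    if initial is None:
        x = np.column_stack([np.zeros(M), np.zeros(M), centers]).astype(float)
        v = system.maxwell_velocities(M, rng)
    else:
        if len(initial) != M:
            raise ValueError("one initial configuration per window required")
        x = np.array([s.position for s in initial], dtype=float)
        v = np.array([s.velocity for s in initial], dtype=float)

    state = ReplicaEnsembleState(
        window_of_replica=np.arange(M), positions=x, velocities=v
    )
    state._beta = system.beta  # cached for the sweep loop

    extra = [cylindrical_bias(cylindrical)] if cylindrical is not None else []
    records: list[ExchangeRecord] = []
    zeta_by_window = np.empty((M, config.n_cycles + 1))
    rep_of_win0 = state.replica_of_window
    zeta_by_window[:, 0] = x[rep_of_win0, 2]
    snap_pos: dict[int, list[np.ndarray]] = {m: [] for m in snapshot_windows}
    snap_full: dict[int, list[PullSnapshot]] = {m: [] for m in snapshot_windows}

    for cycle in range(1, config.n_cycles + 1):
        # dynamics segment under the current replica->window assignment
        bias = [
            umbrella_bias(
                centers[state.window_of_replica], stiffs[state.window_of_replica]
            )
        ] + extra
        _propagate(
            system,
            state.positions,
            state.velocities,
            bias,
            config.steps_per_cycle,
            config.dt,
            config.friction,
            rng,
        )
        state.step = cycle * config.steps_per_cycle
        parity = cycle % 2 if config.parity_alternation else 0
        records.extend(attempt_neighbor_exchanges(state, ladder, parity, rng))
        rep_of_win = state.replica_of_window
        zeta_by_window[:, cycle] = state.positions[rep_of_win, 2]
        for m in snapshot_windows:
            i = int(rep_of_win[m])
            snap_pos[m].append(state.positions[i].copy())
            snap_full[m].append(
                PullSnapshot(
                    zeta=float(state.positions[i, 2]),
                    position=state.positions[i].copy(),
                    velocity=state.velocities[i].copy(),
                )
            )

    return REUSResult(
        zeta_by_window=zeta_by_window,
        records=records,
        initial_permutation=np.arange(M),
        ladder=ladder,
        config=config,
        snapshots=snap_full,
        positions_by_window={m: np.array(p) for m, p in snap_pos.items()},
    )


def acceptance_rates(records: Sequence[ExchangeRecord]):
    """Accepted/attempted per neighbor pair plus the overall mean.

    Returns (per_pair: dict[(m, m+1) -> rate], overall mean rate); an empty
    log yields an empty map and NaN mean.
    """
    attempts: dict[tuple[int, int], list[int]] = {}
    for r in records:
        attempts.setdefault((r.pair_lo, r.pair_hi), []).append(int(r.accepted))
    per_pair = {pair: float(np.mean(a)) for pair, a in sorted(attempts.items())}
    overall = (
        float(np.mean([int(r.accepted) for r in records])) if records else float("nan")
    )
    return per_pair, overall


def replica_trace(result: REUSResult, replica: int) -> np.ndarray:
    """Window label of ``replica`` after each exchange sweep.

    Reconstructed from the exchange log; consecutive labels differ by at
    most one (only neighbor swaps occur).
    """
    M = len(result.ladder)
    if not 0 <= replica < M:
        raise ValueError(f"unknown replica index {replica}")
    perm = result.initial_permutation.copy()
    steps = sorted({r.step for r in result.records})
    by_step: dict[int, list[ExchangeRecord]] = {}
    for r in result.records:
        by_step.setdefault(r.step, []).append(r)
    trace = [perm[replica]]
    for s in steps:
        for r in by_step[s]:
            if r.accepted:
                perm[r.replica_lo], perm[r.replica_hi] = (
                    r.pair_hi,
                    r.pair_lo,
                )
        trace.append(perm[replica])
    return np.array(trace)


# -- a priori acceptance prediction / ladder calibration ----------------

def predict_exchange_acceptance(
    system: ToySystem,
    ladder: Sequence[UmbrellaWindow],
    grid_points: int = 512,
):
    """Expected Metropolis acceptance per neighbor pair under exact sampling.

    For each pair (m, m+1) the biased equilibrium densities p_m, p_{m+1} are
    evaluated on a grid and the acceptance <min(1, e^{-Delta})> is computed
    by 2-D quadrature.  Used to calibrate the default umbrella stiffness to
    the 20-30% acceptance band before any simulation is run.
    """
    ladder = list(ladder)
    beta = system.beta
    dens = []
    for w in ladder:
        grid, p = biased_axial_density(system, w.energy, grid_points)
        dens.append(p)
    grid_w = np.gradient(grid)
    rates = []
    for m in range(len(ladder) - 1):
        vm = ladder[m].energy(grid)
        vm1 = ladder[m + 1].energy(grid)
        # Delta(zi, zj) = beta [vm(zj) - vm(zi) - vm1(zj) + vm1(zi)]
        a = beta * (vm - vm1)  # function of zj when indexed j, of zi with minus
        delta = a[None, :] - a[:, None]  # [i, j]
        acc = np.exp(-np.clip(delta, 0.0, None))
        wi = dens[m] * grid_w
        wj = dens[m + 1] * grid_w
        rates.append(float(wi @ acc @ wj))
    return np.array(rates), float(np.mean(rates))


def calibrate_ladder_stiffness(
    system: ToySystem,
    target: float = 0.25,
    span: tuple[float, float] = (-13.0, 14.0),
    n_windows: int = 32,
    dense_region: tuple[float, float] | None = (-3.0, 3.0),
    dense_spacing: float = 0.5,
    k_bounds: tuple[float, float] = (0.05, 20.0),
    tol: float = 1e-3,
) -> float:
    """Uniform umbrella stiffness whose predicted mean acceptance hits
    ``target`` on the given ladder geometry (bisection; acceptance is
    monotone decreasing in k)."""
    from .restraints import build_window_ladder

    def mean_acc(k: float) -> float:
        ladder = build_window_ladder(
            span, n_windows, dense_region, dense_spacing, stiffness=k
        )
        return predict_exchange_acceptance(system, ladder)[1]

    lo, hi = k_bounds
    if not mean_acc(hi) <= target <= mean_acc(lo):
        raise ValueError("target acceptance not bracketed by k_bounds")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_acc(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
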