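"""End-to-end orchestration: toy system -> steered seeding -> REUS -> WHAM
-> corrections -> assembled binding free energy, with per-stage artifacts.

A single master seed fans out to fixed per-stage offsets (pull, REUS, TI,
bootstrap), so any downstream stage can be rerun in isolation and a fixed
seed reproduces every output byte-for-byte.  The unidirectional variant
truncates the window ladder at the bound center and uses the left flank as
the unbound reference, mirroring the cheaper one-sided pulling protocol.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import V0_STANDARD
from .corrections import (
    BindingResult,
    TISchedule,
    effective_volume,
    restraint_off_correction,
    ti_restraint_on,
)
from .restraints import (
    DEFAULT_UMBRELLA_STIFFNESS,
    CylindricalRestraint,
    UmbrellaWindow,
    assign_snapshots_to_ladder,
    build_window_ladder,
    steered_pull,
)
from .reus import REUSConfig, REUSResult, acceptance_rates, run_reus
from .toy_system import ToySystem, TrajectorySamples, write_trajectory
from .wham import (
    WHAM,
    build_histograms,
    bootstrap_uncertainty,
    delta_g_reus,
)

__all__ = ["LadderConfig", "WHAMConfig", "RunConfig", "PipelineResult", "run_pipeline"]

# master-seed fan-out offsets (stage seeds stay below 2^31)
_SEED_PULL, _SEED_REUS, _SEED_TI, _SEED_BOOT = 101, 211, 307, 401


@dataclass(frozen=True)
class LadderConfig:
    span: tuple[float, float] = (-13.0, 14.0)
    n_windows: int = 32
    dense_region: tuple[float, float] | None = (-3.0, 3.0)
    dense_spacing: float = 0.5
    stiffness: float = DEFAULT_UMBRELLA_STIFFNESS


@dataclass(frozen=True)
class WHAMConfig:
    bin_width: float = 0.2
    edge_padding: float = 1.5
    tol: float = 1e-7
    max_iter: int = 100_000
    mode: str = "depth"  # dG_REUS definition: "depth" or "integrated"
    bound_region: tuple[float, float] = (-3.0, 3.0)
    unbound_margin: float = 3.0  # outermost span of each flank
    n_boot: int = 20
    block: int = 50


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (nested per-stage sections)."""

    system: ToySystem = field(default_factory=ToySystem)
    ladder: LadderConfig = field(default_factory=LadderConfig)
    reus: REUSConfig = field(default_factory=REUSConfig)
    wham: WHAMConfig = field(default_factory=WHAMConfig)
    ti: TISchedule = field(default_factory=TISchedule)
    cylindrical: CylindricalRestraint = field(default_factory=CylindricalRestraint)
    direction: str = "bidirectional"  # or "unidirectional"
    v0: float = V0_STANDARD
    seed: int = 0
    guest: str = "toy"
    parameter_set: str = "toy-default"

    def __post_init__(self) -> None:
        if self.direction not in ("bidirectional", "unidirectional"):
            raise ValueError("direction must be bidirectional or unidirectional")

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x

        kwargs: dict = {}
        if "system" in d:
            s = dict(d["system"])
            s["axial_range"] = tup(s.get("axial_range", (-13.0, 14.0)))
            kwargs["system"] = ToySystem(**s)
        if "ladder" in d:
            l = dict(d["ladder"])
            l["span"] = tup(l.get("span", (-13.0, 14.0)))
            if l.get("dense_region") is not None:
                l["dense_region"] = tup(l["dense_region"])
            kwargs["ladder"] = LadderConfig(**l)
        if "reus" in d:
            kwargs["reus"] = REUSConfig(**d["reus"])
        if "wham" in d:
            w = dict(d["wham"])
            w["bound_region"] = tup(w.get("bound_region", (-3.0, 3.0)))
            kwargs["wham"] = WHAMConfig(**w)
        if "ti" in d:
            t = dict(d["ti"])
            t["lambdas"] = tup(t.get("lambdas", TISchedule().lambdas))
            kwargs["ti"] = TISchedule(**t)
        if "cylindrical" in d:
            c = dict(d["cylindrical"])
            for k in ("axis", "origin"):
                if k in c:
                    c[k] = tup(c[k])
            kwargs["cylindrical"] = CylindricalRestraint(**c)
        for k in ("direction", "v0", "seed", "guest", "parameter_set"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    """Everything the pipeline produced, plus handles for diagnostics."""

    binding: BindingResult
    reus_result: REUSResult
    pmf: "object"
    v_eff: float
    acceptance_mean: float
    ladder: list[UmbrellaWindow]
    config: RunConfig
    ti_table: pd.DataFrame


def _build_ladder(cfg: RunConfig) -> list[UmbrellaWindow]:
    lad = cfg.ladder
    ladder = build_window_ladder(
        lad.span, lad.n_windows, lad.dense_region, lad.dense_spacing, lad.stiffness
    )
    if cfg.direction == "unidirectional":
        # truncate at the bound center; relabel to keep labels contiguous
        kept = [w for w in ladder if w.center <= 0.0 + 1e-9]
        ladder = [
            UmbrellaWindow(center=w.center, stiffness=w.stiffness, label=i)
            for i, w in enumerate(kept)
        ]
    return ladder


def _regions(cfg: RunConfig, ladder) -> tuple[tuple[float, float], list]:
    lo = ladder[0].center
    hi = ladder[-1].center
    m = cfg.wham.unbound_margin
    bound = cfg.wham.bound_region
    if cfg.direction == "unidirectional":
        bound = (bound[0], min(bound[1], hi))
        unbound = [(lo, lo + m)]
    else:
        unbound = [(lo, lo + m), (hi - m, hi)]
    return bound, unbound


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute all stages and (optionally) write per-stage artifacts.

    Artifacts: ladder.json, window_##.dat series, exchange_log.csv, pmf.csv,
    overlap.csv, ti.csv, corrections.csv, result.json.  Deterministic for a
    fixed ``config.seed``.
    """
    cfg = config
    system = cfg.system
    ladder = _build_ladder(cfg)
    bound_region, unbound_regions = _regions(cfg, ladder)
    bound_label = int(np.argmin([abs(w.center) for w in ladder]))
    unbound_label = 0

    # 1. steered pull -> per-window initial configurations
    snapshots = steered_pull(
        system,
        start=ladder[0].center,
        end=ladder[-1].center,
        stiffness=5.0,
        n_steps=20000,
        dt=cfg.reus.dt,
        friction=cfg.reus.friction,
        seed=cfg.seed + _SEED_PULL,
        cylindrical=cfg.cylindrical,
    )
    initial = assign_snapshots_to_ladder(snapshots, ladder)

    # 2. replica exchange
    reus_cfg = dataclasses.replace(cfg.reus, seed=cfg.seed + _SEED_REUS)
    result = run_reus(
        system,
        ladder,
        cfg.cylindrical,
        reus_cfg,
        initial=initial,
        snapshot_windows=(unbound_label, bound_label),
    )
    _, acc_mean = acceptance_rates(result.records)

    # 3. WHAM -> PMF -> dG_REUS (+ block bootstrap)
    series = result.window_series()
    pad = cfg.wham.edge_padding
    lo = ladder[0].center - pad
    hi = ladder[-1].center + pad
    n_bins = int(np.ceil((hi - lo) / cfg.wham.bin_width))
    edges = lo + cfg.wham.bin_width * np.arange(n_bins + 1)
    hist = build_histograms(series, ladder, edges)
    fit = WHAM(hist, system.temperature).fit(
        tol=cfg.wham.tol, max_iter=cfg.wham.max_iter
    )
    pmf = fit.pmf()
    dg_reus = delta_g_reus(
        pmf, bound_region, unbound_regions, mode=cfg.wham.mode, beta=system.beta
    )

    f_warm = fit.f

    def estimator(resampled):
        h = build_histograms(resampled, ladder, edges)
        r = WHAM(h, system.temperature).fit(
            tol=cfg.wham.tol, max_iter=cfg.wham.max_iter, f_init=f_warm
        )
        return delta_g_reus(
            r.pmf(), bound_region, unbound_regions, mode=cfg.wham.mode,
            beta=system.beta,
        )

    stderr_reus, _ = bootstrap_uncertainty(
        series,
        estimator,
        n_boot=cfg.wham.n_boot,
        block=cfg.wham.block,
        seed=cfg.seed + _SEED_BOOT,
    )

    # 4. corrections
    burn = int(cfg.reus.burn_in_fraction * len(result.positions_by_window[unbound_label]))
    unbound_pos = result.positions_by_window[unbound_label][burn:]
    v_eff, r_max, r_min, h_max = effective_volume(unbound_pos)
    dg_off = restraint_off_correction(v_eff, system.temperature, cfg.v0)

    bound_snaps = result.snapshots[bound_label][burn:]
    stride = max(1, len(bound_snaps) // cfg.ti.n_poses)
    poses = bound_snaps[::stride][: cfg.ti.n_poses]
    dg_on, stderr_on, ti_table = ti_restraint_on(
        system,
        poses,
        ladder[bound_label],
        cfg.ti,
        cylindrical=cfg.cylindrical,
        dt=cfg.reus.dt,
        friction=cfg.reus.friction,
        seed=cfg.seed + _SEED_TI,
    )

    binding = BindingResult(
        guest=cfg.guest,
        parameter_set=cfg.parameter_set,
        dg_reus=dg_reus,
        dg_rest_off=dg_off,
        dg_rest_on=dg_on,
        stderr_reus=stderr_reus,
        stderr_rest_on=stderr_on,
        mode=cfg.wham.mode,
        metadata={
            "v_eff": v_eff,
            "r_max": r_max,
            "r_min": r_min,
            "h_max": h_max,
            "acceptance_mean": acc_mean,
            "direction": cfg.direction,
            "seed": cfg.seed,
            "bound_region": bound_region,
            "unbound_regions": unbound_regions,
        },
    )

    out = PipelineResult(
        binding=binding,
        reus_result=result,
        pmf=pmf,
        v_eff=v_eff,
        acceptance_mean=acc_mean,
        ladder=ladder,
        config=cfg,
        ti_table=ti_table,
    )
    if outdir is not None:
        _write_artifacts(Path(outdir), out, hist)
    return out


def _write_artifacts(outdir: Path, res: PipelineResult, hist) -> None:
    from .wham import overlap_matrix

    outdir.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    with open(outdir / "ladder.json", "w") as fh:
        json.dump(
            [
                {"label": w.label, "center": w.center, "stiffness": w.stiffness}
                for w in res.ladder
            ],
            fh,
            indent=1,
        )
    cfg.to_yaml(outdir / "config.yaml")
    for m, z in enumerate(res.reus_result.window_series(discard_burn_in=False)):
        steps = np.arange(len(z)) * cfg.reus.steps_per_cycle
        samples = TrajectorySamples(
            step=steps,
            zeta=z,
            radial=np.zeros_like(z),
            bias_energy=res.ladder[m].energy(z),
        )
        write_trajectory(
            outdir / f"window_{m:02d}.dat",
            samples,
            header=f"window {m} center {res.ladder[m].center}",
        )
    res.reus_result.exchange_log().to_csv(outdir / "exchange_log.csv", index=False)
    res.pmf.to_frame().to_csv(outdir / "pmf.csv", index=False)
    pd.DataFrame(overlap_matrix(hist)).to_csv(outdir / "overlap.csv", index=False)
    res.ti_table.to_csv(outdir / "ti.csv", index=False)
    pd.DataFrame([res.binding.to_row()]).to_csv(
        outdir / "corrections.csv", index=False
    )
    with open(outdir / "result.json", "w") as fh:
        json.dump(
            {
                "dg_reus": res.binding.dg_reus,
                "dg_rest_off": res.binding.dg_rest_off,
                "dg_rest_on": res.binding.dg_rest_on,
                "dg_bind": res.binding.dg_bind,
                "stderr_bind": res.binding.stderr_bind,
                "v_eff": res.v_eff,
                "acceptance_mean": res.acceptance_mean,
                "metadata": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in res.binding.metadata.items()
                    if k != "unbound_regions"
                },
            },
            fh,
            indent=1,
        )
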