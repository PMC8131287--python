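"""Benchmark statistics between computed and experimental binding affinities.

The SAMPL-style scoring used here: RMSE with population denominator n,
Pearson's r (R^2 reported as r^2), Kendall's tau-a rank correlation
(C - D) / (n(n-1)/2) without tie correction (ties are rejected), mean
absolute error, and mean signed error ME = mean(experimental - computed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "rmse",
    "pearson_r",
    "kendall_tau",
    "mae_me",
    "build_report",
]


@dataclass(frozen=True)
class PredictionSet:
    """Paired computed/experimental binding free energies for one parameter
    set (kcal/mol), keyed by guest label."""

    labels: tuple[str, ...]
    computed: tuple[float, ...]
    experimental: tuple[float, ...]
    parameter_set: str = ""

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.computed) == len(self.experimental)):
            raise ValueError("labels, computed and experimental lengths differ")
        if len(self.labels) < 1:
            raise ValueError("need at least one pair")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def diff(self) -> np.ndarray:
        """calc - exp."""
        return np.asarray(self.computed) - np.asarray(self.experimental)


def rmse(pred: PredictionSet) -> float:
    """Root-mean-square error, population denominator n."""
    return float(np.sqrt(np.mean(pred.diff**2)))


def pearson_r(pred: PredictionSet) -> float:
    """Product-moment correlation between computed and experimental values."""
    if pred.n < 3:
        raise ValueError("Pearson r needs at least 3 pairs")
    x = np.asarray(pred.computed)
    y = np.asarray(pred.experimental)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def kendall_tau(pred: PredictionSet) -> float:
    """Kendall tau-a: (concordant - discordant) / (n(n-1)/2), no ties."""
    x = np.asarray(pred.computed)
    y = np.asarray(pred.experimental)
    if pred.n < 2:
        raise ValueError("tau needs at least 2 pairs")
    if len(np.unique(x)) < pred.n or len(np.unique(y)) < pred.n:
        raise ValueError("ties present; tau-a is undefined (tau-b not implemented)")
    c_minus_d = 0
    for i, j in combinations(range(pred.n), 2):
        # sign of each difference separately (their product can underflow)
        c_minus_d += int(np.sign(x[i] - x[j])) * int(np.sign(y[i] - y[j]))
    return float(c_minus_d / (pred.n * (pred.n - 1) / 2))


def mae_me(pred: PredictionSet) -> tuple[float, float]:
    """(mean absolute error, mean signed error exp - calc)."""
    d = pred.diff
    return float(np.mean(np.abs(d))), float(np.mean(-d))


def _stats_row(pred: PredictionSet) -> dict:
    row = {"parameter_set": pred.parameter_set, "n": pred.n}
    if pred.n >= 3:
        r = pearson_r(pred)
        row.update(r=r, r_squared=r**2)
    else:
        row.update(r=np.nan, r_squared=np.nan)
        row["degenerate"] = True
    row["rmse"] = rmse(pred)
    try:
        row["tau"] = kendall_tau(pred)
    except ValueError:
        row["tau"] = np.nan
        row["degenerate"] = True
    row["mae"], row["me"] = mae_me(pred)
    return row


def build_report(
    results, experimental: Mapping[str, float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-guest table plus per-parameter-set statistics table.

    ``results`` is a sequence of objects with ``guest``, ``parameter_set``
    and ``dg_bind`` attributes (e.g. :class:`reusbind.corrections.BindingResult`)
    or a DataFrame with columns guest/parameter_set/bind.  Every guest must
    have an experimental entry.
    """
    if not experimental:
        raise ValueError("experimental map is empty")
    if isinstance(results, pd.DataFrame):
        per_guest = results.rename(columns={"bind": "computed"})[
            ["guest", "parameter_set", "computed"]
        ].copy()
    else:
        per_guest = pd.DataFrame(
            [
                {
                    "guest": r.guest,
                    "parameter_set": r.parameter_set,
                    "computed": r.dg_bind,
                }
                for r in results
            ]
        )
    missing = set(per_guest["guest"]) - set(experimental)
    if missing:
        raise ValueError(f"missing experimental values for guests {sorted(missing)}")
    per_guest["experimental"] = per_guest["guest"].map(experimental)
    stats_rows = []
    for pset, grp in per_guest.groupby("parameter_set", sort=False):
        pred = PredictionSet(
            labels=tuple(grp["guest"]),
            computed=tuple(grp["computed"]),
            experimental=tuple(grp["experimental"]),
            parameter_set=str(pset),
        )
        stats_rows.append(_stats_row(pred))
    return per_guest, pd.DataFrame(stats_rows)
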