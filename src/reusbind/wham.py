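"""Weighted histogram analysis method: biased windows -> unbiased PMF.

Given per-window samples of the reaction coordinate under known umbrella
biases, the discrete WHAM equations are solved self-consistently,

    p_b = ( sum_m n_{mb} ) / ( sum_m N_m exp[beta f_m - beta V_m(zeta_b)] ),
    exp(-beta f_m) = sum_b p_b exp[-beta V_m(zeta_b)],

iterated until max_m |Delta f_m| < tol, with the gauge fixed by f_0 = 0.
The unbiased probabilities give the PMF F(zeta) = -kT ln p(zeta) (anchored
so the minimum is zero), from which the free energy of pulling the guest
into the binding region, dG_REUS, is extracted either as the well depth
relative to the unbound plateau ("depth") or as a Boltzmann-weighted ratio
of region integrals ("integrated").

The estimator is exposed statsmodels-style: ``WHAM(hist, temperature).fit()``
returns a :class:`WHAMResults` carrying window free energies, the PMF,
convergence diagnostics and a ``summary()``; a maximum-likelihood route
(direct minimization of the WHAM log-likelihood with scipy) is available as
an independent cross-check via ``fit(method="ml")``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .constants import KB, T_DEFAULT
from .restraints import UmbrellaWindow

__all__ = [
    "HistogramSet",
    "PMFProfile",
    "WindowFreeEnergies",
    "WHAM",
    "WHAMResults",
    "build_histograms",
    "solve_wham",
    "pmf_from_wham",
    "delta_g_reus",
    "check_symmetry",
    "bootstrap_uncertainty",
    "overlap_matrix",
]


@dataclass
class HistogramSet:
    """Shared-edge histograms of all windows plus tabulated bias energies.

    ``counts[m, b]`` are samples of window m in bin b; ``bias[m, b]`` is the
    window-m bias energy at the bin center (kcal/mol).  The cylindrical
    restraint is constant along zeta by construction and therefore omitted.
    """

    edges: np.ndarray
    counts: np.ndarray
    bias: np.ndarray
    n_windows: int = field(init=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.counts.shape != self.bias.shape:
            raise ValueError("counts and bias shapes differ")
        if self.counts.shape[1] != len(self.edges) - 1:
            raise ValueError("counts do not match edges")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self.n_windows = self.counts.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class PMFProfile:
    """Gridded free energy along zeta, anchored so min over populated bins
    is zero; ``mask`` flags populated (defined) bins; optional bootstrap
    stderr per bin."""

    centers: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray
    stderr: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"zeta": self.centers, "F_kcal_per_mol": self.free_energy}
        )
        if self.stderr is not None:
            df["stderr"] = self.stderr
        return df[self.mask] if self.mask is not None else df


@dataclass
class WindowFreeEnergies:
    """Per-window offsets f_m (kcal/mol, gauge f_0 = 0) with convergence
    metadata."""

    f: np.ndarray
    residual: float
    n_iter: int
    converged: bool


def build_histograms(
    series_by_window: Sequence[np.ndarray],
    windows: Sequence[UmbrellaWindow] | Sequence[Callable[[np.ndarray], np.ndarray]],
    edges: np.ndarray,
) -> HistogramSet:
    """Histogram each window's zeta series on shared ``edges``.

    Bias energies are tabulated at bin centers (midpoint rule).  Raises if
    edges are not strictly increasing, any sample falls outside the edge
    span, or a window is empty.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = []
    bias = []
    for m, (series, w) in enumerate(zip(series_by_window, windows, strict=True)):
        series = np.asarray(series, dtype=float)
        if series.size == 0:
            raise ValueError(f"window {m} has no samples")
        if series.min() < edges[0] or series.max() > edges[-1]:
            raise ValueError(f"window {m} has samples outside the edge span")
        c, _ = np.histogram(series, bins=edges)
        counts.append(c)
        energy = w.energy(centers) if hasattr(w, "energy") else w(centers)
        bias.append(np.asarray(energy, dtype=float))
    return HistogramSet(edges=edges, counts=np.array(counts), bias=np.array(bias))


def overlap_matrix(hist: HistogramSet) -> np.ndarray:
    """Pairwise histogram overlap: summed min of normalized counts.

    Entry (m, n) in [0, 1]; zero means disjoint support.  Used to verify the
    overlap graph is connected before WHAM and as the Fig.-style diagnostic.
    """
    p = hist.counts / np.maximum(hist.sample_totals[:, None], 1)
    M = hist.n_windows
    ov = np.zeros((M, M))
    for a in range(M):
        for b in range(M):
            ov[a, b] = np.minimum(p[a], p[b]).sum()
    return ov


def _check_connected(hist: HistogramSet) -> None:
    shared = (hist.counts[:, None, :] > 0) & (hist.counts[None, :, :] > 0)
    adj = shared.any(axis=2)
    seen = {0}
    frontier = [0]
    while frontier:
        a = frontier.pop()
        for b in np.nonzero(adj[a])[0]:
            if b not in seen:
                seen.add(int(b))
                frontier.append(int(b))
    if len(seen) < hist.n_windows:
        missing = sorted(set(range(hist.n_windows)) - seen)
        raise ValueError(f"overlap graph disconnected; windows {missing} unreachable")


class WHAM:
    """WHAM estimator for one histogram set at a given temperature."""

    def __init__(self, hist: HistogramSet, temperature: float = T_DEFAULT):
        self.hist = hist
        self.temperature = temperature
        self.beta = 1.0 / (KB * temperature)

    # log density up to normalization given window offsets g = beta*f
    def _log_p(self, g: np.ndarray) -> np.ndarray:
        h = self.hist
        with np.errstate(divide="ignore"):
            log_num = np.log(h.counts.sum(axis=0))
        log_den = logsumexp(
            np.log(h.sample_totals)[:, None] + g[:, None] - self.beta * h.bias,
            axis=0,
        )
        log_p = log_num - log_den
        log_p -= logsumexp(log_p[np.isfinite(log_p)])
        return log_p

    def _g_update(self, log_p: np.ndarray) -> np.ndarray:
        finite = np.isfinite(log_p)
        g = -logsumexp(
            log_p[None, finite] - self.beta * self.hist.bias[:, finite], axis=1
        )
        return g - g[0]

    def fit(
        self,
        tol: float = 1e-7,
        max_iter: int = 100_000,
        method: str = "scf",
        f_init: np.ndarray | None = None,
    ) -> "WHAMResults":
        """Solve the WHAM equations.

        ``tol`` is the max |Delta f_m| stopping threshold in kcal/mol for
        the self-consistent iteration (``method="scf"``); ``method="ml"``
        minimizes the equivalent negative log-likelihood with BFGS instead
        (independent numerical route, used for cross-validation).
        Raises on a disconnected overlap graph or non-convergence.
        """
        h = self.hist
        _check_connected(h)
        g = (
            np.zeros(h.n_windows)
            if f_init is None
            else self.beta * np.asarray(f_init, dtype=float)
        )
        if method == "scf":
            n_iter = 0
            residual = np.inf
            for n_iter in range(1, max_iter + 1):
                g_new = self._g_update(self._log_p(g))
                residual = float(np.max(np.abs(g_new - g))) / self.beta
                g = g_new
                if residual < tol:
                    break
            converged = residual < tol
            if not converged:
                raise RuntimeError(
                    f"WHAM did not converge in {max_iter} iterations "
                    f"(residual {residual:.2e} kcal/mol)"
                )
        elif method == "ml":
            g, n_iter = self._fit_ml(g)
            residual = float(
                np.max(np.abs(self._g_update(self._log_p(g)) - g)) / self.beta
            )
            converged = True
        else:
            raise ValueError(f"unknown method {method!r}")
        log_p = self._log_p(g)
        return WHAMResults(
            model=self,
            window_free_energies=WindowFreeEnergies(
                f=g / self.beta, residual=residual, n_iter=n_iter, converged=converged
            ),
            log_probabilities=log_p,
        )

    def _fit_ml(self, g0: np.ndarray) -> tuple[np.ndarray, int]:
        """Direct minimization of the WHAM negative log-likelihood.

        A(g) = -sum_m N_m g_m + sum_b c_b ln sum_m N_m e^{g_m - beta V_mb}
        over g_2..g_M with g_1 = 0 fixed; convex, solved with BFGS and an
        analytic gradient.
        """
        h = self.hist
        N = h.sample_totals.astype(float)
        n_total = N.sum()
        c_b = h.counts.sum(axis=0).astype(float)
        logN = np.log(N)
        bV = self.beta * h.bias

        def objective(g_free: np.ndarray):
            g = np.concatenate([[0.0], g_free])
            a_mb = logN[:, None] + g[:, None] - bV
            log_den = logsumexp(a_mb, axis=0)
            value = (-(N @ g) + c_b @ log_den) / n_total
            w_mb = np.exp(a_mb - log_den)  # softmax over windows
            grad = (-N + w_mb @ c_b) / n_total
            return value, grad[1:]

        res = minimize(
            objective,
            g0[1:],
            jac=True,
            method="BFGS",
            options={"gtol": 1e-11, "maxiter": 5000},
        )
        # BFGS may report precision loss at machine-level gradients; accept
        # any stationary point with a per-sample gradient below 1e-9
        if np.linalg.norm(res.jac, np.inf) > 1e-9:
            raise RuntimeError(f"ML WHAM failed: {res.message}")
        return np.concatenate([[0.0], res.x]), int(res.nit)


@dataclass
class WHAMResults:
    """Fitted WHAM solution: window offsets, unbiased bin probabilities and
    derived PMF."""

    model: WHAM
    window_free_energies: WindowFreeEnergies
    log_probabilities: np.ndarray

    @property
    def f(self) -> np.ndarray:
        return self.window_free_energies.f

    @property
    def probabilities(self) -> np.ndarray:
        p = np.exp(self.log_probabilities)
        return np.where(np.isfinite(self.log_probabilities), p, 0.0)

    def pmf(self) -> PMFProfile:
        return pmf_from_wham(
            self.probabilities, self.model.beta, self.model.hist.centers
        )

    def summary(self) -> str:
        wfe = self.window_free_energies
        lines = [
            "WHAM results",
            "============",
            f"windows: {self.model.hist.n_windows}   "
            f"bins: {len(self.model.hist.centers)}   "
            f"samples: {int(self.model.hist.sample_totals.sum())}",
            f"temperature: {self.model.temperature:.2f} K",
            f"iterations: {wfe.n_iter}   residual: {wfe.residual:.2e} kcal/mol   "
            f"converged: {wfe.converged}",
            "",
            " m    f_m (kcal/mol)",
        ]
        lines += [f"{m:3d}  {fm:12.4f}" for m, fm in enumerate(wfe.f)]
        return "\n".join(lines)


def solve_wham(
    hist: HistogramSet,
    beta: float,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    method: str = "scf",
) -> tuple[WindowFreeEnergies, np.ndarray]:
    """Functional wrapper: returns (window free energies, probabilities)."""
    res = WHAM(hist, temperature=1.0 / (KB * beta)).fit(
        tol=tol, max_iter=max_iter, method=method
    )
    return res.window_free_energies, res.probabilities


def pmf_from_wham(
    probabilities: np.ndarray, beta: float, centers: np.ndarray
) -> PMFProfile:
    """F(zeta_b) = -(1/beta) ln p_b, shifted so the minimum is zero.

    Empty bins (p = 0) are flagged undefined via the profile mask.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.all(p <= 0):
        raise ValueError("all probabilities are zero")
    mask = p > 0
    F = np.full_like(p, np.nan)
    F[mask] = -np.log(p[mask]) / beta
    F -= np.nanmin(F)
    return PMFProfile(centers=np.asarray(centers, dtype=float), free_energy=F, mask=mask)


def _region_bins(pmf: PMFProfile, region: tuple[float, float]) -> np.ndarray:
    lo, hi = region
    sel = (pmf.centers >= lo) & (pmf.centers <= hi) & pmf.mask
    if not np.any(sel):
        raise ValueError(f"region {region} contains no populated bins")
    return sel


def delta_g_reus(
    pmf: PMFProfile,
    bound_region: tuple[float, float],
    unbound_region: tuple[float, float] | Sequence[tuple[float, float]],
    mode: str = "depth",
    beta: float | None = None,
) -> float:
    """Free energy of pulling the guest into the binding region, kcal/mol.

    mode="depth": F at the bound minimum minus the mean F over the unbound
    plateau (negative for a binding well).  mode="integrated":
    -(1/beta) ln[ <e^{-beta F}>_bound / <e^{-beta F}>_unbound ] with bin
    averages over the two regions (requires ``beta``).  ``unbound_region``
    may be one interval or a sequence (both flanks of a bidirectional run).
    """
    regions = (
        [unbound_region]
        if isinstance(unbound_region[0], (int, float))
        else list(unbound_region)
    )
    sel_b = _region_bins(pmf, bound_region)
    sel_u = np.zeros_like(sel_b)
    for reg in regions:
        sel_u |= _region_bins(pmf, reg)
    F = pmf.free_energy
    if mode == "depth":
        return float(np.nanmin(F[sel_b]) - np.nanmean(F[sel_u]))
    if mode == "integrated":
        if beta is None:
            raise ValueError("integrated mode requires beta")
        lb = logsumexp(-beta * F[sel_b]) - np.log(sel_b.sum())
        lu = logsumexp(-beta * F[sel_u]) - np.log(sel_u.sum())
        return float(-(lb - lu) / beta)
    raise ValueError(f"unknown mode {mode!r}")


def check_symmetry(pmf: PMFProfile, center: float = 0.0) -> float:
    """RMS difference between F(center+x) and F(center-x), kcal/mol.

    Interpolated on the overlapping |x| span of the two flanks; diverging
    flanks signal incomplete bidirectional sampling.
    """
    z = pmf.centers[pmf.mask]
    F = pmf.free_energy[pmf.mask]
    right = z[z > center] - center
    left = center - z[z < center]
    if right.size == 0 or left.size == 0:
        raise ValueError("profile does not span both sides of the center")
    xmax = min(right.max(), left.max())
    x = np.linspace(0.0, xmax, 200)
    f_plus = np.interp(center + x, z, F)
    f_minus = np.interp(center - x, z, F)
    return float(np.sqrt(np.mean((f_plus - f_minus) ** 2)))


def bootstrap_uncertainty(
    series_by_window: Sequence[np.ndarray],
    estimator: Callable[[list[np.ndarray]], float],
    n_boot: int = 20,
    block: int = 50,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Block-bootstrap standard error of any window-series statistic.

    Each window's series is resampled as contiguous blocks of length
    ``block`` (with replacement, preserving series length) to respect serial
    correlation; ``estimator`` maps the resampled series list to a scalar
    (e.g. the WHAM -> dG_REUS pipeline).  Returns (stddev over resamples,
    the resample values).  Seed-deterministic.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    for s in series_by_window:
        if len(s) < block:
            raise ValueError("block longer than a window series")
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    for b in range(n_boot):
        resampled = []
        for s in series_by_window:
            s = np.asarray(s)
            n_blocks = int(np.ceil(len(s) / block))
            starts = rng.integers(0, len(s) - block + 1, n_blocks)
            parts = [s[st : st + block] for st in starts]
            resampled.append(np.concatenate(parts)[: len(s)])
        values[b] = estimator(resampled)
    return float(np.std(values, ddof=1)), values
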