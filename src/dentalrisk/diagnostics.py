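"""MCMC convergence diagnostics: autocorrelation, Gelman-Rubin, reports.

The diagnostics operate on numeric draw arrays so everything is testable
without a graphics stack; :mod:`dentalrisk.plots` layers optional trace /
density / ACF figures on top of the exported series.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from dentalrisk.bayes import PosteriorSamples

__all__ = [
    "AcfSeries",
    "PsrfReport",
    "ConvergenceReport",
    "autocorrelation",
    "gelman_rubin",
    "convergence_report",
]


@dataclasses.dataclass(frozen=True)
class AcfSeries:
    """Sample autocorrelation at lags 0..L (lag 0 is exactly 1)."""

    lags: np.ndarray
    values: np.ndarray

    def __getitem__(self, lag: int) -> float:
        return float(self.values[lag])


def autocorrelation(series: np.ndarray, max_lag: int) -> AcfSeries:
    """Sample ACF with overall-mean centering and lag-0 normalisation.

    For a constant (zero-variance) series the ACF is defined as 1 at lag 0
    and 0 elsewhere.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.shape[0]
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be below series length {n}")
    c = x - x.mean()
    denom = float(c @ c)
    values = np.zeros(max_lag + 1)
    values[0] = 1.0
    if denom > 0.0:
        for k in range(1, max_lag + 1):
            values[k] = float(c[:-k] @ c[k:]) / denom
    return AcfSeries(lags=np.arange(max_lag + 1), values=values)


@dataclasses.dataclass(frozen=True)
class PsrfReport:
    """Per-slot Gelman-Rubin potential scale reduction factors.

    ``within`` is the mean within-chain variance W, ``between_over_n`` the
    variance of chain means B/n, ``pooled`` the pooled variance estimate
    ``(n-1)/n W + B/n``, and ``rhat = sqrt(pooled / W)`` floored at 1 (the
    pooled estimate can dip below W by the (n-1)/n factor alone).
    """

    names: tuple[str, ...]
    within: np.ndarray
    between_over_n: np.ndarray
    pooled: np.ndarray
    rhat: np.ndarray
    threshold: float

    @property
    def passed(self) -> bool:
        return bool(np.all(self.rhat < self.threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slot": self.names,
                "within": self.within,
                "between_over_n": self.between_over_n,
                "pooled": self.pooled,
                "rhat": self.rhat,
            }
        ).set_index("slot")


def gelman_rubin(
    samples: PosteriorSamples | np.ndarray,
    names: tuple[str, ...] | None = None,
    threshold: float = 1.1,
) -> PsrfReport:
    """Classic (un-split, un-rank-normalised) Gelman-Rubin diagnostic.

    Accepts a :class:`~dentalrisk.bayes.PosteriorSamples` or a raw array of
    shape (n_chains, n_draws, p).  Requires at least two chains of equal
    stored length — the diagnostic is undefined for a single chain.
    """
    if isinstance(samples, PosteriorSamples):
        draws = samples.draws
        names = names or samples.names
    else:
        draws = np.asarray(samples, dtype=float)
        if draws.ndim == 2:
            draws = draws[:, :, None]
    m, n, p = draws.shape
    if m < 2:
        raise ValueError(
            "Gelman-Rubin requires multiple chains; got a single chain"
        )
    if n < 2:
        raise ValueError("chains must contain at least two draws")
    names = names or tuple(f"x{j}" for j in range(p))
    within = draws.var(axis=1, ddof=1).mean(axis=0)  # (p,)
    chain_means = draws.mean(axis=1)  # (m, p)
    between_over_n = chain_means.var(axis=0, ddof=1)
    pooled = (n - 1) / n * within + between_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(within > 0, pooled / np.where(within > 0, within, 1.0), 1.0)
    rhat = np.sqrt(np.maximum(ratio, 1.0))
    return PsrfReport(
        names=tuple(names),
        within=within,
        between_over_n=between_over_n,
        pooled=pooled,
        rhat=rhat,
        threshold=threshold,
    )


@dataclasses.dataclass(frozen=True)
class ConvergenceReport:
    """Machine-readable convergence report for one posterior run."""

    psrf: PsrfReport
    lag1_acf: pd.DataFrame  # per slot: within-chain lag-1 ACF, mean over chains
    density: dict[str, tuple[np.ndarray, np.ndarray]]  # slot -> (grid, kde)
    trace: dict[str, np.ndarray]  # slot -> (n_chains, n_stored)
    threshold: float

    @property
    def passed(self) -> bool:
        return self.psrf.passed

    def to_frame(self) -> pd.DataFrame:
        frame = self.psrf.to_frame()
        frame["lag1_acf"] = self.lag1_acf["lag1_acf"]
        frame["passed"] = frame["rhat"] < self.threshold
        return frame


def convergence_report(
    samples: PosteriorSamples,
    threshold: float = 1.1,
    density_points: int = 128,
) -> ConvergenceReport:
    """Assemble the standard diagnostic bundle for a posterior run.

    Per slot: Gelman-Rubin R-hat, lag-1 autocorrelation of the stored
    (thinned) draws — computed within each chain and averaged over chains,
    the usual way a common autocorrelation is estimated from multiple
    chains — a Gaussian kernel density of the pooled draws (Silverman
    bandwidth), and per-chain trace series.
    """
    psrf = gelman_rubin(samples, threshold=threshold)
    pooled = samples.pooled()
    lag1 = []
    density: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    trace: dict[str, np.ndarray] = {}
    for j, name in enumerate(samples.names):
        if samples.thin_lag_acf is not None:
            # thinning-lag ACF estimated from the full-resolution chain
            lag1.append(float(samples.thin_lag_acf[:, j].mean()))
        else:
            per_chain = [
                autocorrelation(samples.draws[c, :, j], 1)[1]
                for c in range(samples.n_chains)
            ]
            lag1.append(float(np.mean(per_chain)))
        x = pooled[:, j]
        grid = np.linspace(x.min(), x.max(), density_points)
        if x.std() > 0:
            kde = gaussian_kde(x, bw_method="silverman")
            density[name] = (grid, kde(grid))
        else:
            density[name] = (grid, np.zeros_like(grid))
        trace[name] = samples.draws[:, :, j].copy()
    lag1_frame = pd.DataFrame(
        {"slot": samples.names, "lag1_acf": lag1}
    ).set_index("slot")
    return ConvergenceReport(
        psrf=psrf,
        lag1_acf=lag1_frame,
        density=density,
        trace=trace,
        threshold=threshold,
    )
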