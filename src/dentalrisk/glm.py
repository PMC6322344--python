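"""From-first-principles maximum-likelihood fitters with Wald inference.

Three binary-outcome regressions share one Newton-Raphson core:

* :class:`LogisticModel` — logit link, binomial likelihood; ``exp(beta)``
  is an odds ratio.
* :class:`LogBinomialModel` — log link, binomial likelihood; ``exp(beta)``
  is a risk ratio.  The log link constrains fitted probabilities below 1,
  so steps are halved whenever a proposal leaves the parameter space, and
  an optimum on the boundary is reported as non-converged rather than as a
  silently wrong answer.
* :class:`RobustPoissonModel` — Poisson working likelihood on the binary
  outcome (the "modified Poisson" risk-ratio estimator) with HC0 sandwich
  standard errors ``A^-1 B A^-1``.

Each model's ``fit()`` returns a :class:`ClassicalResults` carrying
estimates, standard errors, Wald z/p/intervals and effect measures.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from dentalrisk.cohort import DEFAULT_CODING, Cohort, CodingScheme, DesignMatrix, encode

__all__ = [
    "ClassicalResults",
    "LogisticModel",
    "LogBinomialModel",
    "RobustPoissonModel",
    "RankDeficientError",
    "SeparationError",
    "ConvergenceError",
    "wald_summary",
]

#: Separation guard: no plausible epidemiological log-effect exceeds this.
SEPARATION_BOUND = 30.0

MAX_HALVINGS = 20


class RankDeficientError(ValueError):
    """The design matrix does not have full column rank."""


class SeparationError(RuntimeError):
    """Estimates diverged, indicating (quasi-)complete separation."""


class ConvergenceError(RuntimeError):
    """Raised only for invalid optimizer settings, never for boundary MLEs."""


@dataclasses.dataclass
class ClassicalResults:
    """Estimates and Wald inference from one classical fit.

    Attributes
    ----------
    params, bse
        Coefficient estimates and standard errors, indexed by slot name.
    effect_label
        ``"OR"`` for the logistic model, ``"RR"`` otherwise; the effect
        measure is ``exp(params)``.
    """

    model_name: str
    params: pd.Series
    bse: pd.Series
    converged: bool
    n_iter: int
    llf: float
    effect_label: str
    message: str = ""
    cov_params: np.ndarray | None = None

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())),
            index=self.params.index,
        )

    @property
    def effect_measures(self) -> pd.Series:
        """exp(estimate): OR or RR per slot."""
        return np.exp(self.params)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald interval ``estimate +/- z * SE`` per slot."""
        if not 0.0 < level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")
        z = stats.norm.ppf(0.5 * (1.0 + level))
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def to_frame(self, level: float = 0.95) -> pd.DataFrame:
        ci = self.conf_int(level)
        return pd.DataFrame(
            {
                "slot": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "z": self.zvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
                "lower": ci["lower"].to_numpy(),
                "upper": ci["upper"].to_numpy(),
                "effect_measure": self.effect_measures.to_numpy(),
            }
        )

    def summary(self, level: float = 0.95) -> str:
        frame = self.to_frame(level)
        header = (
            f"{self.model_name} regression  "
            f"(converged={self.converged}, iterations={self.n_iter}, "
            f"log-likelihood={self.llf:.4f})\n"
            f"effect measure: {self.effect_label} = exp(estimate)\n"
        )
        return header + frame.to_string(index=False, float_format="%.4f")


def wald_summary(results: ClassicalResults, level: float = 0.95) -> pd.DataFrame:
    """Augment a fit with Wald intervals and p-values at the given level."""
    if not results.converged:
        raise ValueError("Wald inference requires a converged fit")
    return results.to_frame(level)


class _NewtonModel:
    """Shared Newton-Raphson machinery over a design matrix."""

    model_name: str = ""
    effect_label: str = ""

    def __init__(self, y: np.ndarray, X: np.ndarray, names=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per outcome")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficientError(
                "design matrix is rank-deficient; drop collinear columns"
            )
        self.y = y
        self.X = X
        self.names = (
            list(names)
            if names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, scheme: CodingScheme = DEFAULT_CODING
    ):
        design = encode(cohort, scheme)
        return cls.from_design(design)

    @classmethod
    def from_design(cls, design: DesignMatrix):
        return cls(design.y, design.X, names=design.columns)

    # subclass contract -----------------------------------------------------
    def _loglik(self, beta: np.ndarray) -> float:
        raise NotImplementedError

    def _score(self, beta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _information(self, beta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _start(self) -> np.ndarray:
        return np.zeros(self.X.shape[1])

    def _valid(self, beta: np.ndarray) -> bool:
        return True

    def _covariance(self, beta: np.ndarray) -> np.ndarray:
        return np.linalg.inv(self._information(beta))

    # -----------------------------------------------------------------------
    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> ClassicalResults:
        """Newton-Raphson with step-halving; converged when the score's
        largest absolute entry falls below ``tol``."""
        if tol <= 0 or max_iter < 1:
            raise ConvergenceError("tol must be positive and max_iter >= 1")
        beta = self._start()
        if not self._valid(beta):
            raise ConvergenceError("starting values outside the parameter space")
        ll = self._loglik(beta)
        converged = False
        message = ""
        it = 0
        for it in range(1, max_iter + 1):
            score = self._score(beta)
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            info = self._information(beta)
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                message = "singular information matrix"
                break
            # halve until the step stays in the parameter space and does not
            # decrease the log-likelihood
            accepted = False
            for _ in range(MAX_HALVINGS + 1):
                candidate = beta + step
                if self._valid(candidate):
                    ll_new = self._loglik(candidate)
                    if ll_new >= ll - 1e-12:
                        beta, ll = candidate, ll_new
                        accepted = True
                        break
                step *= 0.5
            if not accepted:
                message = (
                    "step-halving exhausted; optimum at or near the "
                    "parameter-space boundary"
                )
                break
            if np.max(np.abs(beta)) > SEPARATION_BOUND:
                raise SeparationError(
                    "estimate magnitude exceeded "
                    f"{SEPARATION_BOUND}; data are (quasi-)separated"
                )
        else:
            message = f"score not below tol after {max_iter} iterations"
        if converged:
            score = self._score(beta)
            if np.max(np.abs(score)) >= tol:  # pragma: no cover - safety
                converged = False
        cov = self._covariance(beta)
        se = np.sqrt(np.diag(cov))
        return ClassicalResults(
            model_name=self.model_name,
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(se, index=self.names),
            converged=converged,
            n_iter=it,
            llf=float(ll),
            effect_label=self.effect_label,
            message=message,
            cov_params=cov,
        )


class LogisticModel(_NewtonModel):
    """Binary logistic regression (logit link, binomial likelihood)."""

    model_name = "logistic"
    effect_label = "OR"

    def _loglik(self, beta):
        eta = self.X @ beta
        return float(self.y @ eta - np.logaddexp(0.0, eta).sum())

    def _score(self, beta):
        p = expit(self.X @ beta)
        return self.X.T @ (self.y - p)

    def _information(self, beta):
        p = expit(self.X @ beta)
        w = p * (1.0 - p)
        return (self.X * w[:, None]).T @ self.X


class LogBinomialModel(_NewtonModel):
    """Log-binomial regression: binomial likelihood with a log link.

    Fitted probabilities ``exp(eta)`` must stay below 1, so the iteration
    starts at an interior point (intercept ``ln p-bar``, slopes 0), halves
    any step that leaves the space, and flags boundary optima via
    ``converged=False`` instead of raising.
    """

    model_name = "log-binomial"
    effect_label = "RR"

    def _start(self):
        beta = np.zeros(self.X.shape[1])
        pbar = self.y.mean()
        beta[0] = np.log(pbar) if 0.0 < pbar < 1.0 else -0.1
        if not self._valid(beta):  # no intercept column of ones
            beta = np.full(self.X.shape[1], -1.0 / self.X.shape[1])
        return beta

    def _valid(self, beta):
        return bool(np.all(self.X @ beta < 0.0))

    def _loglik(self, beta):
        eta = self.X @ beta
        ll = float(self.y @ eta)
        mask = self.y < 1.0
        if mask.any():
            with np.errstate(divide="ignore"):
                # -inf (fitted probability 1 on a failure) rejects the step
                ll += float(np.log1p(-np.exp(eta[mask])).sum())
        return ll

    def _score(self, beta):
        p = np.exp(self.X @ beta)
        return self.X.T @ ((self.y - p) / (1.0 - p))

    def _information(self, beta):
        # Fisher (expected) information for the log link: w = p / (1 - p)
        p = np.exp(self.X @ beta)
        w = p / (1.0 - p)
        return (self.X * w[:, None]).T @ self.X


class RobustPoissonModel(_NewtonModel):
    """Poisson regression on a binary outcome with sandwich (HC0) errors.

    The Poisson log-link score is unbiased for the log risk, so point
    estimates are consistent risk-ratio estimates; model-based Poisson
    variances are wrong for Bernoulli data, hence SEs come from
    ``A^-1 B A^-1`` with ``A`` the model-based information and ``B`` the
    outer product of per-record scores.
    """

    model_name = "robust-poisson"
    effect_label = "RR"

    def _start(self):
        beta = np.zeros(self.X.shape[1])
        pbar = self.y.mean()
        beta[0] = np.log(pbar) if pbar > 0 else -0.1
        return beta

    def _loglik(self, beta):
        eta = self.X @ beta
        return float(self.y @ eta - np.exp(eta).sum())

    def _score(self, beta):
        mu = np.exp(self.X @ beta)
        return self.X.T @ (self.y - mu)

    def _information(self, beta):
        mu = np.exp(self.X @ beta)
        return (self.X * mu[:, None]).T @ self.X

    def _covariance(self, beta):
        mu = np.exp(self.X @ beta)
        A = self._information(beta)
        resid2 = (self.y - mu) ** 2
        B = (self.X * resid2[:, None]).T @ self.X
        A_inv = np.linalg.inv(A)
        return A_inv @ B @ A_inv
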