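"""Unpenalised logistic regression and the performance metrics built on it.

Everything downstream of the data-generating machinery rests on four
primitives: a maximum-likelihood logistic fit, the likelihood-ratio based
Cox-Snell :math:`R^2`, the concordance (C) statistic, and the calibration
slope.  The fit is a plain Newton/IRLS iteration written against numpy --
the simulation engines perform on the order of a million refits per run,
so per-call overhead matters and convergence/separation policy must be
under our control (non-convergent fits are *flagged*, not raised, and the
exclusion rules decide their fate downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata

__all__ = [
    "FittedModel",
    "PerformanceMetrics",
    "fit_logistic",
    "cox_snell_r2",
    "c_statistic",
    "calibration_slope",
    "apparent_performance",
]

# Predicted risks are clipped into this open interval before taking logits,
# so near-degenerate predictions from badly overfit models yield finite
# linear predictors rather than infinities.
_P_CLIP = 1e-12


@dataclass
class FittedModel:
    """Maximum-likelihood logistic coefficients with fit diagnostics.

    ``lr`` is the likelihood-ratio statistic
    ``-2 (lnL_null - lnL_model)`` comparing the fitted model against the
    intercept-only model on the same data.
    """

    intercept: float
    coefficients: np.ndarray
    loglik_model: float
    loglik_null: float
    converged: bool
    n: int

    @property
    def lr(self) -> float:
        val = -2.0 * (self.loglik_null - self.loglik_model)
        # the model nests the null; tiny negatives are rounding noise
        return max(val, 0.0)

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + x @ self.coefficients

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted event probabilities for rows of ``x``."""
        return expit(self.linear_predictor(x))

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coefficients": [float(b) for b in self.coefficients],
            "loglik_model": float(self.loglik_model),
            "loglik_null": float(self.loglik_null),
            "converged": bool(self.converged),
            "n": int(self.n),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            loglik_model=float(d["loglik_model"]),
            loglik_null=float(d["loglik_null"]),
            converged=bool(d["converged"]),
            n=int(d["n"]),
        )


@dataclass
class PerformanceMetrics:
    """Discrimination and calibration summary for one model on one dataset."""

    c_stat: float
    r2_cs: float
    calibration_slope: float = field(default=float("nan"))
    calibration_intercept: float = field(default=float("nan"))


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def null_loglik(y: np.ndarray) -> float:
    """Closed-form log-likelihood of the intercept-only logistic model."""
    n = y.shape[0]
    pbar = float(np.mean(y))
    if pbar <= 0.0 or pbar >= 1.0:
        raise ValueError("outcome vector is constant; null model undefined")
    return n * (pbar * math.log(pbar) + (1.0 - pbar) * math.log(1.0 - pbar))


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    *,
    columns: np.ndarray | list[int] | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    gtol: float = 1e-8,
    separation_bound: float = 50.0,
) -> FittedModel:
    """Fit ``y ~ 1 + x[:, columns]`` by Newton-Raphson (IRLS).

    Parameters
    ----------
    x : (n, q) design matrix *without* an intercept column.
    y : binary outcome vector.
    columns : optional subset of predictor columns to use (e.g. the
        measured predictors of a scenario); defaults to all columns.
    start : optional warm-start values ``[intercept, coef...]`` -- the
        bootstrap loop starts each refit at the original fit, roughly
        halving the iteration count.
    gtol : convergence threshold on the infinity norm of the score.
    separation_bound : a fitted coefficient whose magnitude exceeds this
        on the standardised scale (|b_j| * sd(x_j)) marks (quasi-)complete
        separation; the fit is flagged ``converged=False``.

    Raises
    ------
    ValueError
        If the outcome is constant (all events or all non-events).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be a 2-d array")
    if columns is not None:
        x = x[:, list(columns)]
    n, q = x.shape
    if q < 1:
        raise ValueError("at least one predictor column is required")
    ll0 = null_loglik(y)  # raises on constant y

    xd = np.empty((n, q + 1), dtype=float)
    xd[:, 0] = 1.0
    xd[:, 1:] = x

    if start is not None:
        b = np.asarray(start, dtype=float).copy()
        if b.shape != (q + 1,):
            raise ValueError("start must have length q+1 (intercept first)")
    else:
        b = np.zeros(q + 1)
        b[0] = logit(np.clip(np.mean(y), _P_CLIP, 1.0 - _P_CLIP))

    eta = xd @ b
    ll = _bernoulli_loglik(eta, y)
    converged = False
    for _ in range(max_iter):
        p = expit(eta)
        grad = xd.T @ (y - p)
        if np.abs(grad).max() <= gtol:
            converged = True
            break
        w = p * (1.0 - p)
        hess = (xd * w[:, None]).T @ xd
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the iteration monotone in the likelihood
        new_b = b + step
        new_eta = xd @ new_b
        new_ll = _bernoulli_loglik(new_eta, y)
        halvings = 0
        while new_ll < ll - 1e-10 and halvings < 25:
            step *= 0.5
            new_b = b + step
            new_eta = xd @ new_b
            new_ll = _bernoulli_loglik(new_eta, y)
            halvings += 1
        b, eta, ll = new_b, new_eta, new_ll
        if np.abs(step).max() < 1e-12:
            # stalled; the gradient check above decides the flag next pass
            p = expit(eta)
            converged = bool(np.abs(xd.T @ (y - p)).max() <= gtol)
            break

    if converged:
        sd = x.std(axis=0)
        sd[sd == 0.0] = 1.0
        if np.any(np.abs(b[1:]) * sd > separation_bound):
            converged = False

    return FittedModel(
        intercept=float(b[0]),
        coefficients=b[1:].copy(),
        loglik_model=ll,
        loglik_null=ll0,
        converged=converged,
        n=n,
    )


def cox_snell_r2(lr: float, n: int) -> float:
    """Cox-Snell generalised :math:`R^2 = 1 - \\exp(-LR/n)`.

    Tiny negative ``lr`` (within -1e-8, rounding noise from the two
    log-likelihood evaluations) is clamped to zero; anything more negative
    is an error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if lr < -1e-8:
        raise ValueError(f"likelihood-ratio statistic is negative ({lr})")
    lr = max(lr, 0.0)
    return 1.0 - math.exp(-lr / n)


def c_statistic(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Concordance probability (area under the ROC curve).

    The probability, over all event/non-event pairs, that the event
    carries the higher predicted risk; ties count one half.  Computed via
    midranks in O(n log n).
    """
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    n1 = float(np.sum(y))
    n0 = float(y.shape[0] - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic requires at least one event and one non-event")
    ranks = rankdata(p_hat, method="average")
    rank_sum_events = float(np.sum(ranks[y == 1]))
    return (rank_sum_events - n1 * (n1 + 1.0) / 2.0) / (n1 * n0)


def calibration_slope(
    p_hat: np.ndarray,
    y: np.ndarray,
    *,
    return_model: bool = False,
) -> tuple[float, float] | tuple[float, float, FittedModel]:
    """Calibration slope (and intercept) of predicted risks against outcomes.

    Fits ``logit P(Y=1) = a + s * logit(p_hat)`` by maximum likelihood and
    returns ``(s, a)``.  A slope of 1 means the spread of the predictions
    matches the observed outcomes; below 1 the predictions are too extreme
    (the overfitting signature).
    """
    p_hat = np.clip(np.asarray(p_hat, dtype=float), _P_CLIP, 1.0 - _P_CLIP)
    lp = logit(p_hat)
    if np.ptp(lp) < 1e-12:
        raise ValueError("logit of predictions is constant; slope unidentifiable")
    fit = fit_logistic(lp[:, None], y)
    slope = float(fit.coefficients[0])
    intercept = float(fit.intercept)
    if return_model:
        return slope, intercept, fit
    return slope, intercept


def apparent_performance(model: FittedModel, x: np.ndarray, y: np.ndarray) -> PerformanceMetrics:
    """C-statistic and Cox-Snell R2 of ``model`` evaluated on ``(x, y)``.

    When ``(x, y)`` is the data the model was fitted on, these are the
    apparent (optimistic) metrics; the calibration slope is omitted there
    because the score equations force it to 1.
    """
    p_hat = model.predict(x)
    return PerformanceMetrics(
        c_stat=c_statistic(p_hat, y),
        r2_cs=cox_snell_r2(model.lr, model.n),
    )
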