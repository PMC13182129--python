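"""Minimum sample size for developing a logistic risk-prediction model.

Two procedures targeting a pre-specified global shrinkage level S:

* the analytic criterion ``N = p / ((S-1) * ln(1 - R2_cs/S))``, which
  targets the *heuristic* shrinkage factor, with a simulation-based
  conversion from an anticipated C-statistic (plus outcome prevalence) to
  the anticipated Cox-Snell R2 it needs; and

* an iterative simulation-based search: repeatedly simulate development
  cohorts of candidate size n (p standard-normal predictors whose
  coefficients are calibrated so the true model attains the anticipated
  C-statistic at the anticipated prevalence), fit unpenalised models,
  measure the calibration slope in fresh validation cohorts, and find the
  n whose mean slope -- the mean *optimal* shrinkage -- equals the target.

The analytic route is cheap but inherits any bias of the heuristic
estimator; the simulation route targets the optimal shrinkage directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .glm import calibration_slope, cox_snell_r2, fit_logistic

__all__ = [
    "SampleSizeSpec",
    "SearchSettings",
    "riley_n",
    "c_to_r2",
    "sigma_for_c",
    "intercept_for_prevalence",
    "model_c",
    "pavlou_nsim",
]

# Gauss-Hermite grid (probabilists' weight) for expectations over a
# normal linear predictor; 301 nodes is far beyond what the smooth
# integrands here need.
_GH_T, _GH_W = np.polynomial.hermite_e.hermegauss(301)
_GH_W = _GH_W / _GH_W.sum()


@dataclass
class SampleSizeSpec:
    """Inputs to a sample-size calculation.

    Either an anticipated Cox-Snell R2 (``r2_adj``) or an anticipated
    C-statistic with the outcome prevalence must be supplied; the latter
    pair is converted to an R2 when the analytic criterion needs one.
    """

    p: int
    s_target: float = 0.9
    r2_adj: float | None = None
    c_expected: float | None = None
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not (0.0 < self.s_target < 1.0):
            raise ValueError("s_target must lie in (0, 1)")
        if self.r2_adj is None and (self.c_expected is None or self.prevalence is None):
            raise ValueError("supply r2_adj, or c_expected together with prevalence")


@dataclass
class SearchSettings:
    """Controls for the simulation-based sample-size search."""

    m_per_eval: int = 500      # replicates per candidate-n evaluation
    validation_n: int = 100_000
    tolerance: float = 0.005   # on the final mean calibration slope
    max_evals: int = 40
    rel_width: float = 0.02    # stop bisection when the bracket is this narrow
    n_min: int = 20


def riley_n(p: int, r2_adj: float, s_target: float = 0.9) -> int:
    """Analytic minimum sample size targeting heuristic shrinkage ``s_target``.

    ``N = p / ((S - 1) * ln(1 - R2/S))``, rounded up to whole participants.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not (0.0 < s_target < 1.0):
        raise ValueError("s_target must lie in (0, 1)")
    if r2_adj <= 0.0:
        raise ValueError("r2_adj must be positive")
    if r2_adj >= s_target:
        raise ValueError("r2_adj must be smaller than s_target (log argument <= 0)")
    return math.ceil(p / ((s_target - 1.0) * math.log(1.0 - r2_adj / s_target)))


def c_to_r2(
    c: float,
    prevalence: float,
    sim_n: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Anticipated Cox-Snell R2 from an anticipated C-statistic.

    Simulates the standard binormal equal-variance model: with
    ``sigma = sqrt(2) * Phi^{-1}(C)``, linear-predictor values are
    N(0, sigma^2) for non-events and N(sigma^2, sigma^2) for events (the
    construction under which the true outcome model is exactly logistic
    with slope 1 and the C-statistic is exactly C).  A logistic model is
    fitted to the simulated cohort and ``R2 = 1 - exp(-LR/n)`` returned.
    """
    if not (0.5 < c < 1.0):
        raise ValueError("c must lie in (0.5, 1)")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    sigma = math.sqrt(2.0) * float(ndtri(c))
    n1 = int(round(prevalence * sim_n))
    n0 = sim_n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError("sim_n too small for this prevalence")
    lp = np.concatenate(
        [rng.normal(0.0, sigma, size=n0), rng.normal(sigma**2, sigma, size=n1)]
    )
    y = np.concatenate([np.zeros(n0), np.ones(n1)])
    fit = fit_logistic(lp[:, None], y, gtol=1e-6 * sim_n**0.5)
    return cox_snell_r2(fit.lr, sim_n)


def intercept_for_prevalence(sigma: float, prevalence: float) -> float:
    """Intercept a with E[expit(a + L)] = prevalence for L ~ N(0, sigma^2)."""
    if sigma == 0.0:
        return float(np.log(prevalence / (1.0 - prevalence)))
    return float(
        brentq(
            lambda a: float(np.sum(_GH_W * expit(a + sigma * _GH_T))) - prevalence,
            -50.0,
            50.0,
        )
    )


def model_c(sigma: float, prevalence: float) -> float:
    """Exact C-statistic of the logistic model with LP ~ N(0, sigma^2).

    Computed by quadrature: each LP node carries event mass p and
    non-event mass 1-p, and the concordance is the probability that a
    random event outranks a random non-event on the linear predictor.
    """
    a = intercept_for_prevalence(sigma, prevalence)
    p = expit(a + sigma * _GH_T)
    pw = _GH_W * p
    qw = _GH_W * (1.0 - p)
    cum_q = np.cumsum(qw) - qw
    return float((np.sum(pw * cum_q) + 0.5 * np.sum(pw * qw)) / (pw.sum() * qw.sum()))


def sigma_for_c(c: float, prevalence: float) -> float:
    """Linear-predictor standard deviation giving exact model C-statistic c."""
    if not (0.5 < c < 1.0):
        raise ValueError("c must lie in (0.5, 1)")
    return float(brentq(lambda s: model_c(s, prevalence) - c, 1e-6, 20.0))


def _mean_sopt(
    n: int,
    p: int,
    beta: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    m: int,
    validation_n: int,
) -> tuple[float, float, int]:
    """Mean calibration slope of models of p iid-normal predictors fitted at
    size n, each validated on a fresh simulated cohort.

    Returns (mean, sd across replicates, replicate count)."""
    vals = []
    for _ in range(m):
        x = rng.standard_normal((n, p))
        y = (rng.random(n) < expit(alpha + x @ beta)).astype(float)
        s = y.sum()
        if s < 2 or s > n - 2:
            continue
        fit = fit_logistic(x, y)
        if not fit.converged:
            continue
        xv = rng.standard_normal((validation_n, p))
        yv = (rng.random(validation_n) < expit(alpha + xv @ beta)).astype(float)
        try:
            slope, _ = calibration_slope(fit.predict(xv), yv)
        except ValueError:
            continue
        vals.append(slope)
    if not vals:
        return float("nan"), float("nan"), 0
    arr = np.asarray(vals)
    return float(arr.mean()), float(arr.std()), len(vals)


def pavlou_nsim(
    spec: SampleSizeSpec,
    settings: SearchSettings | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, bool]:
    """Simulation-based minimum sample size targeting mean optimal shrinkage.

    The data-generating model has ``p`` independent standard-normal
    predictors with equal coefficients, scaled so the *exact* population
    C-statistic of the true model equals ``c_expected`` at the stated
    prevalence (solved by quadrature).  For a candidate size n, ``m``
    development cohorts are simulated and fitted, each model's calibration
    slope is measured on a fresh validation cohort, and the mean slope
    estimates the expected optimal shrinkage at that n.  The search
    brackets the target starting from the analytic criterion's answer and
    then bisects (geometrically).  Because the mean-slope curve is shallow
    in n, single evaluations are noisy guides near the root; the final
    candidate therefore comes from a replicate-weighted local linear fit
    through all evaluations near the bracket (pooling their Monte-Carlo
    information) and is re-evaluated with doubled replicates --
    ``converged`` records whether that final mean slope lies within
    tolerance of the target.

    Returns ``(n, converged)``; a failed search returns its best candidate
    with ``converged=False`` rather than raising.
    """
    settings = settings or SearchSettings()
    rng = rng if rng is not None else np.random.default_rng()
    if spec.c_expected is None or spec.prevalence is None:
        raise ValueError("the simulation-based search needs c_expected and prevalence")
    if not (0.0 < spec.s_target < 1.0):
        raise ValueError("s_target must lie in (0, 1); the required n is unbounded at 1")
    p, target = spec.p, spec.s_target
    sigma = sigma_for_c(spec.c_expected, spec.prevalence)
    alpha = intercept_for_prevalence(sigma, spec.prevalence)
    beta = np.full(p, sigma / math.sqrt(p))

    # seed the search at the analytic criterion's answer (cheap conversion)
    try:
        r2_seed = c_to_r2(spec.c_expected, spec.prevalence, sim_n=200_000, rng=rng)
        n0 = riley_n(p, r2_seed, target)
    except ValueError:
        n0 = max(settings.n_min, 20 * p)
    n0 = max(n0, settings.n_min, p + 5)

    evals = 0
    history: list[tuple[int, float, int]] = []  # (n, mean slope - target, m)

    def f(n: int, m: int) -> float:
        nonlocal evals
        evals += 1
        mean, _, k = _mean_sopt(n, p, beta, alpha, rng, m, settings.validation_n)
        val = mean - target
        if not math.isnan(val):
            history.append((n, val, k))
        return val

    m = settings.m_per_eval
    f0 = f(n0, m)
    if math.isnan(f0):
        return n0, False

    n_lo = n_hi = n0
    f_lo = f_hi = f0
    grow = 1.4
    while f_hi < 0.0:  # mean slope below target: need more data
        if evals >= settings.max_evals:
            return n_hi, False
        n_lo, f_lo = n_hi, f_hi
        n_hi = int(math.ceil(n_hi * grow))
        f_hi = f(n_hi, m)
        if math.isnan(f_hi):
            return n_lo, False
    while f_lo > 0.0:  # mean slope above target: less data suffices
        if evals >= settings.max_evals:
            return n_lo, False
        n_hi, f_hi = n_lo, f_lo
        n_lo = max(settings.n_min, int(math.floor(n_lo / grow)))
        f_lo = f(n_lo, m)
        if math.isnan(f_lo) or (n_lo == settings.n_min and f_lo > 0.0):
            # even the smallest admissible cohort overshoots the target
            return n_lo, False

    while (n_hi - n_lo) > max(2.0, settings.rel_width * n_hi):
        if evals >= settings.max_evals:
            break
        n_mid = int(round(math.sqrt(n_lo * n_hi)))
        f_mid = f(n_mid, m)
        if math.isnan(f_mid):
            return n_mid, False
        if f_mid < 0.0:
            n_lo, f_lo = n_mid, f_mid
        else:
            n_hi, f_hi = n_mid, f_mid

    n_final = _pooled_root(history, n_lo, n_hi)
    # final check: grow replicates until the Monte-Carlo error is small
    # relative to the tolerance (capped at a 10x budget), then ask whether
    # the mean slope is within tolerance of the target up to that error
    means: list[float] = []
    sds: list[float] = []
    counts: list[int] = []
    budget = 10 * m
    m_step = 2 * m
    while True:
        mean, sd, k = _mean_sopt(n_final, p, beta, alpha, rng, m_step,
                                 settings.validation_n)
        if k == 0:
            return n_final, False
        means.append(mean)
        sds.append(sd)
        counts.append(k)
        total = sum(counts)
        se = math.sqrt(sum(c * s**2 for c, s in zip(counts, sds))) / total
        if se <= settings.tolerance / 2.0 or total >= budget:
            break
        m_step = min(m_step, budget - total)
    pooled = sum(c * v for c, v in zip(counts, means)) / sum(counts)
    converged = abs(pooled - target) <= settings.tolerance + 2.0 * se
    return n_final, converged


def _pooled_root(
    history: list[tuple[int, float, int]], n_lo: int, n_hi: int
) -> int:
    """Root of a replicate-weighted linear fit through nearby evaluations.

    Pools the Monte-Carlo information from every evaluation within a
    window around the final bracket; falls back to the geometric bracket
    midpoint when the pooled fit is degenerate or non-increasing.
    """
    n_mid = math.sqrt(n_lo * n_hi)
    pts = [(n, v, m) for n, v, m in history if 0.7 * n_mid <= n <= 1.45 * n_mid]
    if len(pts) >= 3:
        ns = np.array([q[0] for q in pts], dtype=float)
        vs = np.array([q[1] for q in pts], dtype=float)
        ws = np.array([q[2] for q in pts], dtype=float)
        wmean_n = np.average(ns, weights=ws)
        wmean_v = np.average(vs, weights=ws)
        sxx = float(np.sum(ws * (ns - wmean_n) ** 2))
        if sxx > 0.0:
            slope = float(np.sum(ws * (ns - wmean_n) * (vs - wmean_v))) / sxx
            if slope > 0.0:
                root = wmean_n - wmean_v / slope
                return int(round(min(max(root, 0.85 * n_lo), 1.15 * n_hi)))
    return int(round(n_mid))


def analytic_n(spec: SampleSizeSpec, rng: np.random.Generator | None = None,
               sim_n: int = 1_000_000) -> tuple[int, float]:
    """Analytic minimum sample size from a spec, deriving R2 from C if needed.

    Returns ``(n, r2_used)``.
    """
    if spec.r2_adj is not None:
        r2 = spec.r2_adj
    else:
        r2 = c_to_r2(spec.c_expected, spec.prevalence, sim_n=sim_n, rng=rng)
    return riley_n(spec.p, r2, spec.s_target), r2
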