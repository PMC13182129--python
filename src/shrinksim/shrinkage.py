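"""The three global shrinkage quantities.

After fitting an unpenalised logistic model, a global shrinkage factor S
multiplies all predictor coefficients to pull predictions toward the mean.
The optimal value ``S_opt`` makes the calibration slope 1 in the target
population; it is unknowable at development time and is estimated either
by the closed-form heuristic ``S_vh = 1 - Q/LR`` or by the bootstrap
uniform shrinkage ``S_boot`` (mean calibration slope, in the original
data, of models refitted on bootstrap resamples).

No truncation is applied anywhere: negative heuristic estimates (LR < Q)
and bootstrap means above 2 are real behaviours of the estimators in
high-noise settings and must propagate to the exclusion stage untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import FittedModel, calibration_slope, fit_logistic

__all__ = ["ShrinkageRecord", "s_vh", "s_boot", "s_opt"]


@dataclass
class ShrinkageRecord:
    """Per-iteration shrinkage estimates and apparent performance."""

    iteration_index: int
    s_vh: float
    s_boot: float
    s_opt: float
    c_app: float
    r2_app: float
    boot_failures: int


def s_vh(q: int, lr: float) -> float:
    """Heuristic shrinkage ``1 - Q/LR`` (Q predictor parameters, no intercept).

    Undefined at LR = 0; may be negative when LR < Q.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if lr == 0.0:
        raise ValueError("heuristic shrinkage is undefined at LR = 0")
    return 1.0 - q / lr


def s_boot(
    x: np.ndarray,
    y: np.ndarray,
    b: int = 200,
    rng: np.random.Generator | None = None,
    *,
    start: np.ndarray | None = None,
) -> tuple[float, int]:
    """Bootstrap uniform shrinkage factor.

    For each of ``b`` replicates: resample rows with replacement to the
    original size, refit the logistic model on the replicate, predict on
    the *original* data and take the calibration slope there.  The
    estimate is the mean slope over replicates whose refit converged; a
    replicate with a constant resampled outcome or a non-convergent refit
    counts as a failure and is dropped from the mean.

    Parameters
    ----------
    start : optional warm-start coefficients ``[intercept, coef...]``
        (typically the original fit) passed to every refit.

    Returns
    -------
    (mean slope, number of failed replicates)
    """
    if b < 1:
        raise ValueError("at least one bootstrap replicate is required")
    rng = rng if rng is not None else np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    slopes = []
    failures = 0
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        s = float(yb.sum())
        if s == 0.0 or s == n:
            failures += 1
            continue
        fit = fit_logistic(x[idx], yb, start=start)
        if not fit.converged:
            failures += 1
            continue
        try:
            slope, _ = calibration_slope(fit.predict(x), y)
        except ValueError:
            failures += 1
            continue
        slopes.append(slope)
    if not slopes:
        raise RuntimeError("every bootstrap replicate failed")
    return float(np.mean(slopes)), failures


def s_opt(model: FittedModel, x_val: np.ndarray, y_val: np.ndarray) -> float:
    """Optimal shrinkage: calibration slope of ``model`` in a validation cohort.

    The cohort should be large enough that sampling it is effectively
    sampling the population; only the columns the model was fitted on are
    used (pass ``x_val[:, :q_meas]`` when the cohort carries unmeasured
    predictors too).
    """
    slope, _ = calibration_slope(model.predict(x_val), y_val)
    return slope
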