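"""Diagnostic plots: mean-level agreement and within-scenario instability."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_mean_agreement", "plot_instability"]

_COLOR_SELECTORS = {
    "r2_pop": "population Cox-Snell R2",
    "c_pop": "population C-statistic",
    "q_meas": "measured predictors",
    "epp": "events per predictor parameter",
    "n_dev": "development sample size",
}


def plot_mean_agreement(
    scenarios: pd.DataFrame,
    out: str | Path,
    *,
    estimator: str = "mean_s_vh",
    color_by: str = "c_pop",
    c_threshold: float | None = None,
) -> Path:
    """Scatter of mean estimated shrinkage against mean optimal shrinkage.

    One point per kept scenario, with the 45-degree identity line as the
    unbiasedness reference.  ``color_by`` selects the colouring metric;
    ``c_threshold`` instead renders the population C-statistic as two
    groups split at the given value.
    """
    if color_by not in _COLOR_SELECTORS:
        raise ValueError(f"unknown selector {color_by!r}; choose from {sorted(_COLOR_SELECTORS)}")
    if scenarios.empty:
        raise ValueError("no scenarios to plot")
    out = Path(out)
    fig, ax = plt.subplots(figsize=(6, 6))
    x = scenarios[estimator].to_numpy()
    y = scenarios["mean_s_opt"].to_numpy()
    if c_threshold is not None:
        hi = scenarios["c_pop"].to_numpy() >= c_threshold
        ax.scatter(x[~hi], y[~hi], s=8, alpha=0.6, label=f"C_pop < {c_threshold}")
        ax.scatter(x[hi], y[hi], s=8, alpha=0.6, label=f"C_pop >= {c_threshold}")
        ax.legend()
    else:
        sc = ax.scatter(x, y, s=8, alpha=0.7, c=scenarios[color_by].to_numpy())
        fig.colorbar(sc, ax=ax, label=_COLOR_SELECTORS[color_by])
    lims = [min(np.nanmin(x), np.nanmin(y)), max(np.nanmax(x), np.nanmax(y))]
    ax.plot(lims, lims, color="black", lw=1, ls="--")
    ax.set_xlabel(f"{estimator} (per scenario)")
    ax.set_ylabel("mean optimal shrinkage (per scenario)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_instability(
    records: pd.DataFrame,
    scenario_ids: list[int],
    out: str | Path,
    *,
    x_col: str = "s_boot",
    y_col: str = "s_opt",
) -> Path:
    """Per-iteration scatter of optimal against estimated shrinkage.

    One panel per selected scenario, with horizontal guide lines at the
    2.5th, 25th, 50th, 75th and 97.5th percentiles of the optimal
    shrinkage -- the visual signature that the estimator varies far less
    than the quantity it estimates.
    """
    out = Path(out)
    k = len(scenario_ids)
    if k == 0:
        raise ValueError("select at least one scenario")
    ncol = min(3, k)
    nrow = (k + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.5 * nrow), squeeze=False)
    for ax, sid in zip(axes.flat, scenario_ids):
        sub = records[records["scenario_id"] == sid]
        ax.scatter(sub[x_col], sub[y_col], s=8, alpha=0.6)
        for q in np.percentile(sub[y_col], [2.5, 25, 50, 75, 97.5]):
            ax.axhline(q, color="grey", lw=0.8, ls=":")
        ax.set_title(f"scenario {sid}")
        ax.set_xlabel(x_col)
        ax.set_ylabel(y_col)
    for ax in axes.flat[k:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
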