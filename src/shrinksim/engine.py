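"""Monte-Carlo engines for the two simulation studies.

Study 1 asks how well the heuristic and bootstrap shrinkage estimators
track the optimal shrinkage across randomly drawn scenarios: for each
scenario one large validation cohort fixes the population truth (C_pop,
R2_pop), then each iteration develops a model on a fresh development
dataset and records the heuristic, bootstrap and optimal shrinkage.

Study 2 asks whether the two minimum-sample-size procedures actually
deliver the targeted shrinkage of 0.9: per scenario both sample sizes are
computed from the population performance, and each iteration measures the
optimal shrinkage of models developed at each size.

Both studies report per-scenario bias with its Monte-Carlo standard
error, exclude degenerate scenarios by explicit rules (with reasons
recorded, never silently), and summarise across scenarios stratified by
the population C-statistic.

Seeding gives every scenario an independent, reproducible stream derived
from (master seed, study, scenario index), so results are identical
whether scenarios run serially or concurrently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dgm, glm, shrinkage
from .sample_size import SampleSizeSpec, SearchSettings, pavlou_nsim, riley_n

__all__ = [
    "ScenarioResult",
    "Study2Result",
    "StudySettings",
    "scenario_seed_sequence",
    "run_study1_scenario",
    "run_study2_scenario",
    "run_study1",
    "run_study2",
    "scenario_sd",
    "apply_exclusions_study1",
    "apply_exclusions_study2",
    "summarize",
    "DEFAULT_STRATA",
]

DEFAULT_STRATA = tuple(np.round(np.arange(0.55, 0.901, 0.05), 2))


@dataclass
class StudySettings:
    """Scale and policy knobs shared by the study engines."""

    iterations: int = 250
    validation_n: int = 1_000_000
    b_boot: int = 200
    boot_failure_tol: float = 0.05   # scenario-level bootstrap failure rate cut
    target_shrinkage: float = 0.9    # study 2
    n_cap: int = 100_000             # study 2: computed sizes above this are excluded
    nsim_settings: SearchSettings = field(default_factory=SearchSettings)


@dataclass
class ScenarioResult:
    """Study-1 outcome for one scenario."""

    scenario_id: int
    scenario: dgm.Scenario
    c_pop: float
    r2_pop: float
    epp: float
    records: list[shrinkage.ShrinkageRecord]
    fit_failures: int
    bias_vh: float
    bias_boot: float
    sd_vh: float
    sd_boot: float
    mce_vh: float
    mce_boot: float
    mean_s_vh: float
    mean_s_boot: float
    mean_s_opt: float
    mean_r2_app: float
    boot_failure_rate: float
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class Study2Result:
    """Study-2 outcome for one scenario."""

    scenario_id: int
    scenario: dgm.Scenario
    c_pop: float
    r2_pop: float
    n_original: int
    n_sim: int
    nsim_converged: bool
    mean_sopt_original: float
    mean_sopt_sim: float
    bias_original: float
    bias_sim: float
    sd_original: float
    sd_sim: float
    excluded: bool = False
    exclusion_reason: str = ""


def scenario_seed_sequence(master_seed: int, study: int, scenario_index: int,
                           stream: int = 0) -> np.random.SeedSequence:
    """Deterministic, collision-free seed stream for one scenario sub-task."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(study, scenario_index, stream)
    )


def scenario_sd(deviations: np.ndarray) -> float:
    """Standard deviation with divisor n (not n-1), per the reporting formula."""
    d = np.asarray(deviations, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one deviation")
    return float(np.sqrt(np.mean((d - d.mean()) ** 2)))


def _population_fit(scenario: dgm.Scenario, validation: dgm.Dataset):
    """Fit on the validation cohort (measured predictors only) and return
    (fit, c_pop, r2_pop)."""
    xv = validation.x[:, : scenario.q_meas]
    fit = glm.fit_logistic(xv, validation.y, gtol=1e-6 * math.sqrt(validation.n))
    c_pop = glm.c_statistic(fit.predict(xv), validation.y)
    r2_pop = glm.cox_snell_r2(fit.lr, validation.n)
    return fit, c_pop, r2_pop


def run_study1_scenario(
    scenario: dgm.Scenario,
    settings: StudySettings | None = None,
    rng: np.random.Generator | np.random.SeedSequence | None = None,
    *,
    scenario_id: int = 0,
) -> ScenarioResult:
    """Run every iteration of study 1 for one scenario.

    Steps: one validation cohort and a population fit give C_pop and
    R2_pop; then per iteration a development dataset is drawn, an
    unpenalised logistic model fitted on the measured predictors, the
    heuristic and bootstrap shrinkage plus apparent performance computed,
    and the optimal shrinkage measured as the calibration slope in the
    validation cohort.  Iterations whose development fit fails (constant
    outcome or non-convergence) are counted, not silently dropped.
    """
    settings = settings or StudySettings()
    if isinstance(rng, np.random.SeedSequence):
        ss = rng
    elif rng is None:
        ss = scenario_seed_sequence(0, 1, scenario_id)
    else:
        ss = np.random.SeedSequence(int(rng.integers(0, 2**31)))
    children = ss.spawn(settings.iterations + 1)
    chol = np.linalg.cholesky(
        scenario.omega + 1e-12 * np.eye(scenario.q)
    )

    validation = dgm.generate_dataset(
        scenario, settings.validation_n, np.random.default_rng(children[0]), chol=chol
    )
    _, c_pop, r2_pop = _population_fit(scenario, validation)
    x_val_meas = validation.x[:, : scenario.q_meas]

    records: list[shrinkage.ShrinkageRecord] = []
    fit_failures = 0
    events_total = 0.0
    for m in range(settings.iterations):
        it_rng = np.random.default_rng(children[m + 1])
        dev = dgm.generate_dataset(scenario, scenario.n_dev, it_rng, chol=chol)
        events_total += float(dev.y.sum())
        n_events = dev.y.sum()
        if n_events == 0 or n_events == dev.n:
            fit_failures += 1
            continue
        x_meas = dev.x[:, : scenario.q_meas]
        fit = glm.fit_logistic(x_meas, dev.y)
        if not fit.converged:
            fit_failures += 1
            continue
        warm = np.concatenate([[fit.intercept], fit.coefficients])
        try:
            sb, boot_fail = shrinkage.s_boot(
                x_meas, dev.y, settings.b_boot, it_rng, start=warm
            )
        except RuntimeError:
            fit_failures += 1
            continue
        perf = glm.apparent_performance(fit, x_meas, dev.y)
        records.append(
            shrinkage.ShrinkageRecord(
                iteration_index=m,
                s_vh=shrinkage.s_vh(scenario.q_meas, fit.lr) if fit.lr > 0 else float("nan"),
                s_boot=sb,
                s_opt=shrinkage.s_opt(fit, x_val_meas, validation.y),
                c_app=perf.c_stat,
                r2_app=perf.r2_cs,
                boot_failures=boot_fail,
            )
        )

    epp = (events_total / settings.iterations) / scenario.q_meas

    if not records:
        return ScenarioResult(
            scenario_id=scenario_id, scenario=scenario, c_pop=c_pop, r2_pop=r2_pop,
            epp=epp, records=[], fit_failures=fit_failures,
            bias_vh=float("nan"), bias_boot=float("nan"),
            sd_vh=float("nan"), sd_boot=float("nan"),
            mce_vh=float("nan"), mce_boot=float("nan"),
            mean_s_vh=float("nan"), mean_s_boot=float("nan"),
            mean_s_opt=float("nan"), mean_r2_app=float("nan"),
            boot_failure_rate=1.0, excluded=True,
            exclusion_reason="no_valid_iterations",
        )

    vh = np.array([r.s_vh for r in records])
    boot = np.array([r.s_boot for r in records])
    sopt = np.array([r.s_opt for r in records])
    r2app = np.array([r.r2_app for r in records])
    dev_vh = vh - sopt
    dev_boot = boot - sopt
    k = len(records)
    sd_vh_val = scenario_sd(dev_vh)
    sd_boot_val = scenario_sd(dev_boot)
    boot_fail_rate = sum(r.boot_failures for r in records) / (k * settings.b_boot)

    return ScenarioResult(
        scenario_id=scenario_id,
        scenario=scenario,
        c_pop=c_pop,
        r2_pop=r2_pop,
        epp=epp,
        records=records,
        fit_failures=fit_failures,
        bias_vh=float(np.mean(dev_vh)),
        bias_boot=float(np.mean(dev_boot)),
        sd_vh=sd_vh_val,
        sd_boot=sd_boot_val,
        mce_vh=sd_vh_val / math.sqrt(k),
        mce_boot=sd_boot_val / math.sqrt(k),
        mean_s_vh=float(np.mean(vh)),
        mean_s_boot=float(np.mean(boot)),
        mean_s_opt=float(np.mean(sopt)),
        mean_r2_app=float(np.mean(r2app)),
        boot_failure_rate=boot_fail_rate,
    )


def run_study2_scenario(
    scenario: dgm.Scenario,
    settings: StudySettings | None = None,
    rng: np.random.Generator | np.random.SeedSequence | None = None,
    *,
    scenario_id: int = 0,
) -> Study2Result:
    """Run every iteration of study 2 for one scenario.

    The population fit yields C_pop, R2_pop and the realized prevalence;
    the analytic size targets shrinkage 0.9 via R2_pop, the simulation
    size via C_pop.  Each iteration then develops one model at each size
    and records its optimal shrinkage in the validation cohort.
    """
    settings = settings or StudySettings()
    if isinstance(rng, np.random.SeedSequence):
        ss = rng
    elif rng is None:
        ss = scenario_seed_sequence(0, 2, scenario_id)
    else:
        ss = np.random.SeedSequence(int(rng.integers(0, 2**31)))
    children = ss.spawn(settings.iterations + 2)
    chol = np.linalg.cholesky(scenario.omega + 1e-12 * np.eye(scenario.q))

    validation = dgm.generate_dataset(
        scenario, settings.validation_n, np.random.default_rng(children[0]), chol=chol
    )
    _, c_pop, r2_pop = _population_fit(scenario, validation)
    prevalence = float(np.mean(validation.y))
    x_val_meas = validation.x[:, : scenario.q_meas]
    target = settings.target_shrinkage

    def _excluded(reason: str) -> Study2Result:
        return Study2Result(
            scenario_id=scenario_id, scenario=scenario, c_pop=c_pop, r2_pop=r2_pop,
            n_original=0, n_sim=0, nsim_converged=False,
            mean_sopt_original=float("nan"), mean_sopt_sim=float("nan"),
            bias_original=float("nan"), bias_sim=float("nan"),
            sd_original=float("nan"), sd_sim=float("nan"),
            excluded=True, exclusion_reason=reason,
        )

    try:
        n_original = riley_n(scenario.q_meas, r2_pop, target)
    except ValueError:
        return _excluded("riley_criterion_undefined")
    if n_original > settings.n_cap:
        return _excluded("n_original_exceeds_cap")

    if c_pop <= 0.505:
        n_sim, nsim_converged = n_original, False
    else:
        spec = SampleSizeSpec(
            p=scenario.q_meas, s_target=target,
            c_expected=min(c_pop, 0.999), prevalence=prevalence,
        )
        n_sim, nsim_converged = pavlou_nsim(
            spec, settings.nsim_settings, np.random.default_rng(children[1])
        )
    if nsim_converged and n_sim > settings.n_cap:
        return _excluded("n_sim_exceeds_cap")

    sopt_orig: list[float] = []
    sopt_sim: list[float] = []
    for m in range(settings.iterations):
        it_rng = np.random.default_rng(children[m + 2])
        for n, sink in ((n_original, sopt_orig), (n_sim if nsim_converged else 0, sopt_sim)):
            if n <= 0:
                continue
            dev = dgm.generate_dataset(scenario, n, it_rng, chol=chol)
            s = dev.y.sum()
            if s == 0 or s == dev.n:
                continue
            fit = glm.fit_logistic(dev.x[:, : scenario.q_meas], dev.y)
            if not fit.converged:
                continue
            sink.append(shrinkage.s_opt(fit, x_val_meas, validation.y))

    if not sopt_orig:
        return _excluded("no_valid_iterations")

    so = np.array(sopt_orig)
    mean_orig = float(np.mean(so))
    res = Study2Result(
        scenario_id=scenario_id,
        scenario=scenario,
        c_pop=c_pop,
        r2_pop=r2_pop,
        n_original=n_original,
        n_sim=n_sim if nsim_converged else 0,
        nsim_converged=nsim_converged,
        mean_sopt_original=mean_orig,
        mean_sopt_sim=float("nan"),
        bias_original=float(np.mean(so - target)),
        bias_sim=float("nan"),
        sd_original=scenario_sd(so - target),
        sd_sim=float("nan"),
    )
    if nsim_converged and sopt_sim:
        sm = np.array(sopt_sim)
        res.mean_sopt_sim = float(np.mean(sm))
        res.bias_sim = float(np.mean(sm - target))
        res.sd_sim = scenario_sd(sm - target)
    return res


def apply_exclusions_study1(
    results: list[ScenarioResult],
    boot_failure_tol: float = 0.05,
) -> tuple[list[ScenarioResult], list[ScenarioResult]]:
    """Partition study-1 results into kept and excluded-with-reason.

    Exclusion rules: negative mean heuristic, bootstrap or apparent-R2
    estimates; mean bootstrap shrinkage above 2; or a bootstrap failure
    rate beyond tolerance.  Every excluded scenario carries its reason.
    """
    kept: list[ScenarioResult] = []
    excluded: list[ScenarioResult] = []
    for r in results:
        reasons = []
        if r.excluded and r.exclusion_reason:
            reasons.append(r.exclusion_reason)
        elif not r.records:
            reasons.append("no_valid_iterations")
        else:
            if r.mean_s_vh < 0:
                reasons.append("mean_s_vh<0")
            if r.mean_s_boot < 0:
                reasons.append("mean_s_boot<0")
            if r.mean_r2_app < 0:
                reasons.append("mean_r2_app<0")
            if r.mean_s_boot > 2:
                reasons.append("mean_s_boot>2")
            if r.boot_failure_rate > boot_failure_tol:
                reasons.append(f"boot_failure_rate>{boot_failure_tol}")
        if reasons:
            r.excluded = True
            r.exclusion_reason = ";".join(reasons)
            excluded.append(r)
        else:
            kept.append(r)
    return kept, excluded


def apply_exclusions_study2(
    results: list[Study2Result],
) -> tuple[list[Study2Result], list[Study2Result], list[Study2Result]]:
    """Partition study-2 results into (kept-converged, non-converged, excluded).

    A scenario is excluded when a mean optimal shrinkage is negative or
    above 2 (in either arm); scenarios whose simulation-based size did not
    converge are reported as their own stratum, never silently dropped.
    """
    kept: list[Study2Result] = []
    nonconverged: list[Study2Result] = []
    excluded: list[Study2Result] = []
    for r in results:
        reasons = []
        if r.excluded and r.exclusion_reason:
            reasons.append(r.exclusion_reason)
        else:
            for label, v in (("original", r.mean_sopt_original), ("sim", r.mean_sopt_sim)):
                if not math.isnan(v) and (v < 0 or v > 2):
                    reasons.append(f"mean_sopt_{label}_out_of_[0,2]")
        if reasons:
            r.excluded = True
            r.exclusion_reason = ";".join(reasons)
            excluded.append(r)
        elif not r.nsim_converged:
            nonconverged.append(r)
        else:
            kept.append(r)
    return kept, nonconverged, excluded


_PCTS_DEFAULT = (2.5, 25.0, 50.0, 75.0, 97.5)
_PCTS_MCE = (50.0, 90.0, 99.0)


def summarize(
    results: list,
    statistic: str,
    strata: tuple[float, ...] = DEFAULT_STRATA,
    percentiles: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Cross-scenario summary of a per-scenario statistic, stratified by C_pop.

    ``statistic`` names an attribute of the result objects (``bias_vh``,
    ``mce_boot``, ``mean_sopt_sim``, ...) or ``abs_<attr>`` for its
    magnitude.  Returns one row per C_pop stratum plus an "all" row, with
    count, mean, sd (divisor n) and percentiles (linear interpolation
    between order statistics).  Empty strata yield a row with
    ``n_scenarios=0`` and missing statistics.
    """
    if percentiles is None:
        percentiles = _PCTS_MCE if statistic.startswith("mce") else _PCTS_DEFAULT
    attr = statistic
    absolute = False
    if statistic.startswith("abs_"):
        attr = statistic[4:]
        absolute = True

    vals = np.array([getattr(r, attr) for r in results], dtype=float)
    if absolute:
        vals = np.abs(vals)
    cpop = np.array([r.c_pop for r in results], dtype=float)

    edges = list(strata)
    bins: list[tuple[str, np.ndarray]] = [("all", np.ones_like(vals, dtype=bool))]
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (cpop >= lo) & (cpop < hi)
        bins.append((f"{lo:g} <= C_pop < {hi:g}", mask))

    rows = []
    for label, mask in bins:
        v = vals[mask]
        v = v[~np.isnan(v)]
        row: dict = {"stratum": label, "statistic": statistic, "n_scenarios": int(v.size)}
        if v.size == 0:
            row.update({"mean": np.nan, "sd": np.nan})
            for p in percentiles:
                row[_pct_label(p)] = np.nan
        else:
            row["mean"] = float(np.mean(v))
            row["sd"] = scenario_sd(v) if v.size > 1 else 0.0
            qs = np.percentile(v, percentiles)  # linear interpolation
            for p, qv in zip(percentiles, qs):
                row[_pct_label(p)] = float(qv)
        rows.append(row)
    return pd.DataFrame(rows)


def _pct_label(p: float) -> str:
    return "p" + (f"{p:g}".replace(".", "_"))


def run_study1(
    n_scenarios: int,
    master_seed: int,
    scenario_config: dgm.ScenarioConfig | None = None,
    settings: StudySettings | None = None,
) -> list[ScenarioResult]:
    """Draw and run ``n_scenarios`` study-1 scenarios with derived seeds."""
    scenario_config = scenario_config or dgm.ScenarioConfig()
    settings = settings or StudySettings()
    out = []
    for k in range(n_scenarios):
        scn_rng = np.random.default_rng(scenario_seed_sequence(master_seed, 1, k, 0))
        scn = dgm.sample_scenario(scenario_config, scn_rng, seed=k)
        out.append(
            run_study1_scenario(
                scn, settings, scenario_seed_sequence(master_seed, 1, k, 1),
                scenario_id=k,
            )
        )
    return out


def run_study2(
    n_scenarios: int,
    master_seed: int,
    scenario_config: dgm.ScenarioConfig | None = None,
    settings: StudySettings | None = None,
) -> list[Study2Result]:
    """Draw and run ``n_scenarios`` study-2 scenarios with derived seeds."""
    scenario_config = scenario_config or dgm.ScenarioConfig()
    settings = settings or StudySettings()
    out = []
    for k in range(n_scenarios):
        scn_rng = np.random.default_rng(scenario_seed_sequence(master_seed, 2, k, 0))
        scn = dgm.sample_scenario(scenario_config, scn_rng, seed=k)
        out.append(
            run_study2_scenario(
                scn, settings, scenario_seed_sequence(master_seed, 2, k, 1),
                scenario_id=k,
            )
        )
    return out


def scenarios_frame(results: list) -> pd.DataFrame:
    """One row per scenario: parameters, population truth, biases, exclusion."""
    rows = []
    for r in results:
        scn = r.scenario
        base = {
            "scenario_id": r.scenario_id,
            "q_meas": scn.q_meas,
            "q_unmeas": scn.q_unmeas,
            "n_dev": scn.n_dev,
            "prop": scn.prop,
            "covariance_mode": scn.covariance_mode,
            "c_pop": r.c_pop,
            "r2_pop": r.r2_pop,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason,
        }
        if isinstance(r, ScenarioResult):
            base.update(
                epp=r.epp, bias_vh=r.bias_vh, bias_boot=r.bias_boot,
                sd_vh=r.sd_vh, sd_boot=r.sd_boot, mce_vh=r.mce_vh,
                mce_boot=r.mce_boot, mean_s_vh=r.mean_s_vh,
                mean_s_boot=r.mean_s_boot, mean_s_opt=r.mean_s_opt,
                mean_r2_app=r.mean_r2_app, boot_failure_rate=r.boot_failure_rate,
                fit_failures=r.fit_failures,
            )
        else:
            base.update(
                n_original=r.n_original, n_sim=r.n_sim,
                nsim_converged=r.nsim_converged,
                mean_sopt_original=r.mean_sopt_original,
                mean_sopt_sim=r.mean_sopt_sim,
                bias_original=r.bias_original, bias_sim=r.bias_sim,
                sd_original=r.sd_original, sd_sim=r.sd_sim,
            )
        rows.append(base)
    return pd.DataFrame(rows)


def records_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """One row per (scenario, iteration) with the raw shrinkage records."""
    rows = []
    for r in results:
        for rec in r.records:
            rows.append(
                {
                    "scenario_id": r.scenario_id,
                    "iteration_index": rec.iteration_index,
                    "s_vh": rec.s_vh,
                    "s_boot": rec.s_boot,
                    "s_opt": rec.s_opt,
                    "c_app": rec.c_app,
                    "r2_app": rec.r2_app,
                    "boot_failures": rec.boot_failures,
                }
            )
    return pd.DataFrame(rows)
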