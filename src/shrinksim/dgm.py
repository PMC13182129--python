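"""Synthetic data-generating mechanisms for the simulation studies.

A *scenario* is a frozen set of randomly drawn simulation parameters: the
numbers of measured and unmeasured predictors, their true log-odds-ratio
coefficients, the predictor covariance, the target outcome proportion and
the development sample size.  Datasets are then drawn repeatedly from the
scenario: multivariate-normal predictors, a logistic true-risk model over
*all* predictors (measured and unmeasured), and Bernoulli outcomes.  Models
are only ever fitted on the measured predictors, so the unmeasured block
acts as structured, irreducible noise.

Two mechanisms are provided.  The default draws every coefficient from
Uniform(-0.5, 0.5), which couples the number of predictors to the model's
discrimination.  The alternative ("independent C") mechanism drops the
unmeasured block and rescales the coefficient vector so that the model
attains a target C-statistic drawn from Uniform(0.55, 0.95) -- decoupling
predictor count from discrimination by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "Scenario",
    "Dataset",
    "ScenarioConfig",
    "RescaleSettings",
    "sample_scenario",
    "sample_scenario_alt",
    "random_psd_correlation",
    "generate_dataset",
    "rescale_coefficients_to_c",
    "weighted_concordance",
]

COVARIANCE_MODES = ("random_psd", "identity")
_PSD_TOL = 1e-8


@dataclass
class Scenario:
    """Frozen parameters of one simulation scenario."""

    q_meas: int
    q_unmeas: int
    beta: np.ndarray          # length q_meas + q_unmeas, measured block first
    beta0: float
    omega: np.ndarray         # (q, q) predictor covariance
    prop: float               # target outcome proportion in (0, 1)
    n_dev: int
    covariance_mode: str
    seed: int
    target_c: float | None = None   # set by the independent-C mechanism

    @property
    def q(self) -> int:
        return self.q_meas + self.q_unmeas

    def validate(self) -> None:
        q = self.q
        if not (1 <= self.q_meas <= 30 and 0 <= self.q_unmeas <= 30):
            raise ValueError("predictor counts out of range")
        if self.beta.shape != (q,):
            raise ValueError("beta length does not match predictor count")
        if self.omega.shape != (q, q):
            raise ValueError("omega dimension does not match predictor count")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValueError("omega is not symmetric")
        if np.linalg.eigvalsh(self.omega).min() < -_PSD_TOL:
            raise ValueError("omega is not positive semi-definite")
        if not (0.0 < self.prop < 1.0):
            raise ValueError("prop must lie strictly in (0, 1)")
        if not (100 <= self.n_dev <= 5000):
            raise ValueError("n_dev out of [100, 5000]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = [float(b) for b in self.beta]
        d["omega"] = [[float(v) for v in row] for row in self.omega]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["beta"] = np.asarray(d["beta"], dtype=float)
        d["omega"] = np.asarray(d["omega"], dtype=float)
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Scenario":
        return cls.from_dict(json.loads(s))


@dataclass
class Dataset:
    """A predictor matrix, binary outcomes, and the underlying true risks."""

    x: np.ndarray
    y: np.ndarray
    true_p: np.ndarray

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass
class RescaleSettings:
    """Controls for the coefficient-rescaling search (target C-statistic)."""

    cohort_n: int = 100_000
    tolerance: float = 0.002
    max_iter: int = 60


@dataclass
class ScenarioConfig:
    """Scenario-generation settings shared across a run."""

    covariance_mode: str = "random_psd"
    dgm: str = "default"               # "default" or "independent_c"
    n_dev_cap: int = 5000
    q_max: int = 30
    max_redraws: int = 10_000
    rescale: RescaleSettings = field(default_factory=RescaleSettings)

    def __post_init__(self) -> None:
        if self.covariance_mode not in COVARIANCE_MODES:
            raise ValueError(f"covariance_mode must be one of {COVARIANCE_MODES}")
        if self.dgm not in ("default", "independent_c"):
            raise ValueError("dgm must be 'default' or 'independent_c'")


def random_psd_correlation(q: int, rng: np.random.Generator) -> np.ndarray:
    """A random correlation matrix: Gram matrix of a standard-normal factor,
    rescaled to unit diagonal.  Positive semi-definite by construction and
    inducing non-degenerate random dependence between every pair.
    """
    if q < 1:
        raise ValueError("dimension must be >= 1")
    a = rng.standard_normal((q, q))
    g = a @ a.T
    d = np.sqrt(np.diag(g))
    corr = g / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0


def _draw_n_dev(rng: np.random.Generator, cap: int, max_redraws: int) -> int:
    # n_dev ~ 100 + Weibull(shape 0.5, scale 2500), resampled until <= cap.
    for _ in range(max_redraws):
        n = 100.0 + 2500.0 * rng.weibull(0.5)
        if n <= cap:
            return int(round(n))
    raise RuntimeError("n_dev resampling failed to land under the cap; broken rng?")


def sample_scenario(
    config: ScenarioConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int = 0,
) -> Scenario:
    """Draw one scenario under the default mechanism.

    Predictor counts are uniform integers in 1..30 for both the measured
    and unmeasured blocks, coefficients are Uniform(-0.5, 0.5), the target
    outcome proportion is Uniform(0.05, 0.95) with the intercept set to its
    logit, and the development sample size is 100 + Weibull(0.5, 2500)
    resampled until it is at most the cap (default 5000).
    """
    config = config or ScenarioConfig()
    rng = rng if rng is not None else np.random.default_rng(seed)
    if config.dgm == "independent_c":
        return sample_scenario_alt(config, rng, seed=seed)
    q_meas = int(rng.integers(1, config.q_max + 1))
    q_unmeas = int(rng.integers(1, config.q_max + 1))
    q = q_meas + q_unmeas
    beta = rng.uniform(-0.5, 0.5, size=q)
    if config.covariance_mode == "random_psd":
        omega = random_psd_correlation(q, rng)
    else:
        omega = np.eye(q)
    prop = float(rng.uniform(0.05, 0.95))
    n_dev = _draw_n_dev(rng, config.n_dev_cap, config.max_redraws)
    scn = Scenario(
        q_meas=q_meas,
        q_unmeas=q_unmeas,
        beta=beta,
        beta0=float(logit(prop)),
        omega=omega,
        prop=prop,
        n_dev=n_dev,
        covariance_mode=config.covariance_mode,
        seed=seed,
    )
    scn.validate()
    return scn


def weighted_concordance(eta: np.ndarray, p: np.ndarray) -> float:
    """Population concordance of a logistic model over a covariate sample.

    Rather than sampling outcomes and paying binomial noise, each
    individual contributes event mass ``p_i`` and non-event mass
    ``1 - p_i``; the concordance is the probability that a random event
    outranks a random non-event on the linear predictor ``eta``.
    O(n log n) via sorting.
    """
    order = np.argsort(eta, kind="stable")
    p = p[order]
    q = 1.0 - p
    cum_q = np.cumsum(q) - q          # non-event mass strictly below (ties: none a.s.)
    num = float(np.sum(p * cum_q)) + 0.5 * float(np.sum(p * q))
    return num / (float(p.sum()) * float(q.sum()))


def rescale_coefficients_to_c(
    beta: np.ndarray,
    prevalence: float,
    target_c: float,
    rng: np.random.Generator,
    settings: RescaleSettings | None = None,
    *,
    omega: np.ndarray | None = None,
) -> np.ndarray:
    """Rescale ``beta`` by a scalar k > 0 so the model hits a target C-statistic.

    The C-statistic of a logistic model is monotone in a uniform scaling
    of its coefficients, so k is found by bracketing (repeated doubling /
    halving from k=1) followed by a monotone root solve.  The C for a
    candidate k is evaluated on one large simulated covariate cohort using
    population-weighted concordance, with the intercept fixed at
    ``logit(prevalence)`` -- exactly the generating model the scenario
    will use.
    """
    settings = settings or RescaleSettings()
    beta = np.asarray(beta, dtype=float)
    if not np.any(beta != 0.0):
        raise ValueError("beta is the zero vector; C is fixed at 0.5")
    if not (0.5 < target_c < 1.0):
        raise ValueError("target_c must lie in (0.5, 1)")
    q = beta.shape[0]
    z = rng.standard_normal((settings.cohort_n, q))
    if omega is not None:
        z = z @ _cholesky_psd(omega).T
    u = z @ beta
    order = np.argsort(u, kind="stable")
    u_sorted = u[order]
    alpha = float(logit(prevalence))

    def c_of(k: float) -> float:
        p = expit(alpha + k * u_sorted)
        qm = 1.0 - p
        cum_q = np.cumsum(qm) - qm
        return (float(np.sum(p * cum_q)) + 0.5 * float(np.sum(p * qm))) / (
            float(p.sum()) * float(qm.sum())
        )

    k_lo, k_hi = 1.0, 1.0
    c1 = c_of(1.0)
    if abs(c1 - target_c) <= settings.tolerance:
        return beta.copy()
    if c1 < target_c:
        for _ in range(settings.max_iter):
            k_hi *= 2.0
            if c_of(k_hi) >= target_c:
                break
        else:
            raise RuntimeError("failed to bracket the target C from above")
    else:
        for _ in range(settings.max_iter):
            k_lo *= 0.5
            if c_of(k_lo) <= target_c:
                break
        else:
            raise RuntimeError("failed to bracket the target C from below")

    for _ in range(200):
        k_mid = math.sqrt(k_lo * k_hi)
        c_mid = c_of(k_mid)
        if abs(c_mid - target_c) <= settings.tolerance:
            return k_mid * beta
        if c_mid < target_c:
            k_lo = k_mid
        else:
            k_hi = k_mid
    raise RuntimeError("coefficient rescaling failed to converge")


def sample_scenario_alt(
    config: ScenarioConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int = 0,
) -> Scenario:
    """Draw one scenario under the independent-C mechanism.

    No unmeasured predictors; initial Uniform(-0.5, 0.5) coefficients are
    rescaled so the model attains a target C drawn from Uniform(0.55,
    0.95).  Predictor count and discrimination are then independent by
    construction.
    """
    config = config or ScenarioConfig()
    rng = rng if rng is not None else np.random.default_rng(seed)
    q_meas = int(rng.integers(1, config.q_max + 1))
    beta = rng.uniform(-0.5, 0.5, size=q_meas)
    while not np.any(beta != 0.0):  # measure-zero guard
        beta = rng.uniform(-0.5, 0.5, size=q_meas)
    if config.covariance_mode == "random_psd":
        omega = random_psd_correlation(q_meas, rng)
    else:
        omega = np.eye(q_meas)
    prop = float(rng.uniform(0.05, 0.95))
    target_c = float(rng.uniform(0.55, 0.95))
    n_dev = _draw_n_dev(rng, config.n_dev_cap, config.max_redraws)
    beta = rescale_coefficients_to_c(
        beta, prop, target_c, rng, config.rescale, omega=omega
    )
    scn = Scenario(
        q_meas=q_meas,
        q_unmeas=0,
        beta=beta,
        beta0=float(logit(prop)),
        omega=omega,
        prop=prop,
        n_dev=n_dev,
        covariance_mode=config.covariance_mode,
        seed=seed,
        target_c=target_c,
    )
    # the rescaled coefficients may legitimately leave (-0.5, 0.5), so only
    # structural invariants are re-checked here
    if np.linalg.eigvalsh(scn.omega).min() < -_PSD_TOL:
        raise ValueError("omega is not positive semi-definite")
    return scn


def _cholesky_psd(omega: np.ndarray) -> np.ndarray:
    """Cholesky factor of a (possibly borderline) PSD matrix.

    Raises if the smallest eigenvalue is below -1e-8; otherwise a small
    jitter is added when the plain factorisation fails.
    """
    try:
        return np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(omega)
        if w.min() < -_PSD_TOL:
            raise ValueError("covariance matrix is not PSD within tolerance")
        jitter = max(1e-12, abs(w.min()) * 10.0)
        return np.linalg.cholesky(omega + jitter * np.eye(omega.shape[0]))


def generate_dataset(
    scenario: Scenario,
    n: int,
    rng: np.random.Generator,
    *,
    chol: np.ndarray | None = None,
) -> Dataset:
    """Draw ``n`` individuals from a scenario.

    Predictors are multivariate normal with mean zero and covariance
    ``scenario.omega``; the true risk uses the full linear predictor over
    measured *and* unmeasured predictors; outcomes are Bernoulli draws.
    ``chol`` may carry a precomputed Cholesky factor of omega (the engines
    reuse one per scenario).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    L = chol if chol is not None else _cholesky_psd(scenario.omega)
    x = rng.standard_normal((n, scenario.q)) @ L.T
    eta = scenario.beta0 + x @ scenario.beta
    # keep true risks strictly interior even for extreme linear predictors
    true_p = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    y = (rng.random(n) < true_p).astype(float)
    return Dataset(x=x, y=y, true_p=true_p)
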