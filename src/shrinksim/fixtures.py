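"""Frozen fixture bundles for oracle-based tests.

``make_fixtures`` writes, under an output directory: a toy logistic
dataset with its maximum-likelihood coefficients obtained from a direct
likelihood optimisation (scipy, not the package's own solver), a frozen
scenario, a small validation cohort, and a checksum manifest.  Everything
is deterministic in the seed, so the bundle doubles as a regression
anchor.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from . import dgm

__all__ = ["make_fixtures", "oracle_logistic_fit"]


def oracle_logistic_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct likelihood maximisation (coarse start + BFGS), intercept first.

    Deliberately independent of the package's Newton solver so the two
    routes can be compared in tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = np.column_stack([np.ones(len(y)), x])

    def negll(b):
        eta = xd @ b
        return -(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))

    # coarse grid over a shared scale for all parameters, then polish
    best, best_val = None, np.inf
    for scale in (-2.0, -0.5, 0.0, 0.5, 2.0):
        b0 = np.full(xd.shape[1], scale)
        v = negll(b0)
        if v < best_val:
            best, best_val = b0, v
    res = minimize(negll, best, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 2000})
    return res.x


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(seed: int, out: str | Path) -> dict:
    """Write the fixture bundle; returns the checksum manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # toy logistic dataset, small enough for brute-force oracles
    n_toy, q_toy = 60, 2
    x = rng.standard_normal((n_toy, q_toy))
    eta = 0.3 + x @ np.array([0.8, -0.5])
    y = (rng.random(n_toy) < expit(eta)).astype(float)
    toy = pd.DataFrame({"x1": x[:, 0], "x2": x[:, 1], "y": y})
    toy_path = out / "toy_logistic.csv"
    toy.to_csv(toy_path, index=False, float_format="%.17g")

    coefs = oracle_logistic_fit(x, y)
    oracle_path = out / "toy_oracle_fit.json"
    oracle_path.write_text(
        json.dumps({"intercept": coefs[0], "coefficients": list(coefs[1:])})
    )

    scn = dgm.sample_scenario(
        dgm.ScenarioConfig(covariance_mode="random_psd"),
        np.random.default_rng(seed + 1),
        seed=seed + 1,
    )
    scn_path = out / "scenario.json"
    scn_path.write_text(scn.to_json())

    cohort = dgm.generate_dataset(scn, 10_000, np.random.default_rng(seed + 2))
    cohort_path = out / "validation_cohort.csv"
    pd.DataFrame(
        np.column_stack([cohort.x, cohort.true_p, cohort.y]),
        columns=[f"x{j+1}" for j in range(scn.q)] + ["true_p", "y"],
    ).to_csv(cohort_path, index=False, float_format="%.17g")

    manifest = {
        p.name: _sha256(p) for p in (toy_path, oracle_path, scn_path, cohort_path)
    }
    (out / "checksums.json").write_text(json.dumps(manifest, indent=2))
    return manifest
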