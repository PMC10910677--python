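"""Monte-Carlo validation utilities.

Replicated synthetic-system experiments that quantify how the estimation
chain behaves under known ground truth: empirical coverage of the QALE
confidence intervals, dominance of the health variance component, mean
signed estimation error, and coverage of the association-model
confidence intervals.  These are validation instruments, not part of the
estimation chain itself.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .inclusive_economy import INDICATOR_COLUMNS, fit_association_model
from .pipeline import PipelineConfig, run_pipeline
from .synthetic_data import SystemConfig, generate_system

__all__ = ["coverage_experiment", "association_recovery_experiment"]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n) % (2**31)


def coverage_experiment(
    n_replicates: int,
    base_config: SystemConfig | None = None,
    seed: int = 0,
    level: float = 0.80,
) -> dict:
    """Replicate the full chain on synthetic systems with known truth.

    For each replicate a fresh system is generated, the pipeline is run
    (without the association stage), and each area-sex confidence
    interval is checked against the true QALE.  Returns empirical
    coverage, the share of area-sex estimates whose health variance
    component exceeds the mortality component, and the mean signed
    error in years.
    """
    if base_config is None:
        base_config = SystemConfig()
    seeds = _child_seeds(seed, n_replicates)
    covered = 0
    total = 0
    health_dominates = 0
    signed_errors = []
    for s in seeds:
        cfg = replace(base_config, seed=int(s))
        system = generate_system(cfg)
        result = run_pipeline(
            PipelineConfig(
                deaths=system.deaths,
                population=system.population,
                reference=system.reference_schedule,
                survey=system.survey,
                ci_level=level,
                compute_association=False,
                seed=int(s),
            )
        )
        merged = result.qale.merge(
            system.truth[["area_id", "sex", "true_qale"]], on=["area_id", "sex"]
        )
        covered += int(
            ((merged["ci_lo"] <= merged["true_qale"]) & (merged["true_qale"] <= merged["ci_hi"])).sum()
        )
        health_dominates += int((merged["var_health"] > merged["var_mort"]).sum())
        total += len(merged)
        signed_errors.append(float((merged["qale"] - merged["true_qale"]).mean()))
    return {
        "n_replicates": n_replicates,
        "n_estimates": total,
        "coverage": covered / total,
        "health_dominance_share": health_dominates / total,
        "mean_signed_error_years": float(np.mean(signed_errors)),
    }


def association_recovery_experiment(
    n_replicates: int,
    n_areas: int = 40,
    beta: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Coverage of the association model's 95% CIs under a known linear law.

    Indicator matrices are drawn standard normal and z-standardised, the
    outcome is a known linear combination plus Gaussian noise, and the
    fraction of (replicate, coefficient) pairs whose 95% CI contains the
    true coefficient is reported.
    """
    p = len(INDICATOR_COLUMNS)
    if beta is None:
        rng0 = np.random.default_rng(seed)
        beta = rng0.uniform(-1.0, 1.0, p)
    beta = np.asarray(beta, dtype=float)
    seeds = _child_seeds(seed + 1, n_replicates)
    hits = 0
    total = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        X = rng.standard_normal((n_areas, p))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        y = X @ beta + noise_sd * rng.standard_normal(n_areas)
        qale = pd.DataFrame(
            {"area_id": [f"A{i:03d}" for i in range(n_areas)], "qale": y}
        )
        ind = pd.DataFrame(X, columns=list(INDICATOR_COLUMNS))
        ind.insert(0, "area_id", qale["area_id"])
        res = fit_association_model(qale, ind)
        c = res.coefficients
        hits += int(((c["ci_lo"] <= beta) & (beta <= c["ci_hi"])).sum())
        total += p
    return {
        "n_replicates": n_replicates,
        "n_intervals": total,
        "coverage": hits / total,
        "true_beta": beta,
    }
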