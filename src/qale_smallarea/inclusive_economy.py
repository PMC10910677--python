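"""Area-level reporting and the inclusive-economy association analysis.

Descriptive reporting of quality-adjusted life expectancy across areas
(population-weighted national means, within-nation ranges, within-area
sex gaps) and an exploratory multiple linear regression of QALE on 13
area-level inclusive-economy indicators.  Indicators are z-standardised
before fitting so every coefficient reads as "expected change in QALE,
in years, per 1 SD increase of the indicator"; indicator directions are
taken exactly as supplied, never flipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "INDICATOR_COLUMNS",
    "AssociationResult",
    "z_standardize",
    "fit_association_model",
    "weighted_national_mean",
    "range_report",
    "sex_gap_report",
]

#: The 13 inclusive-economy indicators.  Percentages unless noted; the
#: three inequality/affordability measures are ratios.  Direction is the
#: direction of the source data (higher employment is favourable, higher
#: child poverty is not); it is preserved as-is in all analyses.
INDICATOR_COLUMNS: tuple[str, ...] = (
    "participation_paid_employment",
    "skills_qualifications",
    "involuntary_exclusion",
    "digital_exclusion",
    "wealth_inequality",
    "physical_connectivity",
    "earnings_inequality",
    "housing_affordability",
    "poverty",
    "cost_of_living",
    "decent_pay",
    "inclusion_decision_making",
    "job_security",
)


def z_standardize(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Standardise columns to mean 0, sample SD 1 (n-1 denominator).

    Only the named columns are touched (default: every indicator column
    present); anything else — e.g. an outcome in years — is left alone.
    A constant column cannot be standardised and raises, naming the
    indicator.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in INDICATOR_COLUMNS if c in table.columns]
    for c in columns:
        x = out[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"indicator column '{c}' is constant; cannot standardise")
        out[c] = (x - x.mean()) / sd
    return out


@dataclass
class AssociationResult:
    """Standardised regression of QALE on the inclusive-economy indicators."""

    sex: str
    coefficients: pd.DataFrame  # index indicator; beta, se, ci_lo, ci_hi
    r2: float
    adj_r2: float
    n_areas: int

    def to_frame(self) -> pd.DataFrame:
        out = self.coefficients.reset_index(names="indicator")
        out.insert(0, "sex", self.sex)
        return out


def fit_association_model(
    qale: pd.DataFrame,
    indicators: pd.DataFrame,
    sex: str = "",
    ci_level: float = 0.95,
    cond_threshold: float = 1e8,
) -> AssociationResult:
    """OLS of QALE (years) on all 13 standardised indicators jointly.

    ``qale`` needs columns ``area_id`` and ``qale``; ``indicators`` needs
    ``area_id`` plus the 13 indicator columns.  Per-coefficient
    confidence intervals use the t distribution; the explained-variance
    summary is the adjusted R^2.

    A nearly collinear indicator matrix (condition number above
    ``cond_threshold``) triggers a diagnostic warning, not an error.
    """
    cols = [c for c in INDICATOR_COLUMNS if c in indicators.columns]
    missing = set(INDICATOR_COLUMNS) - set(cols)
    if missing:
        raise ValueError(f"indicator table is missing columns: {sorted(missing)}")
    merged = qale[["area_id", "qale"]].merge(indicators, on="area_id", how="inner")
    n = len(merged)
    p = len(cols)
    if n < p + 2:
        raise ValueError(
            f"need at least {p + 2} areas to fit {p} indicators plus an "
            f"intercept; got {n}"
        )
    std = z_standardize(merged, cols)
    X = std[cols].to_numpy(dtype=float)
    cond = np.linalg.cond(X)
    if cond > cond_threshold:
        warnings.warn(
            f"indicator matrix is nearly collinear (condition number {cond:.3g})",
            UserWarning,
            stacklevel=2,
        )
    y = std["qale"].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=1.0 - ci_level)
    coef = pd.DataFrame(
        {
            "beta": res.params[1:],
            "se": res.bse[1:],
            "ci_lo": ci[1:, 0],
            "ci_hi": ci[1:, 1],
        },
        index=pd.Index(cols, name="indicator"),
    )
    return AssociationResult(
        sex=sex,
        coefficients=coef,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n_areas=n,
    )


def weighted_national_mean(
    qale: pd.DataFrame, populations: pd.DataFrame, nations: pd.DataFrame
) -> pd.DataFrame:
    """Population-weighted mean QALE per nation and sex.

    Weights are total area populations (both sexes combined), so the
    female and male means for a nation use the same weights.
    """
    pop = populations.copy()
    if np.any(pop["population"].to_numpy(dtype=float) <= 0):
        raise ValueError("populations must be positive")
    merged = (
        qale.merge(pop[["area_id", "population"]], on="area_id")
        .merge(nations[["area_id", "nation"]], on="area_id")
    )
    if merged.empty:
        raise ValueError("no areas left after joining populations and nations")
    dropped = set(nations["nation"].unique()) - set(merged["nation"].unique())
    if dropped:
        warnings.warn(f"nations with no areas omitted: {sorted(dropped)}", UserWarning,
                      stacklevel=2)

    def _wm(d):
        return np.average(d["qale"], weights=d["population"])

    out = (
        merged.groupby(["nation", "sex"])
        .apply(_wm, include_groups=False)
        .rename("qale_weighted_mean")
        .reset_index()
    )
    return out


def range_report(qale: pd.DataFrame, nations: pd.DataFrame) -> pd.DataFrame:
    """Extreme areas and the max-minus-min QALE gap per nation and sex."""
    merged = qale.merge(nations[["area_id", "nation"]], on="area_id")
    rows = []
    for (nation, sex), d in merged.groupby(["nation", "sex"]):
        i_min = d["qale"].idxmin()
        i_max = d["qale"].idxmax()
        rows.append(
            {
                "nation": nation,
                "sex": sex,
                "min_area": d.loc[i_min, "area_id"],
                "min_qale": d.loc[i_min, "qale"],
                "max_area": d.loc[i_max, "area_id"],
                "max_qale": d.loc[i_max, "qale"],
                "range": d.loc[i_max, "qale"] - d.loc[i_min, "qale"],
            }
        )
    return pd.DataFrame(rows)


def sex_gap_report(qale: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Female-minus-male gaps in LE and QALE per area.

    Expects columns ``area_id``, ``sex`` (``F``/``M``), ``le``, ``qale``.
    Areas missing either sex are skipped with a warning.  The summary
    counts areas where a female LE advantage coexists with a female QALE
    *dis*advantage — the reversal pattern characteristic of the
    health-survival paradox.
    """
    wide = qale.pivot_table(index="area_id", columns="sex", values=["le", "qale"])
    complete = wide.dropna()
    skipped = len(wide) - len(complete)
    if skipped:
        warnings.warn(
            f"{skipped} area(s) skipped in the sex-gap report (missing a sex)",
            UserWarning,
            stacklevel=2,
        )
    per_area = pd.DataFrame(
        {
            "le_gap": complete[("le", "F")] - complete[("le", "M")],
            "qale_gap": complete[("qale", "F")] - complete[("qale", "M")],
        }
    ).reset_index()
    reversal = (per_area["le_gap"] > 0) & (per_area["qale_gap"] < 0)
    same_sign = np.sign(per_area["le_gap"]) == np.sign(per_area["qale_gap"])
    summary = {
        "n_areas": int(len(per_area)),
        "n_female_le_advantage": int((per_area["le_gap"] > 0).sum()),
        "n_female_qale_advantage": int((per_area["qale_gap"] > 0).sum()),
        "n_reversals": int(reversal.sum()),
        "n_sign_agreement": int(same_sign.sum()),
    }
    if summary["n_reversals"]:
        logger.info(
            "%d area(s) show a female LE advantage but a female QALE "
            "disadvantage", summary["n_reversals"],
        )
    return per_area, summary
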