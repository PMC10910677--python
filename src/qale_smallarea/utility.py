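"""Area-level utility schedules from SF-12 survey microdata.

The health input to a quality-adjusted life expectancy is a mean utility
score per area, sex and age band on the 0 (dead) to 1 (perfect health)
scale.  Raw survey cell means are noisy and often missing for small
areas, so the estimation is two-stage:

1. weighted raw cell means of the SF-12 Physical and Mental Component
   Summary scores (PCS / MCS) per area x sex x 10-year age band, using
   cross-sectional survey weights;
2. a weighted linear model of those cell means (sex, age band, their
   interaction, and an area fixed effect) predicting a smooth, complete
   grid of PCS and MCS means, including cells with no respondents;
3. a deterministic quadratic mapping of the predicted (PCS, MCS) pair
   to a utility score, clamped to [0, 1].

Respondents aged 19 or younger share one 0-19 band, matching an adult
panel survey in which nobody under 16 is interviewed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEFAULT_BANDS",
    "UtilityMapping",
    "DEFAULT_MAPPING",
    "ScoreModel",
    "band_labels",
    "age_to_band",
    "map_to_utility",
    "compute_cell_means",
    "fit_score_model",
    "predict_scores",
    "build_utility_schedule",
    "estimate_utility_schedules",
]

#: 10-year age bands; everyone aged 19 or younger is pooled into 0-19,
#: and the last band is open-ended.
DEFAULT_BANDS: tuple[tuple[int, int | None], ...] = (
    (0, 19),
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 79),
    (80, None),
)

_MAPPING_TERMS = ("intercept", "pcs", "mcs", "pcs2", "mcs2", "pcs_mcs")


def band_labels(bands=DEFAULT_BANDS) -> list[str]:
    return [f"{lo}-{hi}" if hi is not None else f"{lo}+" for lo, hi in bands]


def age_to_band(ages, bands=DEFAULT_BANDS) -> np.ndarray:
    """Label each age with its band; ages below the first band are invalid."""
    lows = np.array([lo for lo, _ in bands])
    labels = np.array(band_labels(bands), dtype=object)
    ages = np.asarray(ages)
    idx = np.searchsorted(lows, ages, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("age below the first band")
    return labels[idx]


@dataclass(frozen=True)
class UtilityMapping:
    """Quadratic map from (PCS, MCS) to a utility score.

    u = b0 + b1*PCS + b2*MCS + b3*PCS^2 + b4*MCS^2 + b5*PCS*MCS

    The six named coefficients accommodate published SF-12-to-utility
    prediction models; transcribe the coefficients of the model you
    trust into a ``utility_mapping`` config block.  The package default
    is a deliberately simple synthetic affine mapping (see
    ``DEFAULT_MAPPING``) so that the toolchain is self-contained.
    """

    intercept: float
    pcs: float
    mcs: float
    pcs2: float = 0.0
    mcs2: float = 0.0
    pcs_mcs: float = 0.0
    source: str = "unspecified"

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityMapping":
        missing = [t for t in _MAPPING_TERMS if t not in d]
        if missing:
            raise ValueError(f"utility mapping is missing coefficients: {missing}")
        return cls(
            intercept=float(d["intercept"]),
            pcs=float(d["pcs"]),
            mcs=float(d["mcs"]),
            pcs2=float(d["pcs2"]),
            mcs2=float(d["mcs2"]),
            pcs_mcs=float(d["pcs_mcs"]),
            source=str(d.get("source", "config")),
        )

    def __call__(self, pcs, mcs):
        pcs = np.asarray(pcs, dtype=float)
        mcs = np.asarray(mcs, dtype=float)
        return (
            self.intercept
            + self.pcs * pcs
            + self.mcs * mcs
            + self.pcs2 * pcs**2
            + self.mcs2 * mcs**2
            + self.pcs_mcs * pcs * mcs
        )


#: Synthetic affine fallback mapping: linear in PCS + MCS, scaled so
#: that population-typical scores (PCS = MCS = 50) give a utility of
#: 0.8.  It exists so the package runs end to end without transcribing
#: a published mapping; it is not an estimate of any published model.
DEFAULT_MAPPING = UtilityMapping(
    intercept=0.1, pcs=0.007, mcs=0.007, source="synthetic affine fallback"
)


def map_to_utility(pcs, mcs, mapping: UtilityMapping = DEFAULT_MAPPING, clamp: bool = True):
    """Evaluate the mapping; by default truncate into the [0, 1] utility range."""
    u = mapping(pcs, mcs)
    if clamp:
        u = np.clip(u, 0.0, 1.0)
    return u


def compute_cell_means(
    survey: pd.DataFrame,
    bands=DEFAULT_BANDS,
    mapping: UtilityMapping = DEFAULT_MAPPING,
) -> pd.DataFrame:
    """Survey-weighted raw cell means per area x sex x age band.

    Returns one row per non-empty cell with the weighted mean PCS and
    MCS, the respondent count ``n`` and ``var_within``, the weighted
    (plug-in) variance of the *mapped utility* within the cell.  The
    within-cell variance is computed on the utility scale because that
    is the scale on which sampling error must later be propagated into
    the health expectancy.

    Cells without respondents are simply absent — nothing is imputed
    here; completion happens in the modelling stage.
    """
    if survey.empty:
        raise ValueError("survey table is empty")
    required = {"area_id", "sex", "age", "pcs", "mcs", "weight"}
    missing = required - set(survey.columns)
    if missing:
        raise ValueError(f"survey table is missing columns: {sorted(missing)}")
    w = survey["weight"].to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("survey weights must be positive and finite")
    if not np.all(np.isfinite(survey[["pcs", "mcs"]].to_numpy(dtype=float))):
        raise ValueError("PCS/MCS scores must be finite")

    df = survey[["area_id", "sex"]].copy()
    df["age_band"] = age_to_band(survey["age"].to_numpy(), bands)
    u = map_to_utility(survey["pcs"], survey["mcs"], mapping)
    df["w"] = w
    df["wp"] = w * survey["pcs"].to_numpy(dtype=float)
    df["wm"] = w * survey["mcs"].to_numpy(dtype=float)
    df["wu"] = w * u
    df["wu2"] = w * u**2

    g = df.groupby(["area_id", "sex", "age_band"], sort=True, observed=True)
    out = g.agg(
        sw=("w", "sum"),
        swp=("wp", "sum"),
        swm=("wm", "sum"),
        swu=("wu", "sum"),
        swu2=("wu2", "sum"),
        n=("w", "size"),
    ).reset_index()
    out["mean_pcs"] = out["swp"] / out["sw"]
    out["mean_mcs"] = out["swm"] / out["sw"]
    mean_u = out["swu"] / out["sw"]
    # plug-in weighted variance of utility (no small-sample correction:
    # var/n then scales exactly as s^2/n under replication)
    out["var_within"] = np.maximum(out["swu2"] / out["sw"] - mean_u**2, 0.0)
    return out[["area_id", "sex", "age_band", "mean_pcs", "mean_mcs", "n", "var_within"]]


def _design(
    cells: pd.DataFrame, areas: list, sexes: list, bands: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + sex + band + sex:band + area fixed effect.

    Reference levels (first sex, first band, first area) are dropped;
    column order is deterministic.
    """
    sex = cells["sex"].to_numpy()
    band = cells["age_band"].to_numpy()
    area = cells["area_id"].to_numpy()
    cols: list[np.ndarray] = [np.ones(len(cells))]
    names: list[str] = ["intercept"]
    for s in sexes[1:]:
        cols.append((sex == s).astype(float))
        names.append(f"sex[{s}]")
    for b in bands[1:]:
        cols.append((band == b).astype(float))
        names.append(f"band[{b}]")
    for s in sexes[1:]:
        for b in bands[1:]:
            cols.append(((sex == s) & (band == b)).astype(float))
            names.append(f"sex[{s}]:band[{b}]")
    for a in areas[1:]:
        cols.append((area == a).astype(float))
        names.append(f"area[{a}]")
    return np.column_stack(cols), names


@dataclass
class ScoreModel:
    """Weighted linear model for one SF-12 component fitted on cell means."""

    component: str
    params: np.ndarray
    column_names: list[str]
    areas: list
    sexes: list
    bands: list[str]
    results: object  # statsmodels RegressionResults
    exog: np.ndarray
    weights: np.ndarray


def fit_score_model(cell_means: pd.DataFrame, component: str) -> ScoreModel:
    """Weighted least squares of cell-mean scores on sex, band, sex:band
    and an area fixed effect.

    Observations are area x sex x band cells; weights are the respondent
    counts, which makes the cell-level fit equivalent to a respondent-
    level fit when survey weights are uniform within cells.

    Raises
    ------
    ValueError
        If the design is rank deficient beyond the dropped reference
        levels (the offending columns are named), or the component is
        unknown.
    """
    if component not in ("pcs", "mcs"):
        raise ValueError("component must be 'pcs' or 'mcs'")
    y = cell_means[f"mean_{component}"].to_numpy(dtype=float)
    w = cell_means["n"].to_numpy(dtype=float)
    areas = sorted(cell_means["area_id"].unique())
    sexes = sorted(cell_means["sex"].unique())
    bands = [b for b in band_labels() if b in set(cell_means["age_band"])]
    X, names = _design(cell_means, areas, sexes, bands)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate aliased columns via pivoted QR on the scaled design
        r = np.linalg.qr(X, mode="r")
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; aliased columns: {bad or 'unknown'}")

    res = sm.WLS(y, X, weights=w).fit()
    return ScoreModel(
        component=component,
        params=np.asarray(res.params),
        column_names=names,
        areas=areas,
        sexes=sexes,
        bands=bands,
        results=res,
        exog=X,
        weights=w,
    )


def predict_scores(model: ScoreModel, grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Predict mean scores on a full (or supplied) area x sex x band grid.

    With ``grid=None`` the complete rectangular grid over the levels
    seen at fit time is used, which fills in cells that had no
    respondents.  Unseen levels raise.
    """
    if grid is None:
        grid = pd.DataFrame(
            [
                (a, s, b)
                for a in model.areas
                for s in model.sexes
                for b in model.bands
            ],
            columns=["area_id", "sex", "age_band"],
        )
    else:
        grid = grid[["area_id", "sex", "age_band"]].copy()
        for col, seen in (
            ("area_id", model.areas),
            ("sex", model.sexes),
            ("age_band", model.bands),
        ):
            unseen = set(grid[col]) - set(seen)
            if unseen:
                raise ValueError(f"unseen {col} levels: {sorted(unseen)}")
    X0, _ = _design(grid, model.areas, model.sexes, model.bands)
    out = grid.copy()
    out[f"pred_{model.component}"] = X0 @ model.params
    return out


def build_utility_schedule(
    predicted: pd.DataFrame,
    cell_means: pd.DataFrame,
    mapping: UtilityMapping = DEFAULT_MAPPING,
    clamp: bool = True,
) -> pd.DataFrame:
    """Assemble the utility schedule: pi and its sampling variance per cell.

    pi is the mapped utility of the modelled (PCS, MCS) cell means.  The
    sampling variance ``var_pi`` is taken from the matching raw cell as
    within-cell utility variance divided by the respondent count; a cell
    mean estimated from n respondents carries variance s^2/n.  Cells
    with fewer than two respondents borrow the pooled within-cell
    variance of their sex x band (n-weighted across areas), falling back
    to the global pool — the conservative choice of treating such a cell
    as a single observation.
    """
    required = {"area_id", "sex", "age_band", "pred_pcs", "pred_mcs"}
    missing = required - set(predicted.columns)
    if missing:
        raise ValueError(f"predicted grid is missing columns: {sorted(missing)}")
    out = predicted.copy()
    out["pi"] = map_to_utility(out["pred_pcs"], out["pred_mcs"], mapping, clamp)
    out = out.merge(
        cell_means[["area_id", "sex", "age_band", "n", "var_within"]],
        on=["area_id", "sex", "age_band"],
        how="left",
    )
    out["n"] = out["n"].fillna(0).astype(int)

    informative = cell_means[cell_means["n"] >= 2]
    if informative.empty:
        pooled_by = pd.Series(dtype=float)
        pooled_global = float(cell_means["var_within"].mean()) if len(cell_means) else 0.0
    else:
        pooled_by = informative.groupby(["sex", "age_band"]).apply(
            lambda d: np.average(d["var_within"], weights=d["n"]),
            include_groups=False,
        )
        pooled_global = float(np.average(informative["var_within"], weights=informative["n"]))

    keys = pd.MultiIndex.from_arrays([out["sex"], out["age_band"]])
    pooled = pooled_by.reindex(keys).to_numpy(dtype=float)
    pooled = np.where(np.isfinite(pooled), pooled, pooled_global)

    n = out["n"].to_numpy()
    var_within = out["var_within"].to_numpy(dtype=float)
    var_pi = np.where(n >= 2, var_within / np.maximum(n, 1), pooled / np.maximum(n, 1))
    out["var_pi"] = var_pi
    return out[["area_id", "sex", "age_band", "pi", "var_pi", "n"]]


def estimate_utility_schedules(
    survey: pd.DataFrame,
    bands=DEFAULT_BANDS,
    mapping: UtilityMapping = DEFAULT_MAPPING,
    clamp: bool = True,
) -> pd.DataFrame:
    """Survey microdata to complete utility schedules in one call.

    Runs the full two-stage procedure: raw weighted cell means, the two
    component score models, prediction on the complete grid, and the
    mapped schedule with sampling variances.
    """
    cells = compute_cell_means(survey, bands, mapping)
    pcs_model = fit_score_model(cells, "pcs")
    mcs_model = fit_score_model(cells, "mcs")
    pred = predict_scores(pcs_model).merge(
        predict_scores(mcs_model), on=["area_id", "sex", "age_band"]
    )
    return build_utility_schedule(pred, cells, mapping, clamp)
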