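"""End-to-end orchestration: inputs to QALE estimates and reports.

Stages: grouped deaths + populations -> TOPALS single-age rates (with
old-age correction) -> life tables -> survey-based utility schedules ->
Sullivan QALE with decomposed uncertainty -> descriptive reports and the
inclusive-economy association.  Every stage's output can be written as
CSV; a run manifest records the configuration hash and library versions
so that a re-run with identical inputs is bit-identical.

A sensitivity switch re-runs the mortality side on a reduced set of
pooled calendar years (e.g. dropping a shock year) and reports the
per-area QALE differences.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inclusive_economy import (
    INDICATOR_COLUMNS,
    fit_association_model,
    range_report,
    sex_gap_report,
    weighted_national_mean,
)
from .lifetable import build_life_table
from .sullivan import estimate_qale, exclude_small_areas
from .topals import (
    DEFAULT_KNOTS,
    MortalityInput,
    ReferenceSchedule,
    correct_old_age,
    fit_topals,
    spread_deaths,
)
from .utility import DEFAULT_MAPPING, UtilityMapping, estimate_utility_schedules

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "sensitivity_exclude_year"]


@dataclass
class PipelineConfig:
    """All inputs, outputs and tuning parameters of one pipeline run.

    Input tables may be given as paths to CSV files or as in-memory
    DataFrames (convenient in tests and simulation loops).
    """

    deaths: object = None
    population: object = None
    reference: object = None
    survey: object = None
    indicators: object = None
    out_dir: str | None = None
    years_included: tuple[int, ...] | None = None
    years_pooled: int = 3  # used only when deaths carry no year column
    exclusion_list: tuple[str, ...] = ()
    ci_level: float = 0.80
    topals_lambda: float = 1.0
    knots: tuple[float, ...] = DEFAULT_KNOTS
    mapping: UtilityMapping = DEFAULT_MAPPING
    radix: float = 100_000.0
    old_age_start: int = 90
    pi_override: float | None = None
    compute_association: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be inside (0, 1)")
        if self.years_included is not None and len(self.years_included) == 0:
            raise ValueError("years_included must be non-empty when given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mapping = raw.pop("utility_mapping", None)
        cfg = cls(**raw)
        if mapping is not None:
            cfg.mapping = UtilityMapping.from_dict(mapping)
        return cfg

    def manifest_dict(self) -> dict:
        d = {}
        for key, value in asdict(self).items():
            if key == "out_dir":  # where results land does not affect them
                continue
            if isinstance(value, pd.DataFrame):
                value = f"<in-memory frame, {len(value)} rows>"
            elif isinstance(value, (Path,)):
                value = str(value)
            d[key] = value
        return d


@dataclass
class PipelineResult:
    """Outputs of a full pipeline run."""

    rates: pd.DataFrame
    lifetables: pd.DataFrame
    utility: pd.DataFrame
    qale: pd.DataFrame
    national_means: pd.DataFrame
    ranges: pd.DataFrame
    sex_gaps: pd.DataFrame
    sex_gap_summary: dict
    association: pd.DataFrame | None
    adj_r2: dict
    manifest: dict
    convergence_failures: int = 0


def _load(source, name: str, required: set[str]) -> pd.DataFrame:
    if source is None:
        raise ValueError(f"pipeline input '{name}' is missing")
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        origin = f"<frame:{name}>"
    else:
        origin = str(source)
        try:
            df = pd.read_csv(source)
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValueError(f"could not read {name} from {origin}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{origin}: missing required columns {sorted(missing)}")
    return df


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.manifest_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full estimation chain and optionally write outputs."""
    deaths = _load(config.deaths, "deaths", {"area_id", "sex", "age_group", "deaths"})
    population = _load(
        config.population, "population", {"area_id", "sex", "age_group", "population"}
    )
    reference = _load(config.reference, "reference", {"sex", "age", "log_mx"})
    survey = _load(config.survey, "survey", {"area_id", "sex", "age", "pcs", "mcs", "weight"})
    indicators = None
    if config.compute_association:
        indicators = _load(
            config.indicators, "indicators", {"area_id", *INDICATOR_COLUMNS}
        )

    # ---- pooling over calendar years -----------------------------------
    if "year" in deaths.columns:
        all_years = sorted(deaths["year"].unique())
        years = list(config.years_included) if config.years_included else all_years
        unknown = set(years) - set(all_years)
        if unknown:
            raise ValueError(f"years_included not present in deaths: {sorted(unknown)}")
        deaths = deaths[deaths["year"].isin(years)]
        n_years = len(years)
    else:
        if config.years_included is not None:
            raise ValueError(
                "deaths table has no 'year' column; per-year selection impossible"
            )
        n_years = config.years_pooled
    deaths_pooled = (
        deaths.groupby(["area_id", "sex", "age_group"], as_index=False)["deaths"].sum()
    )

    # ---- area exclusion (applies to all analyses) ----------------------
    deaths_pooled = exclude_small_areas(deaths_pooled, config.exclusion_list)
    population = exclude_small_areas(population, config.exclusion_list)
    survey = exclude_small_areas(survey, config.exclusion_list)
    if indicators is not None:
        indicators = exclude_small_areas(indicators, config.exclusion_list)

    nation_of = None
    if "nation" in population.columns:
        nation_of = population[["area_id", "nation"]].drop_duplicates()

    merged = deaths_pooled.merge(
        population[["area_id", "sex", "age_group", "population"]],
        on=["area_id", "sex", "age_group"],
        how="inner",
        validate="one_to_one",
    )
    merged["exposure"] = merged["population"].astype(float) * n_years

    ref_by_key = {}
    has_nation_ref = "nation" in reference.columns
    for key, grp in reference.groupby(
        ["nation", "sex"] if has_nation_ref else ["sex"]
    ):
        grp = grp.sort_values("age")
        sex = key[1] if has_nation_ref else (key if isinstance(key, str) else key[0])
        ref_by_key[key if has_nation_ref else sex] = ReferenceSchedule(
            sex=sex, ages=grp["age"].to_numpy(), log_mx=grp["log_mx"].to_numpy()
        )

    # ---- mortality: TOPALS + life tables --------------------------------
    order = {g: i for i, g in enumerate(merged["age_group"].unique())}
    rate_frames, lt_frames = [], []
    deaths_by_age = {}
    failures = 0
    groups = merged.groupby(["area_id", "sex"], sort=True)
    for (area, sex), d in groups:
        d = d.copy()
        d["_lo"] = d["age_group"].map(
            lambda g: int(str(g).rstrip("+").split("-")[0])
        )
        d = d.sort_values("_lo")
        if has_nation_ref:
            nation = (
                nation_of.set_index("area_id").loc[area, "nation"]
                if nation_of is not None
                else reference["nation"].iloc[0]
            )
            ref = ref_by_key[(nation, sex)]
        else:
            ref = ref_by_key[sex]
        mort = MortalityInput(
            area_id=area,
            sex=sex,
            age_groups=list(d["age_group"]),
            deaths=d["deaths"].to_numpy(),
            exposure=d["exposure"].to_numpy(),
        )
        fit = fit_topals(mort, ref, lam=config.topals_lambda)
        if not fit.converged:
            failures += 1
        mx = correct_old_age(fit, ref, config.old_age_start)
        rate_frames.append(
            pd.DataFrame({"area_id": area, "sex": sex, "age": ref.ages, "mx": mx})
        )
        lt = build_life_table(mx, radix=config.radix)
        lt.insert(0, "sex", sex)
        lt.insert(0, "area_id", area)
        lt_frames.append(lt)
        deaths_by_age[(area, sex)] = spread_deaths(mort, mx, ref)
    if not rate_frames:
        raise ValueError("no area/sex mortality series to fit")
    rates = pd.concat(rate_frames, ignore_index=True)
    lifetables = pd.concat(lt_frames, ignore_index=True)

    # ---- utility schedules ----------------------------------------------
    utility = estimate_utility_schedules(survey, mapping=config.mapping)
    if config.pi_override is not None:
        utility = utility.assign(pi=float(config.pi_override), var_pi=0.0)

    # ---- Sullivan QALE ---------------------------------------------------
    qale_rows = []
    for (area, sex), D_x in deaths_by_age.items():
        lt = lifetables[(lifetables["area_id"] == area) & (lifetables["sex"] == sex)]
        sched = utility[(utility["area_id"] == area) & (utility["sex"] == sex)]
        if sched.empty:
            logger.warning("no utility schedule for area=%s sex=%s; skipped", area, sex)
            continue
        est = estimate_qale(
            lt.reset_index(drop=True),
            sched.reset_index(drop=True),
            D_x,
            level=config.ci_level,
            area_id=area,
            sex=sex,
        )
        qale_rows.append(
            {
                "area_id": area,
                "sex": sex,
                "le": est.le,
                "qale": est.qale,
                "se": est.se,
                "var_health": est.var_health,
                "var_mort": est.var_mort,
                "ci_lo": est.ci_lo,
                "ci_hi": est.ci_hi,
            }
        )
    qale = pd.DataFrame(qale_rows)

    # ---- reports ---------------------------------------------------------
    pop_totals = (
        population.groupby("area_id", as_index=False)["population"].sum()
    )
    if nation_of is None:
        nation_of = pd.DataFrame(
            {"area_id": pop_totals["area_id"], "nation": "All"}
        )
    national_means = weighted_national_mean(qale, pop_totals, nation_of)
    ranges = range_report(qale, nation_of)
    sex_gaps, gap_summary = sex_gap_report(qale)

    association = None
    adj_r2: dict = {}
    if config.compute_association and indicators is not None:
        frames = []
        for sex, d in qale.groupby("sex"):
            try:
                res = fit_association_model(d, indicators, sex=sex)
            except ValueError as exc:
                warnings.warn(
                    f"association model skipped for sex={sex}: {exc}",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            frames.append(res.to_frame())
            adj_r2[sex] = res.adj_r2
        association = pd.concat(frames, ignore_index=True) if frames else None

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.manifest_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_years_pooled": n_years,
        "n_areas_modelled": int(qale["area_id"].nunique()) if len(qale) else 0,
        "topals_convergence_failures": failures,
        "adj_r2": adj_r2,
        "sex_gap_summary": gap_summary,
    }

    result = PipelineResult(
        rates=rates,
        lifetables=lifetables,
        utility=utility,
        qale=qale,
        national_means=national_means,
        ranges=ranges,
        sex_gaps=sex_gaps,
        sex_gap_summary=gap_summary,
        association=association,
        adj_r2=adj_r2,
        manifest=manifest,
        convergence_failures=failures,
    )
    if config.out_dir is not None:
        _write_outputs(result, config.out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.rates.to_csv(out / "rates.csv", index=False)
    result.lifetables.to_csv(out / "lifetable.csv", index=False)
    result.utility.to_csv(out / "utility.csv", index=False)
    result.qale.to_csv(out / "qale.csv", index=False)
    summary_rows = []
    for row in result.national_means.itertuples(index=False):
        summary_rows.append(
            ("national_weighted_mean", row.nation, row.sex, "qale", row.qale_weighted_mean)
        )
    for row in result.ranges.itertuples(index=False):
        summary_rows.append(("range", row.nation, row.sex, "qale_range", row.range))
    for sex, r2 in result.adj_r2.items():
        summary_rows.append(("association", "", sex, "adj_r2", r2))
    pd.DataFrame(
        summary_rows, columns=["section", "nation", "sex", "name", "value"]
    ).to_csv(out / "summary.csv", index=False)
    if result.association is not None:
        result.association.to_csv(out / "association.csv", index=False)
    result.sex_gaps.to_csv(out / "sex_gaps.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)


@dataclass
class SensitivityResult:
    """Paired pipeline runs with and without one pooled calendar year."""

    base: PipelineResult
    reduced: PipelineResult
    differences: pd.DataFrame
    mean_difference_by_sex: pd.Series


def sensitivity_exclude_year(config: PipelineConfig, year: int) -> SensitivityResult:
    """Re-run the pipeline without one calendar year of mortality.

    Exposure is reduced to population times the remaining number of
    years; the health side is untouched.  Reports the unweighted mean
    change in QALE by sex (reduced minus base), positive when dropping
    the year raises QALE — the expected signature of excluding a
    mortality-shock year.
    """
    deaths = _load(config.deaths, "deaths", {"area_id", "sex", "age_group", "deaths"})
    if "year" not in deaths.columns:
        raise ValueError(
            "sensitivity analysis needs per-year death counts (a 'year' column); "
            "refusing to approximate from pooled counts"
        )
    all_years = sorted(deaths["year"].unique())
    years = list(config.years_included) if config.years_included else all_years
    if year not in years:
        raise ValueError(f"year {year} is not among the pooled years {years}")
    if len(years) < 2:
        raise ValueError("cannot drop the only pooled year")
    base = run_pipeline(replace(config, out_dir=None, years_included=tuple(years)))
    reduced = run_pipeline(
        replace(
            config,
            out_dir=None,
            years_included=tuple(y for y in years if y != year),
        )
    )
    diff = base.qale[["area_id", "sex", "qale"]].merge(
        reduced.qale[["area_id", "sex", "qale"]],
        on=["area_id", "sex"],
        suffixes=("_base", "_reduced"),
    )
    diff["difference"] = diff["qale_reduced"] - diff["qale_base"]
    mean_by_sex = diff.groupby("sex")["difference"].mean()
    return SensitivityResult(
        base=base,
        reduced=reduced,
        differences=diff,
        mean_difference_by_sex=mean_by_sex,
    )
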