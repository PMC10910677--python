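"""Synthetic small-area system with known ground truth.

Generates every input the estimation pipeline consumes — grouped death
counts and mid-year populations by area, sex and 5-year age group; a
national reference log-mortality schedule by single age; survey
microdata with SF-12 component scores and cross-sectional weights; and
an area-level table of 13 inclusive-economy indicators — together with
a truth file recording the parameters each area was generated from.

The generator emulates the *statistical structure* of the real data
sources (registry death counts, rolled-forward population estimates, an
adult panel survey with an area linkage, and an open indicator set),
not their file layouts:

* deaths are Poisson draws around a known mortality surface, which is a
  national reference schedule perturbed by linear-spline offsets at the
  TOPALS knots — so the mortality model is correctly specified and
  recovery tests isolate estimation error;
* each area carries a latent health/inclusivity level; the spline
  offsets correlate with it at a configurable level, survey scores
  shift with it, and the indicators are linear functions of it plus
  noise, with the sign conventions of the published indicator set;
* survey respondents are adults (16+), with ages drawn from the shared
  population age shape, normally distributed PCS/MCS around smooth
  age-by-sex means, and positive log-normal weights with mean one.

The truth file is written alongside the data but is never read by any
estimation module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import build_life_table
from .sullivan import pi_by_age
from .topals import DEFAULT_KNOTS, build_spline_basis
from .utility import DEFAULT_BANDS, DEFAULT_MAPPING, UtilityMapping, band_labels

__all__ = [
    "SystemConfig",
    "SyntheticSystem",
    "INDICATOR_SCALES",
    "DEFAULT_INDICATOR_EFFECTS",
    "generate_system",
    "round_population",
    "reference_log_mortality",
]

#: (name, mean, sd, kind) of the 13 indicators, on the scales of the
#: published area-level indicator set (percentages or ratios).
INDICATOR_SCALES: tuple[tuple[str, float, float, str], ...] = (
    ("participation_paid_employment", 76.67, 5.09, "pct"),
    ("skills_qualifications", 73.89, 9.54, "pct"),
    ("involuntary_exclusion", 4.97, 2.15, "pct"),
    ("digital_exclusion", 33.86, 20.22, "pct"),
    ("wealth_inequality", 2.68, 1.06, "ratio"),
    ("physical_connectivity", 62.50, 28.02, "pct"),
    ("earnings_inequality", 3.13, 0.39, "ratio"),
    ("housing_affordability", 9.92, 3.62, "ratio"),
    ("poverty", 27.54, 7.07, "pct"),
    ("cost_of_living", 10.83, 2.59, "pct"),
    ("decent_pay", 21.77, 6.06, "pct"),
    ("inclusion_decision_making", 35.18, 6.19, "pct"),
    ("job_security", 95.31, 1.69, "pct"),
)

#: Signed slopes linking latent area inclusivity to each indicator, on
#: the indicator's SD scale.  Signs follow the direction conventions of
#: the indicator set: favourable indicators (employment, skills,
#: connectivity, decision-making, job security) rise with inclusivity;
#: exclusion, inequality, affordability-ratio, poverty, cost-of-living
#: and low-pay indicators fall.
DEFAULT_INDICATOR_EFFECTS: tuple[float, ...] = (
    0.5, 0.5, -0.5, -0.5, -0.3, 0.4, -0.3, -0.3, -0.6, -0.4, -0.4, 0.3, 0.3,
)

_DEFAULT_NATION_WEIGHTS = (("England", 309), ("Scotland", 32), ("Wales", 22))
_NATION_PREFIX = {"England": "E", "Scotland": "S", "Wales": "W"}

#: Score points of PCS/MCS shift per 1 SD of latent area health.
HEALTH_SCORE_SCALE = 2.0
#: Stable-population growth rate used for the shared age shape.
_GROWTH_RATE = 0.004


@dataclass(frozen=True)
class SystemConfig:
    """Configuration of a synthetic area system.

    Defaults describe the study conditions the package targets: three
    pooled calendar years (2018-2020, the last carrying a mortality
    shock), district-sized areas, an adult panel survey far smaller
    than the population, and moderate between-area mortality variation
    negatively correlated with latent health.
    """

    n_areas: int = 40
    nations: tuple[tuple[str, int], ...] | None = None
    age_max: int = 110
    years_pooled: int = 3
    first_year: int = 2018
    population_range: tuple[int, int] = (25_000, 250_000)
    survey_n_range: tuple[int, int] = (30, 400)
    offset_sd: float = 0.15
    health_mortality_corr: float = -0.5
    score_cell_sd: float = 10.0
    indicator_effects: tuple[float, ...] = DEFAULT_INDICATOR_EFFECTS
    knots: tuple[float, ...] = DEFAULT_KNOTS
    mapping: UtilityMapping = DEFAULT_MAPPING
    population_rounding: int | None = None
    excess_year: int | None = 2020
    excess_rate_ratio: float = 1.13
    seed: int = 0

    def __post_init__(self):
        if self.n_areas < 2:
            raise ValueError("n_areas must be at least 2")
        if len(self.population_range) != 2 or self.population_range[0] > self.population_range[1]:
            raise ValueError("population_range must be (min, max) with min <= max")
        if len(self.survey_n_range) != 2 or self.survey_n_range[0] > self.survey_n_range[1]:
            raise ValueError("survey_n_range must be (min, max) with min <= max")
        if self.population_range[0] < self.survey_n_range[1]:
            raise ValueError(
                "population_range minimum must be at least the survey_n_range maximum"
            )
        if not -1.0 <= self.health_mortality_corr <= 1.0:
            raise ValueError("health_mortality_corr must lie in [-1, 1]")
        if self.offset_sd < 0:
            raise ValueError("offset_sd must be non-negative")
        if self.score_cell_sd <= 0:
            raise ValueError("score_cell_sd must be positive")
        if self.years_pooled < 1:
            raise ValueError("years_pooled must be at least 1")
        if len(self.indicator_effects) != len(INDICATOR_SCALES):
            raise ValueError(
                f"indicator_effects must have {len(INDICATOR_SCALES)} entries"
            )
        if self.age_max <= self.knots[-1] - 10:
            raise ValueError("age_max must reach near the last spline knot")
        if self.population_rounding is not None and self.population_rounding < 1:
            raise ValueError("population_rounding must be at least 1")
        if self.excess_rate_ratio <= 0:
            raise ValueError("excess_rate_ratio must be positive")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.first_year + i for i in range(self.years_pooled))

    def nation_allocation(self) -> list[tuple[str, int]]:
        """Areas per nation; default splits proportionally to GB LA counts."""
        if self.nations is not None:
            alloc = [(str(n), int(k)) for n, k in self.nations]
            if sum(k for _, k in alloc) != self.n_areas:
                raise ValueError("nations allocation must sum to n_areas")
            return alloc
        total = sum(w for _, w in _DEFAULT_NATION_WEIGHTS)
        counts = [
            (name, int(round(self.n_areas * w / total)))
            for name, w in _DEFAULT_NATION_WEIGHTS
        ]
        drift = self.n_areas - sum(k for _, k in counts)
        counts[0] = (counts[0][0], counts[0][1] + drift)
        return [(n, k) for n, k in counts if k > 0]


def reference_log_mortality(ages, sex: str, nation: str = "England") -> np.ndarray:
    """Smooth national log-mortality by single age.

    A Siler-type curve: exponentially declining infant/child mortality,
    a background level, and Gompertz senescent growth, with a small
    upward level shift for Scotland mirroring its national mortality
    disadvantage.
    """
    x = np.asarray(ages, dtype=float)
    if sex == "M":
        a1, a3, a4, a5 = 0.0040, 8.0e-5, 2.2e-5, 0.098
    elif sex == "F":
        a1, a3, a4, a5 = 0.0035, 5.0e-5, 7.5e-6, 0.108
    else:
        raise ValueError("sex must be 'M' or 'F'")
    m = a1 * np.exp(-x) + a3 + a4 * np.exp(a5 * x)
    shift = {"England": 0.0, "Wales": 0.02, "Scotland": 0.08}.get(nation, 0.0)
    return np.log(m) + shift


def round_population(populations, granularity: int):
    """Round populations to the nearest multiple of ``granularity``.

    Exact half-multiples round up (151 -> 200 at granularity 100).
    Emulates disclosure-control rounding of published mid-year
    population estimates.
    """
    if granularity < 1:
        raise ValueError("granularity must be at least 1")
    values = np.asarray(populations, dtype=float)
    if np.any(values < 0):
        raise ValueError("populations must be non-negative")
    rounded = np.floor(values / granularity + 0.5) * granularity
    if np.isscalar(populations) or np.ndim(populations) == 0:
        return type(populations)(rounded.item()) if isinstance(populations, (int, float)) else rounded.item()
    return rounded


@dataclass
class SyntheticSystem:
    """Bundle of generated input tables plus the ground-truth record."""

    config: SystemConfig
    deaths: pd.DataFrame
    population: pd.DataFrame
    reference_schedule: pd.DataFrame
    survey: pd.DataFrame
    indicators: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Write all six tables as CSV; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "deaths", "population", "reference_schedule", "survey",
            "indicators", "truth",
        ):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def _age_group_starts(age_max: int) -> list[tuple[str, int, int]]:
    groups = []
    for lo in range(0, 90, 5):
        groups.append((f"{lo}-{lo + 4}", lo, lo + 4))
    groups.append(("90+", 90, age_max))
    return groups


def _population_shape(ages: np.ndarray, sex: str) -> np.ndarray:
    """Stable-population age distribution: survivorship discounted by growth."""
    log_m = reference_log_mortality(ages, sex)
    lt = build_life_table(np.exp(log_m))
    lx = lt["lx"].to_numpy() / lt["lx"].iloc[0]
    shape = lx * np.exp(-_GROWTH_RATE * ages)
    return shape / shape.sum()


def generate_system(config: SystemConfig) -> SyntheticSystem:
    """Generate a complete synthetic system; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    ages = np.arange(0, config.age_max + 1)
    groups = _age_group_starts(config.age_max)
    group_starts = np.array([lo for _, lo, _ in groups])
    labels = [g for g, _, _ in groups]

    alloc = config.nation_allocation()
    area_ids, area_nations = [], []
    for nation, count in alloc:
        prefix = _NATION_PREFIX.get(nation, nation[:1].upper())
        start = len(area_ids)
        for i in range(count):
            area_ids.append(f"{prefix}{start + i + 1:03d}")
            area_nations.append(nation)
    n_areas = len(area_ids)
    sexes = ("F", "M")

    basis = build_spline_basis(
        np.clip(ages.astype(float), config.knots[0], config.knots[-1]), config.knots
    )
    K = basis.knots.size

    # --- latent structure ------------------------------------------------
    populations_total = rng.integers(
        config.population_range[0], config.population_range[1] + 1, n_areas
    )
    latent_health = rng.standard_normal(n_areas)
    rho = config.health_mortality_corr
    eps = rng.standard_normal((n_areas, len(sexes), K))
    # each knot offset correlates with latent health at rho
    alpha_true = config.offset_sd * (
        rho * latent_health[:, None, None] + np.sqrt(1.0 - rho**2) * eps
    )

    # --- reference schedules ---------------------------------------------
    ref_rows = []
    nations_present = [n for n, _ in alloc]
    ref_log = {}
    for nation in nations_present:
        for sex in sexes:
            lm = reference_log_mortality(ages, sex, nation)
            ref_log[(nation, sex)] = lm
            ref_rows.append(
                pd.DataFrame(
                    {"nation": nation, "sex": sex, "age": ages, "log_mx": lm}
                )
            )
    reference_schedule = pd.concat(ref_rows, ignore_index=True)

    # --- population and deaths -------------------------------------------
    shapes = {sex: _population_shape(ages, sex) for sex in sexes}
    pop_rows, death_rows = [], []
    m_true = np.empty((n_areas, len(sexes), ages.size))
    N_x = np.empty_like(m_true)
    for si, sex in enumerate(sexes):
        for ai in range(n_areas):
            nation = area_nations[ai]
            log_m = ref_log[(nation, sex)] + basis.B @ alpha_true[ai, si]
            m_true[ai, si] = np.exp(log_m)
            N_x[ai, si] = populations_total[ai] / 2.0 * shapes[sex]

    years = config.years
    for si, sex in enumerate(sexes):
        expected_x = N_x[:, si, :] * m_true[:, si, :]
        expected_g = np.add.reduceat(expected_x, group_starts, axis=1)
        pop_g = np.rint(np.add.reduceat(N_x[:, si, :], group_starts, axis=1))
        if config.population_rounding is not None:
            pop_g = round_population(pop_g, config.population_rounding)
        for year in years:
            factor = (
                config.excess_rate_ratio
                if config.excess_year is not None and year == config.excess_year
                else 1.0
            )
            draws = rng.poisson(expected_g * factor)
            for ai in range(n_areas):
                death_rows.append(
                    pd.DataFrame(
                        {
                            "area_id": area_ids[ai],
                            "nation": area_nations[ai],
                            "sex": sex,
                            "age_group": labels,
                            "year": year,
                            "deaths": draws[ai],
                        }
                    )
                )
        for ai in range(n_areas):
            pop_rows.append(
                pd.DataFrame(
                    {
                        "area_id": area_ids[ai],
                        "nation": area_nations[ai],
                        "sex": sex,
                        "age_group": labels,
                        "population": pop_g[ai].astype(int),
                    }
                )
            )
    deaths = pd.concat(death_rows, ignore_index=True)
    population = pd.concat(pop_rows, ignore_index=True)

    # --- survey ------------------------------------------------------------
    adult = (ages >= 16) & (ages <= 89)
    adult_ages = ages[adult]
    adult_shape = (shapes["F"][adult] + shapes["M"][adult]) / 2.0
    adult_shape = adult_shape / adult_shape.sum()
    n_resp = rng.integers(
        config.survey_n_range[0], config.survey_n_range[1] + 1, n_areas
    )
    total = int(n_resp.sum())
    area_idx = np.repeat(np.arange(n_areas), n_resp)
    resp_age = rng.choice(adult_ages, size=total, p=adult_shape)
    resp_male = rng.integers(0, 2, total)
    h_resp = latent_health[area_idx]
    pcs_mean = 53.0 - 0.11 * (resp_age - 16) + 0.8 * resp_male + HEALTH_SCORE_SCALE * h_resp
    mcs_mean = 45.0 + 0.07 * (resp_age - 16) + 2.2 * resp_male + HEALTH_SCORE_SCALE * h_resp
    pcs = pcs_mean + config.score_cell_sd * rng.standard_normal(total)
    mcs = mcs_mean + config.score_cell_sd * rng.standard_normal(total)
    weight = rng.lognormal(mean=-0.125, sigma=0.5, size=total)
    survey = pd.DataFrame(
        {
            "person_id": np.arange(1, total + 1),
            "area_id": np.asarray(area_ids, dtype=object)[area_idx],
            "sex": np.where(resp_male == 1, "M", "F"),
            "age": resp_age,
            "pcs": pcs,
            "mcs": mcs,
            "weight": weight,
        }
    )

    # --- indicators --------------------------------------------------------
    ind = {"area_id": area_ids}
    for (name, mean, sd, kind), effect in zip(
        INDICATOR_SCALES, config.indicator_effects
    ):
        noise = rng.standard_normal(n_areas)
        val = mean + sd * (
            effect * latent_health + np.sqrt(max(0.0, 1.0 - effect**2)) * noise
        )
        if kind == "pct":
            val = np.clip(val, 0.0, 100.0)
        else:
            val = np.maximum(val, 0.05)
        ind[name] = val
    indicators = pd.DataFrame(ind)

    # --- truth -------------------------------------------------------------
    truth = _build_truth(
        config, area_ids, sexes, alpha_true, m_true, latent_health,
        ages, adult_shape, adult_ages,
    )

    return SyntheticSystem(
        config=config,
        deaths=deaths,
        population=population,
        reference_schedule=reference_schedule,
        survey=survey,
        indicators=indicators,
        truth=truth,
    )


def _build_truth(
    config, area_ids, sexes, alpha_true, m_true, latent_health,
    ages, adult_shape, adult_ages,
):
    """True per-area, per-sex utility bands, LE and QALE.

    The true band utility is defined exactly as the estimator's target:
    the mapped mean score over the band's *surveyed* age range (the
    first band only has respondents aged 16-19), so recovery tests
    compare like with like.
    """
    bands = DEFAULT_BANDS
    labels_b = band_labels(bands)
    rows = []
    for ai, area in enumerate(area_ids):
        for si, sex in enumerate(sexes):
            male = 1.0 if sex == "M" else 0.0
            pi_true = []
            for (lo, hi) in bands:
                hi_eff = hi if hi is not None else int(adult_ages[-1])
                sel = (adult_ages >= lo) & (adult_ages <= hi_eff)
                w = adult_shape[sel]
                a = adult_ages[sel]
                pcs_b = np.average(53.0 - 0.11 * (a - 16) + 0.8 * male, weights=w)
                mcs_b = np.average(45.0 + 0.07 * (a - 16) + 2.2 * male, weights=w)
                pcs_b += HEALTH_SCORE_SCALE * latent_health[ai]
                mcs_b += HEALTH_SCORE_SCALE * latent_health[ai]
                u = float(np.clip(config.mapping(pcs_b, mcs_b), 0.0, 1.0))
                pi_true.append(u)
            lt = build_life_table(m_true[ai, si])
            sched = pd.DataFrame({"age_band": labels_b, "pi": pi_true})
            pi_x, _ = pi_by_age(sched, ages)
            l0 = lt["lx"].iloc[0]
            qale = float(np.sum(pi_x * lt["Lx"].to_numpy()) / l0)
            row = {
                "area_id": area,
                "sex": sex,
                "latent_inclusivity": latent_health[ai],
                "true_le": float(lt["ex"].iloc[0]),
                "true_qale": qale,
            }
            for k in range(alpha_true.shape[2]):
                row[f"alpha_{k}"] = alpha_true[ai, si, k]
            for label, u in zip(labels_b, pi_true):
                row[f"pi_{label}"] = u
            rows.append(row)
    return pd.DataFrame(rows)
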