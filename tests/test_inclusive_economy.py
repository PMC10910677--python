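"""Standardisation, the association regression, and descriptive reports."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from qale_smallarea.inclusive_economy import (
    INDICATOR_COLUMNS,
    fit_association_model,
    range_report,
    sex_gap_report,
    weighted_national_mean,
    z_standardize,
)


def make_indicator_table(rng, n_areas=40):
    df = pd.DataFrame(
        rng.normal(50, 10, size=(n_areas, len(INDICATOR_COLUMNS))),
        columns=list(INDICATOR_COLUMNS),
    )
    df.insert(0, "area_id", [f"A{i:03d}" for i in range(n_areas)])
    return df


class TestZStandardize:
    def test_three_point_column(self):
        df = pd.DataFrame({"poverty": [1.0, 2.0, 3.0]})
        out = z_standardize(df, ["poverty"])
        assert np.allclose(out["poverty"], [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, rng):
        df = make_indicator_table(rng)
        out = z_standardize(df)
        for c in INDICATOR_COLUMNS:
            assert abs(out[c].mean()) < 1e-12
            assert out[c].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        df = make_indicator_table(rng)
        once = z_standardize(df)
        twice = z_standardize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_constant_column_names_the_indicator(self):
        df = pd.DataFrame({"job_security": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="job_security"):
            z_standardize(df, ["job_security"])

    def test_outcome_column_untouched(self, rng):
        df = make_indicator_table(rng)
        df["qale"] = rng.normal(65, 3, len(df))
        out = z_standardize(df)
        assert np.allclose(out["qale"], df["qale"])


class TestAssociationModel:
    def test_matches_normal_equations_and_t_quantile_oracle(self, rng):
        """Coefficients, CIs and adjusted R^2 against a hand-rolled
        normal-equations + t-distribution oracle on a 40-area fixture."""
        ind = make_indicator_table(rng, n_areas=40)
        beta_true = rng.uniform(-1, 1, len(INDICATOR_COLUMNS))
        Z = z_standardize(ind)[list(INDICATOR_COLUMNS)].to_numpy()
        y = 65.0 + Z @ beta_true + rng.normal(0, 1.0, 40)
        qale = pd.DataFrame({"area_id": ind["area_id"], "qale": y})
        res = fit_association_model(qale, ind)

        X = np.column_stack([np.ones(40), Z])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta_hat = XtX_inv @ X.T @ y
        resid = y - X @ beta_hat
        df_resid = 40 - X.shape[1]
        sigma2 = resid @ resid / df_resid
        se = np.sqrt(np.diag(XtX_inv) * sigma2)
        tq = t_dist.ppf(0.975, df_resid)
        assert np.abs(res.coefficients["beta"].to_numpy() - beta_hat[1:]).max() < 1e-8
        assert np.abs(
            res.coefficients["ci_lo"].to_numpy() - (beta_hat[1:] - tq * se[1:])
        ).max() < 1e-8
        assert np.abs(
            res.coefficients["ci_hi"].to_numpy() - (beta_hat[1:] + tq * se[1:])
        ).max() < 1e-8
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot
        adj = 1.0 - (1.0 - r2) * (40 - 1) / (40 - len(INDICATOR_COLUMNS) - 1)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.adj_r2 == pytest.approx(adj, abs=1e-10)

    def test_pure_noise_outcome_has_near_zero_adjusted_r2(self):
        rng = np.random.default_rng(991)
        ind = make_indicator_table(rng, n_areas=200)
        qale = pd.DataFrame(
            {"area_id": ind["area_id"], "qale": rng.normal(65, 3, 200)}
        )
        res = fit_association_model(qale, ind)
        assert abs(res.adj_r2) < 0.15

    def test_standardised_betas_invariant_to_affine_indicator_rescaling(self, rng):
        ind = make_indicator_table(rng)
        y = rng.normal(65, 3, len(ind))
        qale = pd.DataFrame({"area_id": ind["area_id"], "qale": y})
        res1 = fit_association_model(qale, ind)
        rescaled = ind.copy()
        rescaled["poverty"] = 100.0 * rescaled["poverty"] - 7.0
        res2 = fit_association_model(qale, rescaled)
        assert np.allclose(
            res1.coefficients["beta"], res2.coefficients["beta"], atol=1e-10
        )

    def test_too_few_areas_rejected(self, rng):
        ind = make_indicator_table(rng, n_areas=10)
        qale = pd.DataFrame({"area_id": ind["area_id"], "qale": rng.normal(65, 3, 10)})
        with pytest.raises(ValueError, match="areas"):
            fit_association_model(qale, ind)

    def test_collinear_indicators_warn(self, rng):
        ind = make_indicator_table(rng, n_areas=40)
        ind["decent_pay"] = 2.0 * ind["poverty"] + 1e-9 * rng.normal(size=40)
        qale = pd.DataFrame({"area_id": ind["area_id"], "qale": rng.normal(65, 3, 40)})
        with pytest.warns(UserWarning, match="collinear"):
            fit_association_model(qale, ind)


class TestNationalMeans:
    def test_hand_weighted_example(self):
        qale = pd.DataFrame(
            {"area_id": ["A", "B"], "sex": ["F", "F"], "qale": [60.0, 70.0]}
        )
        pops = pd.DataFrame({"area_id": ["A", "B"], "population": [100, 300]})
        nations = pd.DataFrame({"area_id": ["A", "B"], "nation": ["X", "X"]})
        out = weighted_national_mean(qale, pops, nations)
        assert out["qale_weighted_mean"].iloc[0] == pytest.approx(67.5)

    def test_equal_populations_give_simple_mean(self, rng):
        q = rng.normal(65, 3, 6)
        qale = pd.DataFrame(
            {"area_id": [f"A{i}" for i in range(6)], "sex": "M", "qale": q}
        )
        pops = pd.DataFrame({"area_id": qale["area_id"], "population": 1000})
        nations = pd.DataFrame({"area_id": qale["area_id"], "nation": "X"})
        out = weighted_national_mean(qale, pops, nations)
        assert out["qale_weighted_mean"].iloc[0] == pytest.approx(q.mean())

    def test_single_area_nation_returns_its_own_value(self):
        qale = pd.DataFrame({"area_id": ["A"], "sex": ["F"], "qale": [63.2]})
        pops = pd.DataFrame({"area_id": ["A"], "population": [5000]})
        nations = pd.DataFrame({"area_id": ["A"], "nation": ["Solo"]})
        out = weighted_national_mean(qale, pops, nations)
        assert out["qale_weighted_mean"].iloc[0] == 63.2

    def test_mean_bounded_by_member_extremes(self, rng):
        qale = pd.DataFrame(
            {"area_id": [f"A{i}" for i in range(8)], "sex": "F",
             "qale": rng.normal(65, 4, 8)}
        )
        pops = pd.DataFrame(
            {"area_id": qale["area_id"], "population": rng.integers(1000, 9000, 8)}
        )
        nations = pd.DataFrame({"area_id": qale["area_id"], "nation": "X"})
        out = weighted_national_mean(qale, pops, nations)
        val = out["qale_weighted_mean"].iloc[0]
        assert qale["qale"].min() <= val <= qale["qale"].max()


#: Published within-nation QALE extremes (years): the lowest- and
#: highest-ranked local authorities per nation and sex.
PUBLISHED_EXTREMES = [
    # nation, sex, low area, low QALE, high area, high QALE, printed gap
    ("Wales", "F", "Merthyr Tydfil", 56.9, "Vale of Glamorgan", 71.4, 14.5),
    ("Wales", "M", "Merthyr Tydfil", 57.5, "Vale of Glamorgan", 71.4, 13.9),
    ("England", "F", "Mansfield", 56.3, "Runnymede", 77.7, 21.4),
    ("England", "M", "Mansfield", 57.7, "Runnymede", 77.2, 19.5),
]


class TestRangeReport:
    def test_published_extremes_reproduce_printed_differences(self):
        rows, nation_rows = [], []
        for nation, sex, lo_area, lo, hi_area, hi, _ in PUBLISHED_EXTREMES:
            rows += [
                {"area_id": lo_area, "sex": sex, "qale": lo},
                {"area_id": hi_area, "sex": sex, "qale": hi},
            ]
            nation_rows += [
                {"area_id": lo_area, "nation": nation},
                {"area_id": hi_area, "nation": nation},
            ]
        qale = pd.DataFrame(rows).drop_duplicates()
        nations = pd.DataFrame(nation_rows).drop_duplicates()
        report = range_report(qale, nations)
        for nation, sex, lo_area, lo, hi_area, hi, gap in PUBLISHED_EXTREMES:
            row = report[(report["nation"] == nation) & (report["sex"] == sex)]
            assert row["range"].iloc[0] == pytest.approx(gap, abs=1e-9)
            assert row["min_area"].iloc[0] == lo_area
            assert row["max_area"].iloc[0] == hi_area

    def test_equal_areas_give_zero_range(self):
        qale = pd.DataFrame(
            {"area_id": ["A", "B"], "sex": ["F", "F"], "qale": [64.0, 64.0]}
        )
        nations = pd.DataFrame({"area_id": ["A", "B"], "nation": ["X", "X"]})
        assert range_report(qale, nations)["range"].iloc[0] == 0.0


class TestSexGapReport:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["area_id", "sex", "le", "qale"])

    def test_identical_sexes_give_zero_gaps(self):
        df = self._frame(
            [("A", "F", 80.0, 65.0), ("A", "M", 80.0, 65.0)]
        )
        per_area, summary = sex_gap_report(df)
        assert per_area["le_gap"].iloc[0] == 0.0
        assert per_area["qale_gap"].iloc[0] == 0.0
        assert summary["n_reversals"] == 0

    def test_constructed_reversal_is_flagged(self):
        """Female LE advantage with female QALE disadvantage."""
        df = self._frame(
            [("A", "F", 83.0, 63.0), ("A", "M", 79.0, 64.0)]
        )
        _, summary = sex_gap_report(df)
        assert summary["n_reversals"] == 1
        assert summary["n_female_le_advantage"] == 1
        assert summary["n_female_qale_advantage"] == 0

    def test_gaps_match_direct_subtraction(self, rng):
        rows = []
        for i in range(5):
            rows.append((f"A{i}", "F", 80 + rng.normal(), 65 + rng.normal()))
            rows.append((f"A{i}", "M", 76 + rng.normal(), 64 + rng.normal()))
        df = self._frame(rows)
        per_area, _ = sex_gap_report(df)
        wide = df.pivot(index="area_id", columns="sex", values="qale")
        expected = (wide["F"] - wide["M"]).sort_index()
        got = per_area.set_index("area_id")["qale_gap"].sort_index()
        assert np.allclose(got, expected)

    def test_area_missing_one_sex_is_skipped_with_warning(self):
        df = self._frame(
            [("A", "F", 83.0, 65.0), ("A", "M", 79.0, 64.0), ("B", "F", 82.0, 66.0)]
        )
        with pytest.warns(UserWarning, match="skipped"):
            per_area, summary = sex_gap_report(df)
        assert summary["n_areas"] == 1
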