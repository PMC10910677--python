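"""Survey cell means, the two-stage score model, and the utility mapping."""

import numpy as np
import pandas as pd
import pytest

from qale_smallarea.utility import (
    UtilityMapping,
    build_utility_schedule,
    compute_cell_means,
    estimate_utility_schedules,
    fit_score_model,
    map_to_utility,
    predict_scores,
)


def make_survey(rows):
    df = pd.DataFrame(rows, columns=["area_id", "sex", "age", "pcs", "mcs", "weight"])
    df.insert(0, "person_id", np.arange(1, len(df) + 1))
    return df


class TestCellMeans:
    def test_hand_weighted_mean(self):
        survey = make_survey(
            [("A", "F", 40, 40.0, 40.0, 1.0), ("A", "F", 42, 48.0, 48.0, 3.0)]
        )
        cells = compute_cell_means(survey)
        assert len(cells) == 1
        assert cells["mean_pcs"].iloc[0] == pytest.approx(46.0)
        assert cells["n"].iloc[0] == 2

    def test_single_respondent_cell(self):
        survey = make_survey([("A", "M", 25, 51.3, 47.2, 2.5)])
        cells = compute_cell_means(survey)
        assert cells["mean_pcs"].iloc[0] == pytest.approx(51.3)
        assert cells["n"].iloc[0] == 1
        assert cells["age_band"].iloc[0] == "20-29"

    def test_equal_weights_give_arithmetic_mean(self, rng):
        scores = rng.normal(50, 8, 10)
        survey = make_survey(
            [("A", "F", 33, s, 50.0, 2.0) for s in scores]
        )
        cells = compute_cell_means(survey)
        assert cells["mean_pcs"].iloc[0] == pytest.approx(scores.mean())

    def test_teenagers_pool_into_lowest_band(self):
        survey = make_survey(
            [("A", "F", 16, 50.0, 50.0, 1.0), ("A", "F", 19, 52.0, 50.0, 1.0)]
        )
        cells = compute_cell_means(survey)
        assert list(cells["age_band"]) == ["0-19"]

    def test_empty_survey_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_cell_means(make_survey([]))

    def test_non_positive_weight_rejected(self):
        survey = make_survey([("A", "F", 30, 50.0, 50.0, 0.0)])
        with pytest.raises(ValueError, match="weight"):
            compute_cell_means(survey)


class TestMapping:
    def test_constant_mapping(self):
        m = UtilityMapping(intercept=0.7, pcs=0.0, mcs=0.0)
        assert map_to_utility(10.0, 90.0, m) == pytest.approx(0.7)

    def test_clamp_bounds(self):
        m = UtilityMapping(intercept=1.2, pcs=0.0, mcs=0.0)
        assert map_to_utility(0.0, 0.0, m) == 1.0
        assert map_to_utility(0.0, 0.0, m, clamp=False) == pytest.approx(1.2)
        low = UtilityMapping(intercept=-0.3, pcs=0.0, mcs=0.0)
        assert map_to_utility(0.0, 0.0, low) == 0.0

    def test_full_quadratic_hand_evaluation(self):
        m = UtilityMapping(
            intercept=0.2, pcs=0.004, mcs=0.003, pcs2=1e-5, mcs2=-2e-5, pcs_mcs=3e-6
        )
        pcs, mcs = 50.0, 50.0
        expected = (
            0.2 + 0.004 * 50 + 0.003 * 50 + 1e-5 * 2500 - 2e-5 * 2500 + 3e-6 * 2500
        )
        assert map_to_utility(pcs, mcs, m, clamp=False) == pytest.approx(expected)

    def test_missing_coefficient_rejected(self):
        with pytest.raises(ValueError, match="pcs2"):
            UtilityMapping.from_dict({"intercept": 0.1, "pcs": 0.0, "mcs": 0.0})


def make_cell_fixture(rng, n_areas=3):
    """Balanced cell-mean table across areas, sexes and three bands."""
    rows = []
    for a in range(n_areas):
        for sex in ("F", "M"):
            for band in ("20-29", "30-39", "40-49"):
                rows.append(
                    {
                        "area_id": f"A{a}",
                        "sex": sex,
                        "age_band": band,
                        "mean_pcs": rng.normal(50, 3),
                        "mean_mcs": rng.normal(48, 3),
                        "n": int(rng.integers(2, 30)),
                        "var_within": rng.uniform(0.001, 0.01),
                    }
                )
    return pd.DataFrame(rows)


class TestScoreModel:
    def test_coefficients_solve_weighted_normal_equations(self, rng):
        """WLS estimates equal the normal-equations solution on the
        model's own design matrix (independent solver)."""
        cells = make_cell_fixture(rng)
        model = fit_score_model(cells, "pcs")
        X, w = model.exog, model.weights
        y = cells["mean_pcs"].to_numpy()
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert np.abs(model.params - beta).max() < 1e-8

    def test_single_area_model_is_saturated(self, rng):
        cells = make_cell_fixture(rng, n_areas=1)
        model = fit_score_model(cells, "mcs")
        fitted = model.exog @ model.params
        assert np.allclose(fitted, cells["mean_mcs"], atol=1e-8)

    def test_constant_shift_moves_only_intercept(self, rng):
        cells = make_cell_fixture(rng)
        m0 = fit_score_model(cells, "pcs")
        shifted = cells.assign(mean_pcs=cells["mean_pcs"] + 5.0)
        m1 = fit_score_model(shifted, "pcs")
        delta = m1.params - m0.params
        assert delta[0] == pytest.approx(5.0, abs=1e-8)
        assert np.abs(delta[1:]).max() < 1e-8

    def test_prediction_grid_is_complete_rectangle(self, rng):
        cells = make_cell_fixture(rng, n_areas=4).iloc[:-3]  # drop some cells
        model = fit_score_model(cells, "pcs")
        pred = predict_scores(model)
        assert len(pred) == 4 * 2 * 3

    def test_predictions_match_design_times_params(self, rng):
        cells = make_cell_fixture(rng)
        model = fit_score_model(cells, "pcs")
        pred = predict_scores(model, cells)
        assert np.allclose(pred["pred_pcs"], model.exog @ model.params)

    def test_unseen_level_rejected(self, rng):
        cells = make_cell_fixture(rng)
        model = fit_score_model(cells, "pcs")
        bad = pd.DataFrame(
            {"area_id": ["Z9"], "sex": ["F"], "age_band": ["20-29"]}
        )
        with pytest.raises(ValueError, match="unseen"):
            predict_scores(model, bad)


class TestUtilitySchedule:
    def test_identical_respondents_give_zero_variance(self):
        survey = make_survey([("A", "F", 35, 50.0, 50.0, 1.0)] * 5)
        sched = estimate_utility_schedules(survey)
        assert sched["var_pi"].iloc[0] == pytest.approx(0.0, abs=1e-15)
        assert sched["pi"].iloc[0] == pytest.approx(
            float(map_to_utility(50.0, 50.0))
        )

    def test_duplicating_every_respondent_halves_var_pi(self, rng):
        rows = [
            ("A", "F", 30 + int(rng.integers(0, 9)), rng.normal(50, 9),
             rng.normal(48, 9), float(rng.uniform(0.5, 2)))
            for _ in range(12)
        ]
        s1 = make_survey(rows)
        s2 = make_survey(rows + rows)
        v1 = estimate_utility_schedules(s1)["var_pi"].iloc[0]
        v2 = estimate_utility_schedules(s2)["var_pi"].iloc[0]
        assert v2 == pytest.approx(v1 / 2.0, rel=1e-9)

    def test_pi_always_within_unit_interval(self, rng):
        for _ in range(100):
            rows = [
                ("A", sex, age + int(rng.integers(0, 5)),
                 rng.normal(50, 25), rng.normal(50, 25), float(rng.uniform(0.2, 3)))
                for sex in ("F", "M")
                for age in (20, 30, 40)
            ]
            sched = estimate_utility_schedules(make_survey(rows))
            assert ((sched["pi"] >= 0) & (sched["pi"] <= 1)).all()

    def test_unobserved_cell_borrows_pooled_variance(self, rng):
        # area B has no 40-49 respondents; prediction exists with pooled var
        rows = []
        for area in ("A", "B"):
            for age in (25, 35):
                for _ in range(6):
                    rows.append(
                        (area, "F", age + int(rng.integers(0, 5)),
                         rng.normal(50, 8), rng.normal(48, 8), 1.0)
                    )
        for _ in range(6):
            rows.append(("A", "F", 45, rng.normal(49, 8), rng.normal(47, 8), 1.0))
        sched = estimate_utility_schedules(make_survey(rows))
        missing = sched[(sched["area_id"] == "B") & (sched["age_band"] == "40-49")]
        assert len(missing) == 1
        assert missing["n"].iloc[0] == 0
        assert missing["var_pi"].iloc[0] > 0
        assert np.isfinite(missing["pi"].iloc[0])

    def test_two_stage_reproduces_raw_means_in_saturated_case(self, rng):
        """Single area: predictions equal raw weighted cell means exactly."""
        rows = [
            ("A", sex, age, rng.normal(50, 10), rng.normal(48, 10),
             float(rng.uniform(0.5, 2)))
            for sex in ("F", "M")
            for age in (22, 27, 33, 38, 45)
            for _ in range(4)
        ]
        survey = make_survey(rows)
        cells = compute_cell_means(survey)
        model = fit_score_model(cells, "pcs")
        pred = predict_scores(model, cells)
        assert np.allclose(pred["pred_pcs"], cells["mean_pcs"], atol=1e-8)

    def test_higher_area_effect_raises_mapped_utility(self, rng):
        """With a PCS-monotone mapping and MCS held fixed, the area with
        the larger fixed effect gets the higher utility schedule."""
        rows = []
        for area, shift in (("A", 0.0), ("B", 4.0)):
            for sex in ("F", "M"):
                for age in (25, 35, 45):
                    for _ in range(5):
                        rows.append(
                            (area, sex, age + int(rng.integers(0, 5)),
                             50 + shift + rng.normal(0, 2), 48.0, 1.0)
                        )
        sched = estimate_utility_schedules(make_survey(rows))
        wide = sched.pivot_table(index=["sex", "age_band"], columns="area_id", values="pi")
        assert (wide["B"] >= wide["A"] - 1e-12).all()
        assert wide["B"].mean() > wide["A"].mean()


class TestBuildScheduleValidation:
    def test_missing_prediction_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_utility_schedule(
                pd.DataFrame({"area_id": [], "sex": []}), pd.DataFrame()
            )
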