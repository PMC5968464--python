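"""The four prevalence estimators and the linear list regression."""

import numpy as np
import pandas as pd
import pytest

from itemcount import (
    ListExperiment,
    ListRegression,
    ResponseModelConfig,
    direct_prevalence,
    generate_cohort,
    lr_difference_in_means,
    lr_linear_regression,
    truth_prevalence,
    truth_prevalence_adjusted,
    truth_summary,
)
from itemcount.estimators import EstimationError


def make_records(design, a_counts, b_ctrl_answers, block_id=3, b_direct=None,
                 strata=None):
    """Minimal canonical frame carrying one block's data."""
    J = design.n_controls
    rows = []
    for i, c in enumerate(a_counts):
        row = {"respondent_id": f"a{i}", "arm": "A", "stratum": "negative",
               f"count_block{block_id}": float(c), f"pos_block{block_id}": 1.0}
        rows.append(row)
    for i, answers in enumerate(b_ctrl_answers):
        row = {"respondent_id": f"b{i}", "arm": "B", "stratum": "negative"}
        for k, v in enumerate(answers, start=1):
            row[f"ctrl_b{block_id}_i{k}"] = float(v)
        row[f"direct_b{block_id}"] = float(b_direct[i]) if b_direct else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    if strata is not None:
        df["stratum"] = strata
    return df


def sums_to_answers(sums, J=4):
    return [[1] * s + [0] * (J - s) for s in sums]


class TestDifferenceInMeans:
    def test_identical_constant_arms(self, design):
        rec = make_records(design, [3, 3, 3], sums_to_answers([3, 3, 3]))
        est = lr_difference_in_means(rec, design, 3)
        assert est.point == 0.0 and est.se == 0.0
        assert est.ci_low == est.ci_high == 0.0

    def test_hand_arithmetic(self, design):
        # mean{3,2,4,1} - mean{2,2,1,3} = 2.5 - 2.0
        rec = make_records(design, [3, 2, 4, 1], sums_to_answers([2, 2, 1, 3]))
        est = lr_difference_in_means(rec, design, 3)
        assert est.point == pytest.approx(0.5)
        # Welch SE from sample variances 5/3 ... 2/3
        se = np.sqrt(np.var([3, 2, 4, 1], ddof=1) / 4 + np.var([2, 2, 1, 3], ddof=1) / 4)
        assert est.se == pytest.approx(se)
        assert est.ci_low == pytest.approx(0.5 - 1.96 * se)
        assert est.n_treat == 4 and est.n_control == 4

    def test_empty_arm_names_arm_and_filter(self, design):
        rec = make_records(design, [3, 2], sums_to_answers([2, 2]))
        rec = rec[rec["arm"] == "A"]
        with pytest.raises(EstimationError, match="arm B.*full"):
            lr_difference_in_means(rec, design, 3)

    def test_point_may_exceed_unit_interval(self, design):
        rec = make_records(design, [5, 5], sums_to_answers([0, 0]))
        est = lr_difference_in_means(rec, design, 3)
        assert est.point == 5.0  # reported unclipped

    def test_ci_symmetric(self, noiseless_cohort, design):
        est = lr_difference_in_means(noiseless_cohort, design, 2)
        assert est.point - est.ci_low == pytest.approx(est.ci_high - est.point)


class TestDirectPrevalence:
    def test_degenerate_all_affirmative(self, design):
        rec = make_records(design, [3], sums_to_answers([2, 2]), b_direct=[1, 1])
        est = direct_prevalence(rec, design, 3)
        assert est.point == 1.0 and est.se == 0.0 and est.ci_high == 1.0

    def test_three_of_ten(self, design):
        rec = make_records(design, [3], sums_to_answers([1] * 10),
                           b_direct=[1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        est = direct_prevalence(rec, design, 3)
        assert est.point == pytest.approx(0.30)
        assert est.se == pytest.approx(np.sqrt(0.3 * 0.7 / 10))
        assert est.se == pytest.approx(np.sqrt(0.021), rel=1e-12)

    def test_ci_truncated_to_unit_interval(self, design):
        rec = make_records(design, [3], sums_to_answers([1, 1, 1]),
                           b_direct=[1, 1, 0])
        est = direct_prevalence(rec, design, 3)
        assert 0.0 <= est.ci_low <= est.point <= est.ci_high <= 1.0

    def test_no_arm_b_records(self, design):
        rec = make_records(design, [3, 2], sums_to_answers([2]))
        rec = rec[rec["arm"] == "A"]
        with pytest.raises(EstimationError, match="no Arm B"):
            direct_prevalence(rec, design, 3)


class TestTruthPrevalence:
    def test_refusers_excluded_for_hiv_item(self, design, noiseless_cohort):
        est = truth_prevalence(noiseless_cohort, design, "hiv_negative")
        non_ref = noiseless_cohort[noiseless_cohort["stratum"] != "refused"]
        assert est.point == pytest.approx(non_ref["truth_hiv_negative"].mean())
        assert est.n_control == len(non_ref)

    def test_all_refused_unavailable(self, design):
        cfg = ResponseModelConfig(stratum_props=(0.0, 0.0, 0.0, 1.0), seed=1)
        coh = generate_cohort(200, design, cfg)
        est = truth_prevalence(coh, design, "hiv_negative")
        assert not est.available
        assert "truth" in est.note

    def test_refusal_item_uses_full_sample(self, design, noiseless_cohort):
        est = truth_prevalence(noiseless_cohort, design, "refused_test")
        assert est.point == pytest.approx(noiseless_cohort["truth_refused"].mean())


class TestAdjustedTruth:
    def test_worked_counts(self, design):
        """483 respondents, 106 tested negative, 72 refusers imputed at 31%:
        (106 + 0.31 * 72) / 483 = 128.32 / 483."""
        n_neg, n_ref, n_pos = 106, 72, 483 - 106 - 72
        strata = (["negative"] * n_neg + ["pos_linked"] * n_pos + ["refused"] * n_ref)
        df = pd.DataFrame({
            "respondent_id": [f"r{i}" for i in range(483)],
            "arm": "B", "stratum": strata,
            "truth_hiv_negative": [1.0] * n_neg + [0.0] * n_pos + [np.nan] * n_ref,
        })
        est = truth_prevalence_adjusted(df, design, pop_prev=0.31)
        assert est.point == pytest.approx(128.32 / 483)
        assert est.n_control == 483

    def test_no_refusers_reduces_to_truth(self, design):
        cfg = ResponseModelConfig(stratum_props=(0.3, 0.3, 0.4, 0.0), seed=5)
        coh = generate_cohort(600, design, cfg)
        adj = truth_prevalence_adjusted(coh, design, pop_prev=0.31)
        tru = truth_prevalence(coh, design, "hiv_negative")
        assert adj.point == pytest.approx(tru.point, abs=1e-15)
        assert adj.ci_high - adj.ci_low == pytest.approx(tru.ci_high - tru.ci_low)

    def test_ci_halfwidth_equals_nonrefused_interval(self, design, noiseless_cohort):
        adj = truth_prevalence_adjusted(noiseless_cohort, design, pop_prev=0.31)
        tru = truth_prevalence(noiseless_cohort, design, "hiv_negative")
        assert (adj.ci_high - adj.ci_low) == pytest.approx(
            tru.ci_high - tru.ci_low, abs=1e-12)


class TestModelResults:
    def test_fit_covers_items_and_methods(self, noiseless_cohort, design):
        res = ListExperiment(noiseless_cohort, design).fit()
        df = res.to_frame()
        assert set(df["item_id"]) == set(design.sensitive_items)
        assert set(df["method"]) >= {"lr", "direct", "truth"}
        # tutorial block flagged
        assert df.loc[df["item_id"] == "brushed_teeth", "tutorial"].eq(1).all()
        assert "Prevalence estimates" in res.summary()

    def test_lr_close_to_truth_on_noiseless_cohort(self, noiseless_cohort, design):
        res = ListExperiment(noiseless_cohort, design).fit(items=["hiv_negative"])
        lr = res.get("hiv_negative", "lr")
        tru = truth_summary(noiseless_cohort, design).loc["hiv_negative", "overall"]
        assert abs(lr.point - tru) < 3 * lr.se

    def test_subpopulation_filtering(self, noiseless_cohort, design):
        res = ListExperiment(noiseless_cohort, design).fit(
            items=["hiv_negative"], subpop="negative", methods=("truth",))
        assert res.estimates[0].point == 1.0


class TestListRegression:
    def test_intercept_only_equals_difference_in_means(self, design):
        """Algebraic identity: interaction least squares with only an
        intercept reproduces the difference in means to machine precision."""
        for seed in (1, 2, 3):
            coh = generate_cohort(700, design,
                                  ResponseModelConfig(lambda_direct=0.2, seed=seed))
            for block_id in (2, 3):
                reg = lr_linear_regression(coh, design, block_id, [])
                dim = lr_difference_in_means(coh, design, block_id)
                assert reg.delta["const"] == pytest.approx(dim.point, abs=1e-10)

    def test_covariate_recovery(self, design):
        """Sensitive prevalence 0.2 + 0.4x is recovered by the interaction
        coefficients on a large noiseless cohort."""
        cfg = ResponseModelConfig(
            item_prevs={"used_condom": (0.2, {"x": 0.4})},
            covariates={"x": ("uniform", 0.0, 1.0)}, seed=8)
        coh = generate_cohort(20000, design, cfg)
        blk = design.block_for_item("used_condom")
        reg = lr_linear_regression(coh, design, blk.block_id, ["x"])
        assert abs(reg.delta["const"] - 0.2) < 3 * reg.delta_se["const"]
        assert abs(reg.delta["x"] - 0.4) < 3 * reg.delta_se["x"]
        assert reg.n_total == reg.n_arm_a + reg.n_arm_b == 20000

    def test_rank_deficiency_names_columns(self, design, noiseless_cohort):
        coh = noiseless_cohort.copy()
        coh["dup"] = coh["truth_refused"]
        blk = design.block_for_item("refused_test")
        with pytest.raises(EstimationError, match="dup"):
            ListRegression(coh, design, blk.block_id,
                           ["truth_refused", "dup"]).fit()

    def test_truth_association_detected(self, design):
        """With truthful answers, the refusal item's count shifts by one for
        true refusers: the interaction coefficient on truth is ~1."""
        coh = generate_cohort(8000, design, ResponseModelConfig(seed=13))
        blk = design.block_for_item("refused_test")
        reg = lr_linear_regression(coh, design, blk.block_id, ["truth_refused"])
        assert abs(reg.delta["truth_refused"] - 1.0) < 3 * reg.delta_se["truth_refused"]
        assert 0 <= reg.residual_se <= 1.2
        assert "Linear list-experiment regression" in reg.summary()

    def test_missing_covariate_errors(self, design, noiseless_cohort):
        with pytest.raises(EstimationError, match="absent"):
            ListRegression(noiseless_cohort, design, 3, ["ghost"]).fit()
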