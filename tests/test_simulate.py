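"""Synthetic-cohort generator: determinism, noiseless identities, and the
closed-form behaviour of the misreporting mechanism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from itemcount import ResponseModelConfig, generate_cohort, truth_summary
from itemcount.design import truth_column
from itemcount.estimators import arm_b_control_sums
from itemcount.simulate import ConfigError


class TestDeterminismAndConfig:
    def test_same_seed_identical_cohort(self, design):
        cfg = ResponseModelConfig(lambda_direct=0.2, epsilon_count=0.1, seed=5)
        a = generate_cohort(300, design, cfg)
        b = generate_cohort(300, design, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, design):
        a = generate_cohort(300, design, seed=1)
        b = generate_cohort(300, design, seed=2)
        assert not a.drop(columns="respondent_id").equals(b.drop(columns="respondent_id"))

    @pytest.mark.parametrize("kwargs", [
        dict(lambda_direct=1.5),
        dict(epsilon_count=-0.1),
        dict(stratum_props=(0.5, 0.5, 0.0, 0.1)),
        dict(stratum_props=(1.0, 0.0, 0.0)),
        dict(item_prevs={"used_condom": 2.0}),
    ])
    def test_invalid_config_raises_before_sampling(self, design, kwargs):
        with pytest.raises(ConfigError):
            generate_cohort(10, design, ResponseModelConfig(**kwargs))


class TestNoiselessIdentities:
    def test_counts_equal_true_block_sums_and_direct_equals_truth(self, design):
        """With every noise dial at 0, Arm A counts are exact block sums of
        truthful answers and Arm B direct answers equal truth."""
        coh = generate_cohort(1000, design, ResponseModelConfig(seed=3))
        b_rows = coh[coh["arm"] == "B"]
        for blk in design.blocks:
            t = b_rows[truth_column(blk.sensitive_item_id)]
            d = b_rows[f"direct_b{blk.block_id}"]
            assert (d == t).all()
        # Arm A counts lie in range and, since controls are truthful and the
        # sensitive answer unflipped, equal controls + truth when we rebuild
        # the sum from the B-arm distributions in expectation; the exact
        # per-respondent identity is checked via the no-slip decomposition:
        a_rows = coh[coh["arm"] == "A"]
        for blk in design.blocks:
            counts = a_rows[f"count_block{blk.block_id}"]
            assert counts.between(0, design.n_controls + 1).all()
            t = a_rows[truth_column(blk.sensitive_item_id)]
            # count minus sensitive truth must be a feasible control sum
            resid = counts - t
            assert resid.between(0, design.n_controls).all()

    def test_truth_summary_equals_direct_prevalence_when_noiseless(
            self, noiseless_cohort, design):
        ts = truth_summary(noiseless_cohort, design)
        b = noiseless_cohort[noiseless_cohort["arm"] == "B"]
        for blk in design.blocks:
            direct = b[f"direct_b{blk.block_id}"].mean()
            truth_b = b[truth_column(blk.sensitive_item_id)].mean()
            assert direct == pytest.approx(truth_b, abs=1e-12)
        assert (ts["overall"] <= 1).all() and (ts["overall"] >= 0).all()


class TestStructure:
    def test_stratum_counts_near_quarter_each(self, design):
        """8000 draws at 25% per stratum land within binomial 99% bounds of
        2000 each."""
        coh = generate_cohort(8000, design, seed=7)
        counts = coh["stratum"].value_counts()
        half_width = 2.576 * np.sqrt(8000 * 0.25 * 0.75)
        for s in design.strata:
            assert abs(counts[s] - 2000) < half_width

    def test_stratum_determined_truth(self, noiseless_cohort):
        df = noiseless_cohort
        assert (df.loc[df["stratum"] == "negative", "truth_hiv_negative"] == 1).all()
        assert (df.loc[df["stratum"].isin(["pos_linked", "pos_unlinked"]),
                       "truth_hiv_negative"] == 0).all()
        assert (df["truth_refused"] == (df["stratum"] == "refused")).all()

    def test_refuser_hiv_truth_imputed_at_population_prevalence(self, design):
        cfg = ResponseModelConfig(pop_neg_prev=0.31, seed=21)
        coh = generate_cohort(20000, design, cfg)
        ref = coh.loc[coh["stratum"] == "refused", "truth_hiv_negative"]
        se = np.sqrt(0.31 * 0.69 / len(ref))
        assert abs(ref.mean() - 0.31) < 3 * se

    def test_arm_independent_of_truth_within_stratum(self, design):
        """Chi-square of arm x HIV truth within the refused stratum (the only
        stratum with within-stratum truth variation) is non-significant at
        roughly the nominal rate over repeated seeds."""
        rejections = 0
        n_seeds = 60
        for s in range(n_seeds):
            coh = generate_cohort(2000, design, seed=100 + s)
            ref = coh[coh["stratum"] == "refused"]
            tab = pd.crosstab(ref["arm"], ref["truth_hiv_negative"])
            if tab.shape == (2, 2):
                _, p, _, _ = stats.chi2_contingency(tab)
                rejections += p < 0.05
        # Binomial(60, 0.05): P(X > 8) < 0.005
        assert rejections <= 8

    def test_degenerate_stratum_gives_prevalence_one(self, design):
        cfg = ResponseModelConfig(stratum_props=(0.0, 0.0, 1.0, 0.0), seed=2)
        coh = generate_cohort(500, design, cfg)
        ts = truth_summary(coh, design)
        assert ts.loc["hiv_negative", "overall"] == 1.0

    def test_truth_summary_marks_missing_truth_unavailable(self, design, tiny_canonical):
        df = tiny_canonical.drop(columns=["truth_used_condom"])
        ts = truth_summary(df, design)
        assert np.isnan(ts.loc["used_condom", "overall"])
        assert ts.loc["brushed_teeth", "overall"] == 1.0


class TestMisreporting:
    def test_direct_prevalence_shifts_by_lambda_one_minus_pi(self, design, misreport_cohort):
        """Under flip probability lambda toward the desirable answer, a +1
        item's observed direct prevalence is pi + lambda(1 - pi)."""
        coh = misreport_cohort  # lambda_direct = 0.3, n = 20000
        b = coh[coh["arm"] == "B"]
        t = b["truth_hiv_negative"]
        pi = t.mean()
        expected = pi + 0.3 * (1 - pi)
        observed = b["direct_b3"].mean()
        mc_se = np.sqrt(expected * (1 - expected) / len(b))
        assert abs(observed - expected) < 3 * mc_se

    def test_negative_sign_item_shifts_down(self, design):
        """A -1 item (desirable answer 'false') is deflated to pi(1 - lambda)."""
        cfg = ResponseModelConfig(lambda_direct=0.4, seed=31,
                                  item_prevs={"anal_sex": 0.30})
        coh = generate_cohort(20000, design, cfg)
        b = coh[coh["arm"] == "B"]
        pi = b["truth_anal_sex"].mean()
        expected = pi * (1 - 0.4)
        mc_se = np.sqrt(max(expected * (1 - expected), 1e-9) / len(b))
        assert abs(b["direct_b4"].mean() - expected) < 3 * mc_se

    def test_lambda_list_biases_counts_not_direct(self, design):
        """lambda_list inflates Arm A counts (via the contributed sensitive
        answer) while leaving direct answers truthful."""
        cfg = ResponseModelConfig(lambda_list=0.5, seed=41)
        coh = generate_cohort(30000, design, cfg)
        b = coh[coh["arm"] == "B"]
        assert (b["direct_b3"] == b["truth_hiv_negative"]).all()
        a = coh[coh["arm"] == "A"]
        pi_a = a["truth_hiv_negative"].mean()
        # mean count = mean control sum + pi + lambda(1 - pi)
        expected_sens = pi_a + 0.5 * (1 - pi_a)
        ctrl_mean = sum(design.block(3).control_probs)
        observed = a["count_block3"].mean()
        se = a["count_block3"].std(ddof=1) / np.sqrt(len(a))
        assert abs(observed - (ctrl_mean + expected_sens)) < 4 * se

    def test_epsilon_count_keeps_mean_but_inflates_variance(self, design):
        base = generate_cohort(30000, design, ResponseModelConfig(seed=51))
        noisy = generate_cohort(
            30000, design, ResponseModelConfig(epsilon_count=0.5, seed=51))
        a0 = base.loc[base["arm"] == "A", "count_block3"]
        a1 = noisy.loc[noisy["arm"] == "A", "count_block3"]
        se = np.sqrt(a0.var() / len(a0) + a1.var() / len(a1))
        # symmetric +-1 slips cancel in the mean (interior counts) ...
        assert abs(a0.mean() - a1.mean()) < 4 * se
        # ... but add variance
        assert a1.var(ddof=1) > a0.var(ddof=1)

    def test_covariate_dependent_prevalence(self, design):
        cfg = ResponseModelConfig(
            item_prevs={"used_condom": (0.2, {"x": 0.4})},
            covariates={"x": ("uniform", 0.0, 1.0)}, seed=61)
        coh = generate_cohort(40000, design, cfg)
        lo = coh[coh["x"] < 0.25]["truth_used_condom"]
        hi = coh[coh["x"] > 0.75]["truth_used_condom"]
        assert lo.mean() == pytest.approx(0.2 + 0.4 * 0.125, abs=0.02)
        assert hi.mean() == pytest.approx(0.2 + 0.4 * 0.875, abs=0.02)
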