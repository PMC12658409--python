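import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import gesturebias as gb
from gesturebias.design import Condition
from gesturebias.simulate import Exp1Params, LearnerParams, RT_THRESHOLD_MS


class TestTransformRating:
    @pytest.mark.parametrize("raw, expected", [(2, 98), (50, 50), (73, 73), (0, 100), (100, 100)])
    def test_folding(self, raw, expected):
        assert gb.transform_rating(raw) == expected

    def test_out_of_range_rejected(self):
        for bad in (-1, 100.5):
            with pytest.raises(ValueError):
                gb.transform_rating(bad)


class TestExp1:
    def test_two_rows_per_participant(self, exp1_cohort):
        assert len(exp1_cohort) == 2 * 2 * 160
        per = exp1_cohort.groupby("participant_id")["phase"].agg(sorted)
        assert all(p == ["slider", "test"] for p in per)

    def test_unbiased_coin_choice_rate(self):
        params = Exp1Params(
            n_per_condition=5000, theta_descriptive=0.5, theta_possessive=0.5
        )
        t = gb.simulate_exp1(params, seed=1)
        choice = t[t.phase == "test"]
        frac = choice["is_natural"].mean()  # natural == predicted order
        se = np.sqrt(0.25 / len(choice))
        assert abs(frac - 0.5) < 3 * se

    def test_intercept_recovery_at_default_rate(self):
        """Cohorts at theta = 0.6375 recover an intercept near
        logit(0.6375) = 0.565 on average."""
        betas = []
        for seed in range(40):
            t = gb.simulate_exp1(Exp1Params(p_mismatch=0.0), seed=seed)
            choice = t[(t.phase == "test") & (t.meaning_type == "possessive")]
            k = int(choice["is_natural"].sum())
            betas.append(gb.fit_logistic_intercept(k, len(choice))["intercept"]["coef"])
        se_mean = 0.164 / np.sqrt(40)
        assert abs(np.mean(betas) - logit(0.6375)) < 3 * se_mean

    def test_determinism(self):
        a = gb.simulate_exp1(seed=9)
        b = gb.simulate_exp1(seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestExclusions:
    def test_fast_rt_excluded(self, exp1_cohort):
        clean, log = gb.apply_exclusions(exp1_cohort)
        choice = exp1_cohort[exp1_cohort.phase == "test"]
        fast_ids = set(choice.loc[choice.rt_ms < RT_THRESHOLD_MS, "participant_id"])
        assert fast_ids.isdisjoint(set(clean.participant_id))
        assert log.n_fast_rt + log.n_both == len(fast_ids)
        assert log.to_dict()["participants_retained"] == clean.participant_id.nunique()

    def test_slow_rt_agreeing_slider_retained(self, exp1_cohort):
        clean, _ = gb.apply_exclusions(exp1_cohort)
        choice = exp1_cohort[exp1_cohort.phase == "test"].set_index("participant_id")
        slider = exp1_cohort[exp1_cohort.phase == "slider"].set_index("participant_id")
        agree = (slider["slider_raw"] > 50) == (choice["order"] == "postnominal")
        keep = (choice["rt_ms"] >= RT_THRESHOLD_MS) & agree
        assert set(choice.index[keep]) == set(clean.participant_id)

    def test_no_mismatch_no_slider_exclusions(self):
        params = Exp1Params(p_mismatch=0.0, rt_mean_ms=30_000, rt_sd_ms=100)
        t = gb.simulate_exp1(params, seed=3)
        _, log = gb.apply_exclusions(t)
        assert log.n_excluded == 0

    def test_default_fast_rt_rate_near_ten_percent(self, exp1_cohort):
        _, log = gb.apply_exclusions(exp1_cohort)
        rate = (log.n_fast_rt + log.n_both) / log.n_input
        assert 0.04 < rate < 0.18

    def test_missing_fields_rejected(self, exp1_cohort):
        broken = exp1_cohort.copy()
        broken.loc[broken.phase == "test", "rt_ms"] = np.nan
        with pytest.raises(ValueError, match="rt_ms"):
            gb.apply_exclusions(broken)


class TestExp2Learners:
    def test_cohort_shape_and_ids(self, matcher_cohort):
        assert matcher_cohort.participant_id.nunique() == 200
        assert len(matcher_cohort) == 200 * 32
        sizes = (
            matcher_cohort[matcher_cohort.phase == "test"]
            .groupby("condition")["participant_id"]
            .nunique()
            .to_dict()
        )
        assert sizes == gb.EXP2_SAMPLE_SIZES

    def test_empty_sample_sizes_give_empty_frame(self):
        t = gb.simulate_exp2_experiment(sample_sizes={}, seed=0)
        assert t.empty

    def test_determinism_byte_identical(self, tmp_path):
        a = gb.simulate_exp2_experiment(seed=42)
        b = gb.simulate_exp2_experiment(seed=42)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_pure_matcher_rate(self, matcher_cohort):
        test = matcher_cohort[matcher_cohort.phase == "test"]
        se = np.sqrt(0.75 * 0.25 / len(test))
        assert abs(test["is_majority"].mean() - 0.75) < 3 * se

    def test_extreme_regularizer_is_categorical(self):
        params = gb.regularizer(lam=50.0, sigma_u=0.0)
        t = gb.simulate_exp2_participant(
            Condition.from_label("natural descriptive"), params, seed=1
        )
        test = t[t.phase == "test"]
        assert test["is_majority"].all()
        m = gb.participant_metrics(t)
        assert m["delta_h"].iloc[0] == pytest.approx(-gb.shannon_entropy((12, 4)))

    def test_noiseless_conditioner_reaches_one_bit(self):
        params = gb.conditioner(epsilon=0.0)
        t = gb.simulate_exp2_participant(
            Condition.from_label("unnatural possessive"), params, seed=2
        )
        m = gb.participant_metrics(t)
        assert m["mi"].iloc[0] == pytest.approx(1.0)

    def test_delta_h_monotone_in_regularization_strength(self):
        means = []
        for lam in (1.0, 2.0, 4.0, 8.0):
            t = gb.simulate_exp2_experiment(
                params=gb.regularizer(lam=lam, sigma_u=0.0), seed=77
            )
            means.append(gb.participant_metrics(t)["delta_h"].mean())
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_delta_mi_increases_with_conditioner_weight(self):
        means = []
        for w in (0.0, 0.5, 1.0):
            params = LearnerParams(
                w_matcher=1.0 - w, w_regularizer=0.0, w_conditioner=w, epsilon=0.1
            )
            t = gb.simulate_exp2_experiment(params=params, seed=88)
            means.append(gb.participant_metrics(t)["delta_mi"].mean())
        assert means[0] < means[1] < means[2]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LearnerParams(w_matcher=0.7, w_regularizer=0.7, w_conditioner=-0.4)
        with pytest.raises(ValueError):
            LearnerParams(lam=0.5)
        with pytest.raises(ValueError):
            LearnerParams(epsilon=0.9)
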