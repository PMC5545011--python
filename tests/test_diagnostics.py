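"""Accuracy statistics: exact intervals, ROC/AUC, paired comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from _oracles import pairwise_auc
from porc.diagnostics import (
    BLOCK,
    NO_BLOCK,
    ContingencyTable,
    auc_concordance,
    clopper_pearson,
    compare_auc,
    compare_auc_bootstrap,
    dichotomize_reference,
    dichotomize_tactile,
    evaluate_tool,
    model_correlation,
    roc,
    sens_spec,
)
from porc.errors import UndefinedMarginError
from porc.simulate import SimulationConfig, simulate_cohort


class TestDichotomisation:
    @pytest.mark.parametrize(
        "tofr, eps, expected",
        [
            (0.69, 0.7, BLOCK),
            (0.70, 0.7, NO_BLOCK),  # strict inequality at the boundary
            (0.89, 0.9, BLOCK),
            (0.90, 0.9, NO_BLOCK),
        ],
    )
    def test_reference_cut_is_strict(self, tofr, eps, expected):
        assert dichotomize_reference(tofr, eps) == expected

    def test_epsilon_must_be_plausible(self):
        with pytest.raises(ValueError):
            dichotomize_reference(0.5, 1.5)

    def test_tactile_judgement_mapping(self):
        assert dichotomize_tactile("palpable") == BLOCK
        assert dichotomize_tactile("not palpable") == NO_BLOCK
        assert dichotomize_tactile("not_palpable") == NO_BLOCK

    def test_unknown_tactile_label_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_tactile("maybe")


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, lower_pct, upper_pct",
        [
            (0, 7, 0.0, 41.0),
            (7, 7, 59.0, 100.0),
            (3, 7, 9.9, 81.6),
            (71, 71, 94.9, 100.0),
            (10, 29, 17.9, 54.3),
        ],
    )
    def test_published_interval_values(self, x, n, lower_pct, upper_pct):
        lo, hi = clopper_pearson(x, n)
        assert round(lo * 100, 1) == lower_pct
        assert round(hi * 100, 1) == upper_pct

    @given(n=st.integers(1, 200), frac=st.floats(0, 1),
           conf=st.sampled_from([0.90, 0.95, 0.99]))
    def test_matches_statsmodels_beta_interval(self, n, frac, conf):
        x = round(n * frac)
        lo, hi = clopper_pearson(x, n, conf)
        ref_lo, ref_hi = proportion_confint(x, n, alpha=1 - conf,
                                            method="beta")
        assert lo == pytest.approx(0.0 if x == 0 else ref_lo, abs=1e-12)
        assert hi == pytest.approx(1.0 if x == n else ref_hi, abs=1e-12)

    @given(n=st.integers(1, 150), frac=st.floats(0, 1))
    def test_interval_symmetry(self, n, frac):
        x = round(n * frac)
        lo, _ = clopper_pearson(x, n)
        _, hi = clopper_pearson(n - x, n)
        assert lo == pytest.approx(1.0 - hi, abs=1e-12)

    def test_zero_trials_undefined(self):
        with pytest.raises(UndefinedMarginError):
            clopper_pearson(0, 0)

    def test_successes_bounded_by_trials(self):
        with pytest.raises(ValueError):
            clopper_pearson(8, 7)


class TestSensSpec:
    def test_validation_cohort_shaped_table(self):
        # 100 patients at the 0.7 cut: 71 blocked all detected, 29 recovered
        # of whom 10 cleared
        acc = sens_spec(ContingencyTable(tp=71, fp=19, fn=0, tn=10),
                        epsilon=0.7)
        assert acc.sens == 1.0
        assert acc.sens_ci == pytest.approx(clopper_pearson(71, 71))
        assert round(acc.sens_ci[0] * 100, 1) == 94.9
        assert acc.spec == pytest.approx(10 / 29)
        assert acc.spec_ci == pytest.approx(clopper_pearson(10, 29))

    def test_point_estimates_inside_their_intervals(self):
        acc = sens_spec(ContingencyTable(tp=30, fp=4, fn=6, tn=20))
        assert acc.sens_ci[0] <= acc.sens <= acc.sens_ci[1]
        assert acc.spec_ci[0] <= acc.spec <= acc.spec_ci[1]

    def test_empty_diseased_margin_is_an_error(self):
        with pytest.raises(UndefinedMarginError):
            sens_spec(ContingencyTable(tp=0, fp=5, fn=0, tn=5))

    def test_perfect_classifier(self):
        acc = sens_spec(ContingencyTable(tp=40, fp=0, fn=0, tn=60))
        assert acc.sens == 1.0 and acc.spec == 1.0

    def test_evaluate_tool_builds_the_table_from_labels(self):
        emg = [0.2, 0.5, 0.8, 1.0]
        pred = [True, False, False, True]  # one miss, one false alarm
        acc = evaluate_tool(pred, emg, epsilon=0.7)
        assert acc.table == ContingencyTable(tp=1, fp=1, fn=1, tn=1)

    def test_label_convention_swap_transposes_the_table(self):
        emg = [0.2, 0.5, 0.8, 1.0, 0.6]
        pred = [True, False, False, True, True]
        acc = evaluate_tool(pred, emg, epsilon=0.7)
        flipped = evaluate_tool([not p for p in pred],
                                [1.3 - v for v in emg], epsilon=0.61)
        # relabelling healthy<->diseased and pass<->flag swaps sens and spec
        assert flipped.table.tp == acc.table.tn
        assert flipped.table.fn == acc.table.fp


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        r = roc([0.2, 0.3, 0.8, 0.9], [True, True, False, False])
        assert r.auc == 1.0

    def test_curve_spans_origin_to_corner(self):
        r = roc([0.2, 0.9, 0.5, 0.4], [True, False, False, True])
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_uninformative_predictor_near_half(self, rng):
        n = 2000
        labels = rng.random(n) < 0.5
        preds = rng.random(n)
        r = roc(preds, labels)
        m, n_neg = int(labels.sum()), int((~labels).sum())
        se = np.sqrt((m + n_neg + 1) / (12 * m * n_neg))
        assert abs(r.auc - 0.5) < 3 * se

    def test_trapezoid_equals_pairwise_concordance_on_random_instances(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 30))
            preds = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = roc(preds, labels)
            assert r.auc == pytest.approx(pairwise_auc(preds, labels))
            assert r.auc == pytest.approx(auc_concordance(preds, labels))

    def test_agrees_with_sklearn_oracle(self, rng):
        preds = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        ours = roc(preds, labels, block_low=True).auc
        ref = roc_auc_score(labels, -preds)
        assert ours == pytest.approx(ref)

    def test_invariant_under_monotone_transform(self, rng):
        preds = rng.random(60)
        labels = rng.random(60) < 0.5
        a = roc(preds, labels).auc
        b = roc(np.exp(3 * preds), labels).auc
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([0.1, 0.2], [True, True])


class TestCompareAuc:
    def test_identical_predictors_give_zero_diff_p_one(self, rng):
        preds = rng.random(40)
        labels = rng.random(40) < 0.5
        res = compare_auc(preds, preds, labels)
        assert res.diff == 0.0 and res.p_value == 1.0

    def test_opposite_predictors_on_separable_data_give_small_p(self):
        labels = np.array([True] * 20 + [False] * 20)
        good = np.r_[np.linspace(0.1, 0.4, 20), np.linspace(0.6, 0.9, 20)]
        res = compare_auc(good, -good, labels)
        assert res.auc_a == 1.0 and res.auc_b == 0.0
        assert res.p_value < 1e-6

    def test_delong_aucs_match_roc_aucs(self, rng):
        a = rng.normal(size=80)
        b = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        res = compare_auc(a, b, labels)
        assert res.auc_a == pytest.approx(roc(a, labels).auc)
        assert res.auc_b == pytest.approx(roc(b, labels).auc)

    def test_delong_p_close_to_paired_bootstrap_oracle(self):
        # 40-patient synthetic set with a modest real AUC difference; the
        # asymptotic and resampling p-values agree up to Monte-Carlo and
        # small-sample error
        rng = np.random.default_rng(14)
        tofr = rng.uniform(0.2, 1.0, 40)
        labels = tofr < 0.7
        tool_a = tofr + rng.normal(0, 0.08, 40)
        tool_b = tofr + rng.normal(0, 0.25, 40)
        res_d = compare_auc(tool_a, tool_b, labels)
        res_b = compare_auc_bootstrap(tool_a, tool_b, labels, n_boot=10_000,
                                      seed=99)
        assert res_d.diff == pytest.approx(res_b.diff)
        assert abs(res_d.p_value - res_b.p_value) < 0.1

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            compare_auc([0.1, 0.2], [0.1, 0.2, 0.3],
                        [True, False, True])


class TestCorrelation:
    def test_identical_vectors_correlate_perfectly(self):
        x = [0.1, 0.4, 0.6, 0.9]
        assert model_correlation(x, x) == pytest.approx(1.0)
        assert model_correlation(x, x, method="pearson") == pytest.approx(1.0)

    def test_negated_vector_anticorrelates(self):
        x = np.array([0.1, 0.4, 0.6, 0.9])
        assert model_correlation(-x, x) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError):
            model_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])

    def test_amg_tracks_emg_strongly_across_replicates(self):
        # the uncalibrated-AMG channel keeps a strong monotone association
        # with the EMG standard in nearly every simulated 165-patient cohort
        hits = 0
        for seed in range(100):
            cohort = simulate_cohort(
                SimulationConfig(n_patients=165, seed=5000 + seed)
            )
            r = model_correlation([c.amg_tofr for c in cohort],
                                  [c.emg_tofr for c in cohort])
            hits += r > 0.7
        assert hits >= 95
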