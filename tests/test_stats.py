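"""Group statistics: ANOVA oracles, Tukey identities, corrected correlations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import verbgen as vg


def anova_f_oracle(groups):
    """From-definition sums of squares: F = MS_between / MS_within."""
    arrays = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(arrays).mean()
    ss_b = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = sum(len(a) for a in arrays) - len(arrays)
    return (ss_b / df_b) / (ss_w / df_w)


class TestOnewayAnova:
    def test_hand_computed_example(self):
        res = vg.oneway_anova([[1, 2, 3], [4, 5, 6]])
        eff = res.effects[0]
        assert eff.f == pytest.approx(13.5)
        assert (eff.df_num, eff.df_den) == (1, 4)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            groups = [rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(3, 12))
                      for _ in range(rng.integers(2, 5))]
            res = vg.oneway_anova(groups)
            assert res.effects[0].f == pytest.approx(anova_f_oracle(groups), abs=1e-9)

    def test_identical_constants_reported_undefined(self):
        res = vg.oneway_anova([[5, 5, 5], [5, 5, 5]])
        assert np.isnan(res.effects[0].f) and res.note is not None

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(300):
            groups = [rng.normal(0, 1, 8) for _ in range(3)]
            ps.append(vg.oneway_anova(groups).effects[0].p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestTukey:
    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        pair = vg.tukey_hsd({"a": a, "b": b}).pairs[0]
        t_p = sps.ttest_ind(a, b).pvalue
        assert pair.p_adj == pytest.approx(t_p, abs=1e-6)

    def test_adjusted_p_at_least_unadjusted_t(self):
        rng = np.random.default_rng(4)
        groups = {n: rng.normal(i * 0.3, 1, 9) for i, n in enumerate("abc")}
        res = vg.tukey_hsd(groups)
        for pair in res.pairs:
            t_p = sps.ttest_ind(groups[pair.group_a], groups[pair.group_b]).pvalue
            assert pair.p_adj >= t_p - 1e-9

    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(5)
        groups = {n: rng.normal(i * 5.0, 1, 10) for i, n in enumerate("abc")}
        assert all(p.p_adj < 0.05 for p in vg.tukey_hsd(groups).pairs)

    def test_identical_groups_near_one(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 10)
        groups = {"a": base, "b": base + 1e-6 * rng.normal(size=10),
                  "c": base + 1e-6 * rng.normal(size=10)}
        assert all(p.p_adj > 0.85 for p in vg.tukey_hsd(groups).pairs)

    def test_all_unordered_pairs_present_once(self):
        rng = np.random.default_rng(8)
        res = vg.tukey_hsd({n: rng.normal(size=5) for n in "abcd"})
        pairs = {frozenset((p.group_a, p.group_b)) for p in res.pairs}
        assert len(pairs) == len(res.pairs) == 6


def _profile(sid, group, mix):
    correct = 100 - sum(mix)
    return vg.SubjectProfile(subject_id=sid, group=group, n_trials=100,
                             pct_correct=correct, pct_not_verb=mix[0],
                             pct_unrelated_verb=mix[1], pct_missing=mix[2],
                             pct_error_consistency=None,
                             pct_error_type_consistency=None, mean_rt_s=None)


class TestErrortypeAnova:
    def test_identical_mixes_give_null_interaction(self):
        rng = np.random.default_rng(9)
        profiles = []
        for g in vg.PATIENT_GROUPS:
            for i in range(12):
                mix = np.clip(rng.normal([20, 10, 10], 4), 1, None)
                profiles.append(_profile(f"{g}{i}", g, mix))
        res = vg.group_by_errortype_anova(profiles)
        assert res.effect("interaction").p > 0.05

    def test_variant_specific_mixes_give_interaction(self, tiny_profiles):
        patients = [p for p in tiny_profiles if p.group != "HC"]
        res = vg.group_by_errortype_anova(patients)
        assert res.design == "group_by_errortype"
        assert res.effect("interaction").p < 0.05
        assert res.effect("group").f >= 0

    def test_single_group_reduces_to_within_design(self, tiny_profiles):
        sv = [p for p in tiny_profiles if p.group == "svPPA"]
        res = vg.group_by_errortype_anova(sv)
        assert res.design == "one_way_within"
        assert res.effect("error_type").f >= 0


class TestCorrelations:
    def test_perfect_linear_predictor(self):
        acc = pd.Series({f"n{i}": 10.0 * i for i in range(8)})
        pred = pd.DataFrame({"freq_log": acc * 0.5 + 3})
        row = vg.by_item_correlations(acc, pred, family_size=6).row("freq_log")
        assert row.r == pytest.approx(1.0)
        assert row.survives

    def test_independent_predictor_does_not_survive(self):
        rng = np.random.default_rng(10)
        acc = pd.Series(rng.uniform(0, 100, 40), index=[f"n{i}" for i in range(40)])
        pred = pd.DataFrame({"noise": rng.normal(size=40)}, index=acc.index)
        row = vg.by_item_correlations(acc, pred, family_size=6).row("noise")
        assert abs(row.r) < 0.4 and not row.survives

    def test_bonferroni_adjustment_and_survival_rule(self):
        rng = np.random.default_rng(11)
        acc = pd.Series(rng.uniform(size=30), index=range(30))
        pred = pd.DataFrame({f"p{i}": rng.normal(size=30) + (acc if i == 0 else 0)
                             for i in range(6)}, index=acc.index)
        table = vg.by_item_correlations(acc, pred)
        for row in table.rows:
            assert row.p_adj == pytest.approx(min(1.0, 6 * row.p_raw))
            assert row.survives == (row.p_raw <= 0.05 / 6)

    def test_zero_variance_predictor_flagged(self):
        acc = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = pd.DataFrame({"const": [7.0] * 5})
        row = vg.by_item_correlations(acc, pred).row("const")
        assert np.isnan(row.r) and row.note == "zero variance" and not row.survives

    def test_frequency_effect_recovered_in_svppa(self):
        # the generator ties svPPA item accuracy to log frequency with an
        # effect sized for r ~ 0.5; at full study scale (50 nouns, 28
        # subjects) the by-item analysis recovers it
        cfg = vg.GeneratorConfig(seed=14)
        sim = vg.generate_stimuli(cfg)
        trials = vg.generate_patient_cohort(vg.default_cohort_specs()["svPPA"],
                                            sim, cfg)
        acc = vg.per_item_accuracy(trials)
        norms = sim.norms()
        pred = pd.DataFrame({"freq_log": {n: norms[n].freq_log for n in acc.index}})
        row = vg.by_item_correlations(acc, pred, family_size=6).row("freq_log")
        assert 0.2 < row.r < 0.8

    def test_by_subject_accuracy_identity_and_trails_anticorrelation(self, tiny_dataset):
        patients = [t for t in tiny_dataset.trials if t.group != "HC"]
        acc = vg.per_subject_accuracy(patients)
        pred = vg.neuropsych_predictors(
            [s for s in tiny_dataset.subjects if s.group != "HC"])
        table = vg.by_subject_correlations(acc, pred)
        assert table.row("trails_total_time").r < 0  # planted anti-correlation
        ident = vg.by_subject_correlations(acc, pd.DataFrame({"self": acc}))
        assert ident.row("self").r == pytest.approx(1.0)

    def test_missing_scores_reported_pairwise_complete(self):
        subjects = [
            vg.SubjectRecord("a", "svPPA", {"single_word_comprehension": 10,
                                            "phonemic_fluency": 8,
                                            "semantic_fluency": 4,
                                            "trails_total_time": 60}),
            vg.SubjectRecord("b", "svPPA", {"single_word_comprehension": 12,
                                            "trails_total_time": 50}),
            vg.SubjectRecord("c", "svPPA", {"single_word_comprehension": 8,
                                            "phonemic_fluency": 6,
                                            "semantic_fluency": 0,  # zero denominator
                                            "trails_total_time": 70}),
            vg.SubjectRecord("d", "svPPA", {"single_word_comprehension": 9,
                                            "phonemic_fluency": 5,
                                            "semantic_fluency": 5,
                                            "trails_total_time": 80}),
        ]
        acc = pd.Series({"a": 70.0, "b": 60.0, "c": 50.0, "d": 40.0})
        table = vg.by_subject_correlations(acc, vg.neuropsych_predictors(subjects))
        assert table.row("single_word_comprehension").n == 4
        assert table.row("fluency_ratio").n == 2  # b missing, c zero-denominator
        assert table.row("fluency_ratio").note is not None  # too few pairs
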