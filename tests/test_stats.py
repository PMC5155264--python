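import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cilms.stats import (GroupComparison, anova_tukey, autoscale, bh_qvalues,
                         classify_temporal_pattern, fold_change_test,
                         grade_vs_control, permutation_validate, plsda_fit,
                         venn_select)


class TestAutoscale:
    def test_column_centred_and_unit_variance(self):
        out = autoscale(np.array([[1.0], [2.0], [3.0]]))
        assert out.mean() == pytest.approx(0.0)
        assert out.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent_on_scaled_input(self, rng):
        X = autoscale(rng.normal(size=(20, 5)))
        assert np.allclose(autoscale(X), X, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            autoscale(np.column_stack([np.arange(5.0), np.full(5, 2.0)]))


class TestFoldChange:
    def test_identical_groups_give_unit_fc_p_one(self):
        g = [1.0, 2.0, 3.0]
        fc, p = fold_change_test(g, g)
        assert fc == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_doubled_group_gives_fc_two(self, rng):
        g2 = rng.lognormal(0, 0.3, 10)
        fc, _ = fold_change_test(2 * g2, g2)
        assert fc == pytest.approx(2.0)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            fold_change_test([1.0, -1.0, 2.0], [1.0, 1.0, 2.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_p_matches_permutation_oracle(self, seed):
        """Welch p-value on log2 ratios agrees with a 10^4-resample
        permutation test of the same statistic within Monte-Carlo and
        finite-sample error."""
        rng = np.random.default_rng(seed)
        g1 = rng.lognormal(0.4, 0.3, 12)
        g2 = rng.lognormal(0.0, 0.3, 12)
        _, p = fold_change_test(g1, g2)

        def stat(a, b, axis):
            return sps.ttest_ind(a, b, equal_var=False, axis=axis).statistic

        perm = sps.permutation_test(
            (np.log2(g1), np.log2(g2)), stat, n_resamples=10_000,
            alternative="two-sided", rng=np.random.default_rng(99))
        assert p == pytest.approx(perm.pvalue, abs=0.05)


def bh_step_up_oracle(p):
    """Independent BH oracle: descending pass with a running minimum."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBH:

    def test_hand_computed_example(self):
        assert np.allclose(bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_qvalues([0.2]) == pytest.approx([0.2])

    @pytest.mark.parametrize("n", [5, 50, 1000])
    def test_matches_independent_oracle(self, n, rng):
        p = rng.uniform(size=n)
        assert np.allclose(bh_qvalues(p), bh_step_up_oracle(p), atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_q_at_least_p_and_bounded(self, ps):
        q = bh_qvalues(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.1, 1.5])


class TestAnovaTukey:
    def test_f_statistic_closed_form_on_3x3_table(self):
        """p reproduces the closed-form sum-of-squares F on a hand-sized
        table."""
        groups = {"A": [1.0, 2.0, 3.0], "B": [2.0, 3.0, 4.0],
                  "C": [4.0, 5.0, 6.0]}
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(3 * (np.mean(v) - grand) ** 2
                         for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                        for v in groups.values())
        f = (ss_between / 2) / (ss_within / 6)
        p_expected = sps.f.sf(f, 2, 6)
        p, _ = anova_tukey(groups)
        assert p == pytest.approx(p_expected, rel=1e-10)

    def test_two_groups_reduce_to_t_test(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        p_anova, _ = anova_tukey({"A": a, "B": b})
        p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert p_anova == pytest.approx(p_t, rel=1e-9)

    def test_pairwise_results_symmetric(self, rng):
        groups = {g: rng.normal(i, 1, 6) for i, g in enumerate("ABC")}
        _, pw = anova_tukey(groups)
        assert frozenset(("A", "B")) in pw
        assert len(pw) == 3

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="'B'"):
            anova_tukey({"A": [1, 2, 3], "B": [1.0]})


class TestPlsda:
    def test_vip_normalization_mean_square_one(self, rng):
        X = autoscale(rng.normal(size=(40, 12)))
        y = np.repeat([0, 1], 20)
        m = plsda_fit(X, y, 2)
        assert np.mean(m.vip ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_scores_orthogonal(self, rng):
        X = autoscale(rng.normal(size=(30, 8)))
        m = plsda_fit(X, np.repeat([0, 1], 15), 3)
        gram = m.scores.T @ m.scores
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0, atol=1e-8)

    def test_single_informative_feature_dominates_vip(self, rng):
        n, p = 60, 10
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, p))
        X[:, 3] += 3 * y
        m = plsda_fit(autoscale(X), y, 2)
        assert np.argmax(m.vip) == 3
        assert np.all(m.vip[np.arange(p) != 3] < 1.0)

    def test_one_feature_vip_is_one(self, rng):
        X = autoscale(rng.normal(size=(20, 1)))
        m = plsda_fit(X, np.repeat([0, 1], 10), 1)
        assert m.vip == pytest.approx([1.0])

    def test_separable_classes_give_high_q2(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6))
        X[:, 0] += 4 * y
        X[:, 1] -= 4 * y
        m = plsda_fit(autoscale(X), y, 2)
        assert m.q2 > 0.5

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            plsda_fit(rng.normal(size=(10, 3)), np.zeros(10), 1)

    def test_excess_components_rejected(self, rng):
        X = autoscale(rng.normal(size=(6, 3)))
        with pytest.raises(ValueError, match="rank"):
            plsda_fit(X, np.repeat([0, 1], 3), 5)


class TestPermutationValidation:
    @pytest.mark.parametrize("seed", range(5))
    def test_informative_labels_validate(self, seed):
        rng = np.random.default_rng(seed)
        n = 36
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 8))
        X[:, 0] += 2.5 * y
        X[:, 1] += 2.0 * y
        valid, _, q2s = permutation_validate(autoscale(X), y, 2, n_perm=20,
                                             seed=seed)
        assert valid
        assert len(q2s) == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_noise_labels_rarely_validate(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = autoscale(rng.normal(size=(30, 8)))
        y = np.repeat([0, 1], 15)
        valid, _, _ = permutation_validate(X, y, 2, n_perm=20, seed=seed)
        assert not valid

    def test_single_permutation_runs(self, rng):
        X = autoscale(rng.normal(size=(20, 4)))
        y = np.repeat([0, 1], 10)
        _, r2s, q2s = permutation_validate(X, y, 1, n_perm=1)
        assert len(r2s) == len(q2s) == 1


class TestTemporalPattern:
    @pytest.mark.parametrize("t_means,expected", [
        ((0.2, 0.5, 1.0), "pattern1"),
        ((-0.2, -0.5, -1.0), "pattern1"),
        ((1.0, 0.5, 0.1), "pattern2"),
        ((0.0, 0.0, 0.0), "other"),
        ((1.0, -0.8, 0.9), "other"),  # sign flips: not a monotone drift
    ])
    def test_rule_on_canonical_trajectories(self, t_means, expected):
        call = classify_temporal_pattern("m", 0.0, t_means)
        assert call.pattern == expected

    def test_patterns_mutually_exclusive_on_grid(self):
        for d1 in np.linspace(-1.5, 1.5, 7):
            for d2 in np.linspace(-1.5, 1.5, 7):
                for d3 in np.linspace(-1.5, 1.5, 7):
                    call = classify_temporal_pattern("m", 0.0, (d1, d2, d3))
                    assert call.pattern in ("pattern1", "pattern2", "other")

    def test_pattern_recovery_on_cohort(self, csf_cohort, csf_table_raw):
        """Injected pattern-1/pattern-2 metabolites are re-called from
        estimated group means in >= 90% of cases."""
        truth = {m["name"]: m["pattern"]
                 for m in csf_cohort.truth_record["metabolites"]}
        log_vals = np.log2(csf_table_raw.values)
        ids_n = [s.sample_id for s in csf_table_raw.samples
                 if s.grade == "N" and not s.is_qc]
        ids_t = {tw: [s.sample_id for s in csf_table_raw.samples
                      if s.time_window == tw] for tw in ("t1", "t2", "t3")}
        correct = total = 0
        for i in range(csf_table_raw.n_features):
            name = csf_table_raw.features["identity"].iloc[i]
            if name is None or name not in truth:
                continue
            injected = truth[name]
            if injected == "flat":
                continue
            want = "pattern1" if injected.startswith("pattern1") else "pattern2"
            ctrl = float(np.nanmean(log_vals[ids_n].iloc[i]))
            means = tuple(float(np.nanmean(log_vals[ids_t[tw]].iloc[i]))
                          for tw in ("t1", "t2", "t3"))
            call = classify_temporal_pattern(name, ctrl, means)
            total += 1
            correct += call.pattern == want
        assert total >= 20
        assert correct / total >= 0.9


class TestVennSelect:
    def cmp(self, name, fc, p):
        return GroupComparison(name, fc, p)

    def test_significant_everywhere_lands_in_centre(self):
        comps = {g: [self.cmp("m", 2.0, 0.01)] for g in "ABC"}
        regions = venn_select(comps)
        assert regions[frozenset("ABC")] == {"m"}

    def test_fc_below_threshold_excluded(self):
        comps = {g: [self.cmp("m", 1.4, 0.001)] for g in "ABC"}
        regions = venn_select(comps)
        assert all(not v for v in regions.values())

    def test_reciprocal_fold_change_counts(self):
        comps = {"A": [self.cmp("m", 0.5, 0.01)],
                 "B": [self.cmp("m", 1.0, 0.01)],
                 "C": [self.cmp("m", 1.0, 0.01)]}
        regions = venn_select(comps)
        assert regions[frozenset("A")] == {"m"}

    def test_regions_partition_the_union(self, rng):
        comps = {g: [self.cmp(f"m{i}", float(rng.lognormal(0, 0.8)),
                              float(rng.uniform(0, 0.2)))
                     for i in range(30)] for g in "ABC"}
        regions = venn_select(comps)
        union = set().union(*regions.values())
        assert sum(len(v) for v in regions.values()) == len(union)

    def test_marker_selection_on_cohort(self, csf_cohort, csf_table_raw):
        """Metabolites injected with |log2 FC| >= 1 at t1 are selected
        with sensitivity >= 0.9; metabolites with no injected effect are
        selected at rate <= 0.1."""
        comps = {g: grade_vs_control(csf_table_raw, g, "t1") for g in "ABC"}
        regions = venn_select(comps)
        selected = set().union(*regions.values())
        truth = csf_cohort.truth_record["metabolites"]
        strong = {m["name"] for m in truth
                  if any(abs(m["log2_fc"][f"{g}:t1"]) >= 1 for g in "ABC")}
        null = {m["name"] for m in truth
                if all(m["log2_fc"][f"{g}:t1"] == 0 for g in "ABC")}
        identified = set(csf_table_raw.features["identity"].dropna())
        strong &= identified
        null &= identified
        assert strong and null
        assert len(selected & strong) / len(strong) >= 0.9
        assert len(selected & null) / len(null) <= 0.1
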