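import itertools

import numpy as np
import pytest
import scipy.stats

from microstab import inference


@pytest.fixture()
def heteroscedastic_layout():
    rng = np.random.default_rng(11)
    groups = np.repeat(["A", "B", "C", "D", "E"], 8)
    values = rng.standard_normal(40) * np.repeat([1.0, 1.0, 2.0, 2.0, 4.0], 8)
    values += np.repeat([0.0, 0.5, 1.0, 1.5, 2.0], 8)
    return values, groups


class TestHcAnova:
    def test_layout_degrees_of_freedom(self, heteroscedastic_layout):
        values, groups = heteroscedastic_layout
        res = inference.hc_anova(values, groups)
        assert (res.df_num, res.df_den) == (4, 35)

    def test_identical_values_are_degenerate(self):
        res = inference.hc_anova(np.ones(40), np.repeat(list("ABCDE"), 8))
        assert res.F == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_two_groups_equal_welch_type_t_squared(self):
        # robust F == squared heteroscedastic t from the same HC covariance
        x = np.array([3.1, 4.5, 2.2, 5.0, 3.3, 4.1])
        y = np.array([7.9, 6.2, 9.4, 8.8, 7.1])
        values = np.concatenate([x, y])
        groups = np.array(["a"] * 6 + ["b"] * 5)
        for hc, power in [("HC0", 0), ("HC3", 2)]:
            res = inference.hc_anova(values, groups, hc_type=hc)
            v = []
            for arr in (x, y):
                e2 = (arr - arr.mean()) ** 2
                v.append((e2 / (1 - 1 / len(arr)) ** power).sum() / len(arr) ** 2)
            t = (y.mean() - x.mean()) / np.sqrt(v[0] + v[1])
            assert res.F == pytest.approx(t**2, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            inference.hc_anova([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_hc0_converges_to_classical_f_under_homoscedasticity(self):
        # groups standardised to identical sample variance: the HC0 and
        # pooled-variance F then differ only by the n/(n-1) small-sample
        # factor, which is below 2% at n=200 per group
        rng = np.random.default_rng(3)
        n = 200
        parts = []
        for shift in (0, 0.1, 0.2, 0.3, 0.4):
            x = rng.standard_normal(n)
            parts.append((x - x.mean()) / x.std(ddof=1) + shift)
        values = np.concatenate(parts)
        groups = np.repeat(list("ABCDE"), n)
        res = inference.hc_anova(values, groups, hc_type="HC0")
        assert res.F == pytest.approx(res.f_classical, rel=0.02)

    def test_classical_f_reported_alongside(self, heteroscedastic_layout):
        values, groups = heteroscedastic_layout
        res = inference.hc_anova(values, groups)
        f_cls, p_cls = scipy.stats.f_oneway(*[values[groups == g] for g in "ABCDE"])
        assert res.f_classical == pytest.approx(f_cls)
        assert res.p_classical == pytest.approx(p_cls)


class TestTukeyHsd:
    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(8)
        values = np.tile(base, 5)
        groups = np.repeat(list("ABCDE"), 8)
        res = inference.tukey_hsd(values, groups)
        assert len(set(res.letters.values())) == 1

    def test_far_outlying_group_gets_unique_letter(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal(40)
        groups = np.repeat(list("ABCDE"), 8)
        values[groups == "E"] += 10.0  # 10 pooled SDs away
        res = inference.tukey_hsd(values, groups)
        e_letters = set(res.letters["E"])
        others = set("".join(res.letters[g] for g in "ABCD"))
        assert not (e_letters & others)
        # direct studentized-range check of the E-vs-A comparison
        mse = np.mean([values[groups == g].var(ddof=1) for g in "ABCDE"])
        q = abs(values[groups == "E"].mean() - values[groups == "A"].mean()) / np.sqrt(mse / 8)
        assert scipy.stats.studentized_range.sf(q, 5, 35) < 0.05

    def test_letters_invariant_to_label_permutation(self, heteroscedastic_layout):
        values, groups = heteroscedastic_layout
        res1 = inference.tukey_hsd(values, groups)
        mapping = {"A": "E", "B": "D", "C": "C", "D": "B", "E": "A"}
        res2 = inference.tukey_hsd(values, np.vectorize(mapping.get)(groups))
        for g in "ABCDE":
            assert res1.letters[g] == res2.letters[mapping[g]]

    def test_adjusted_p_not_below_unadjusted(self, heteroscedastic_layout):
        values, groups = heteroscedastic_layout
        res = inference.tukey_hsd(values, groups)
        labels = sorted(set(groups))
        mse = np.mean([values[groups == g].var(ddof=1) for g in labels])
        for row in res.table.itertuples():
            xa = values[groups == row.group1]
            xb = values[groups == row.group2]
            t = abs(xa.mean() - xb.mean()) / np.sqrt(mse * (1 / len(xa) + 1 / len(xb)))
            p_unadj = 2 * scipy.stats.t.sf(t, len(values) - len(labels))
            assert row.p_adj >= p_unadj - 1e-10

    def test_letter_display_consistency(self, heteroscedastic_layout):
        # no pair sharing a letter has adjusted p < alpha, and every
        # non-significant pair shares at least one letter
        values, groups = heteroscedastic_layout
        res = inference.tukey_hsd(values, groups)
        for row in res.table.itertuples():
            shared = set(res.letters[row.group1]) & set(res.letters[row.group2])
            if shared:
                assert row.p_adj >= res.alpha
            else:
                assert row.p_adj < res.alpha


class TestCompactLetterDisplay:
    def test_chain_structure(self):
        # A<B<C with A-C significant only: expect letters a, ab, b
        letters = inference.compact_letter_display(
            ["A", "B", "C"], {"A": 0.0, "B": 1.0, "C": 2.0}, {("A", "C")}
        )
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_all_significant_gives_distinct_letters(self):
        pairs = set(itertools.combinations("ABC", 2))
        letters = inference.compact_letter_display(
            ["A", "B", "C"], {"A": 0.0, "B": 1.0, "C": 2.0}, pairs
        )
        assert sorted(letters.values()) == ["a", "b", "c"]


class TestRobustPairwise:
    def test_separated_group_rejected(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal(40)
        groups = np.repeat(list("ABCDE"), 8)
        values[groups == "E"] += 12.0
        res = inference.robust_pairwise(values, groups)
        e_rows = res.table[(res.table.group1 == "E") | (res.table.group2 == "E")]
        assert e_rows.reject.all()
        assert res.method == "hc3-holm"


class TestPearsonCorrelation:
    def test_perfect_linear_relationships(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = inference.pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = inference.pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 3, sx^2 = sy^2 = 5 -> r = 3/5
        r, p = inference.pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert 0 < p < 1

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            inference.pearson_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError, match="zero variance"):
            inference.pearson_correlation([1, 1, 1], [1, 2, 3])
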