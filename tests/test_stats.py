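"""Closed-form ANOVA, LSD letters, descriptives and Pearson correlation,
cross-checked against independent oracles (scipy equivalents and a
brute-force pairwise-decision closure)."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from ofswheat.stats import (
    StatsError,
    describe,
    fisher_lsd_letters,
    letters_from_decisions,
    lsd_significant_pairs,
    one_way_anova,
    pearson,
)


class TestDescribe:
    def test_hand_example(self):
        d = describe([1, 2, 3])
        assert d.mean == 2 and d.sd == pytest.approx(1.0)
        assert d.cv_percent == pytest.approx(50.0)
        assert d.median == 2 and d.min == 1 and d.max == 3

    def test_constant_vector(self):
        d = describe([4.2, 4.2, 4.2])
        assert d.sd == 0 and d.cv_percent == 0

    def test_requires_two_values(self):
        with pytest.raises(StatsError):
            describe([1.0])

    @given(
        st.lists(st.floats(1, 100), min_size=2, max_size=20),
        st.floats(-5, 5),
        st.floats(0.1, 10),
    )
    def test_location_scale_equivariance(self, xs, shift, scale):
        base = describe(xs)
        shifted = describe([x + shift for x in xs])
        scaled = describe([x * scale for x in xs])
        assert shifted.mean == pytest.approx(base.mean + shift, abs=1e-9)
        assert shifted.median == pytest.approx(base.median + shift, abs=1e-9)
        assert scaled.mean == pytest.approx(base.mean * scale, rel=1e-9)
        assert scaled.sd == pytest.approx(base.sd * scale, rel=1e-9, abs=1e-12)
        if base.sd > 1e-9:  # cv invariant under positive scaling
            assert scaled.cv_percent == pytest.approx(base.cv_percent, rel=1e-6)


class TestAnova:
    def test_hand_computed_sums_of_squares(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res.f_statistic == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == 0 and res.p_value == 1

    def test_zero_within_variance_unequal_means(self):
        res = one_way_anova({"a": [1, 1], "b": [2, 2]})
        assert math.isinf(res.f_statistic) and res.p_value == 0

    def test_small_groups_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova({"a": [1.0], "b": [1, 2]})
        with pytest.raises(StatsError):
            one_way_anova({"a": [1, 2]})

    def test_ss_decomposition_and_scipy_agreement(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 6)
            groups = {
                f"g{i}": rng.normal(rng.uniform(-2, 2), 1, rng.integers(2, 9)).tolist()
                for i in range(k)
            }
            res = one_way_anova(groups)
            allx = np.concatenate([np.asarray(v) for v in groups.values()])
            ss_total = ((allx - allx.mean()) ** 2).sum()
            assert res.ss_between + res.ss_within == pytest.approx(ss_total, rel=1e-10)
            f_ref, p_ref = sps.f_oneway(*groups.values())
            assert res.f_statistic == pytest.approx(f_ref, rel=1e-10)
            assert res.p_value == pytest.approx(p_ref, rel=1e-8)


def _shares_letter(letters, a, b):
    return bool(set(letters[a]) & set(letters[b]))


class TestLsdLetters:
    def test_identical_groups_share_a(self):
        out = fisher_lsd_letters({"x": [1, 2, 3], "y": [1, 2, 3], "z": [1, 2, 3]})
        assert all(s.letters == "a" for s in out)

    def test_well_separated_groups_get_abc_by_descending_mean(self):
        groups = {"lo": [1.0, 1.1, 0.9], "hi": [100.0, 100.1, 99.9], "mid": [50.0, 50.1, 49.9]}
        out = {s.treatment: s.letters for s in fisher_lsd_letters(groups)}
        assert out == {"hi": "a", "mid": "b", "lo": "c"}

    def test_letters_equal_bruteforce_decision_closure(self):
        """Two groups share a letter iff the direct LSD test does not
        declare them different (oracle equivalence on random instances)."""
        rng = np.random.default_rng(1)
        for _ in range(60):
            k = int(rng.integers(2, 7))
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 3), 1.0, int(rng.integers(3, 8))).tolist()
                for i in range(k)
            }
            _, decisions = lsd_significant_pairs(groups, alpha=0.05)
            letters = {s.treatment: s.letters for s in fisher_lsd_letters(groups)}
            for i, gi in enumerate(groups):
                for gj in list(groups)[i + 1:]:
                    assert _shares_letter(letters, gi, gj) == (not decisions[(gi, gj)]), (
                        gi, gj, letters, decisions[(gi, gj)],
                    )

    def test_insert_and_absorb_on_fixed_decision_pattern(self):
        # chain structure: a-b n.s., b-c n.s., but a-c significant -> a, ab, b
        order = ["g1", "g2", "g3"]
        decisions = {("g1", "g3"): True, ("g3", "g1"): True,
                     ("g1", "g2"): False, ("g2", "g1"): False,
                     ("g2", "g3"): False, ("g3", "g2"): False}
        letters = letters_from_decisions(order, decisions)
        assert letters == {"g1": "a", "g2": "ab", "g3": "b"}

    def test_protected_variant_suppresses_letters_when_anova_ns(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(0, 1, 5).tolist() for i in range(4)}
        out = fisher_lsd_letters(groups, alpha=1e-6, protected=True)
        assert all(s.letters == "a" for s in out)


class TestPearson:
    def test_perfect_lines(self):
        x = [1.0, 2, 3, 4, 5]
        r, p = pearson(x, x)
        assert r == pytest.approx(1.0, rel=1e-12) and p == pytest.approx(0.0, abs=1e-12)
        r, p = pearson(x, [-2 * v + 5 for v in x])
        assert r == pytest.approx(-1.0, rel=1e-12) and p == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)
            r, p = pearson(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_length_preconditions(self):
        with pytest.raises(StatsError):
            pearson([1, 2], [1, 2])
        with pytest.raises(StatsError):
            pearson([1, 2, 3], [1, 2])
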