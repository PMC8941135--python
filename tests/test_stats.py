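import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from exoflux import (
    bh_fdr,
    class_summary,
    classify_exchange,
    depletion_percent_from_lfc,
    growth_synergy_panel,
    growth_synergy_test,
    kruskal_wallis,
    log2_fold_change,
    overall_depletion_fraction,
    differential_abundance,
)
from exoflux.model import Call, Direction


def brute_force_exact_kw(start, end):
    """Independent oracle: scipy H per enumerated assignment."""
    combined = np.concatenate([start, end])
    n1 = len(start)

    def h(g1, g2):
        try:
            return sps.kruskal(g1, g2).statistic
        except ValueError:
            return 0.0

    h_obs = h(start, end)
    idx = set(range(len(combined)))
    count = total = 0
    for chosen in itertools.combinations(range(len(combined)), n1):
        g1 = combined[list(chosen)]
        g2 = combined[list(idx - set(chosen))]
        total += 1
        if h(g1, g2) >= h_obs - 1e-12:
            count += 1
    return count / total


class TestLog2FoldChange:
    def test_identity(self):
        v = [10.0, 20.0, 30.0]
        assert log2_fold_change(v, v) == 0.0

    def test_adenine_printed_means(self):
        """Start mean 14.9e7, end 0.9e7 gives LFC -4.05."""
        assert log2_fold_change([14.9e7] * 4, [0.9e7] * 4) == pytest.approx(-4.05, abs=0.01)

    def test_pseudocount_guards_zeros(self):
        assert log2_fold_change([1000.0] * 4, [0.0] * 4, pseudocount=1.0) == pytest.approx(
            np.log2(1 / 1001), abs=1e-9
        )


class TestKruskalWallis:
    SEP4 = ([10, 11, 12, 13], [1, 2, 3, 4])

    def test_asymptotic_complete_separation_4v4(self):
        assert kruskal_wallis(*self.SEP4, mode="asymptotic") == pytest.approx(
            0.0209, abs=0.0005
        )

    def test_exact_complete_separation_4v4(self):
        assert kruskal_wallis(*self.SEP4, mode="exact") == pytest.approx(2 / 70)

    def test_all_tied_returns_one(self):
        assert kruskal_wallis([5.0] * 4, [5.0] * 4, mode="asymptotic") == 1.0
        assert kruskal_wallis([5.0] * 4, [5.0] * 4, mode="exact") == 1.0

    def test_exact_refuses_large_n(self):
        with pytest.raises(ValueError, match="exact"):
            kruskal_wallis(np.arange(8), np.arange(8) + 10, mode="exact")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_exact_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        start = rng.integers(0, 8, n1).astype(float)  # integer values force ties
        end = rng.integers(0, 8, n2).astype(float)
        if np.all(np.concatenate([start, end]) == start[0]):
            return
        assert kruskal_wallis(start, end, mode="exact") == pytest.approx(
            brute_force_exact_kw(start, end)
        )

    def test_larger_h_never_larger_exact_p(self):
        """Exact p is monotone non-increasing in the observed H for fixed n."""
        rng = np.random.default_rng(5)
        datasets = [
            (rng.uniform(0, 10, 4), rng.uniform(0, 10, 4)) for _ in range(20)
        ]
        from exoflux.stats import _h_statistic

        pairs = sorted(
            ((_h_statistic(s, e), kruskal_wallis(s, e, mode="exact")) for s, e in datasets),
        )
        for (h1, p1), (h2, p2) in zip(pairs, pairs[1:]):
            if h2 > h1 + 1e-12:
                assert p2 <= p1 + 1e-12


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p_and_bh_beats_bonferroni(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        bonf = np.minimum(np.asarray(ps) * len(ps), 1.0)
        # BH rejection set contains Bonferroni's at any alpha
        for alpha in (0.01, 0.05, 0.1):
            assert set(np.where(bonf <= alpha)[0]) <= set(np.where(q <= alpha)[0])


class TestClassifyAndPercent:
    @pytest.mark.parametrize(
        "lfc,q,expected",
        [(-2.7, 0.02, Call.depleted), (-2.7, 0.20, Call.unchanged), (1.3, 0.02, Call.exuded)],
    )
    def test_classification_rule(self, lfc, q, expected):
        assert classify_exchange(lfc, q, alpha=0.05) == expected

    def test_zero_lfc_is_zero_percent(self):
        assert depletion_percent_from_lfc(0.0) == 0.0

    def test_choline_o_sulfate_lfc_gives_98(self):
        assert round(depletion_percent_from_lfc(-5.62)) == 98

    def test_trehalose_lfc_gives_85(self):
        assert round(depletion_percent_from_lfc(-2.7)) == 85

    def test_positive_lfc_rejected(self):
        with pytest.raises(ValueError):
            depletion_percent_from_lfc(0.5)


def _results_frame(rows):
    return pd.DataFrame(
        rows, columns=["metabolite", "chem_class", "direction", "lfc", "p_value", "q_value", "call"]
    )


class TestSummaries:
    def test_three_of_four_amino_acids_is_75(self):
        rows = [
            (f"aa{i}", "amino_acid", "A_fed_to_B", -1.0, 0.02, 0.02,
             "depleted" if i < 3 else "unchanged")
            for i in range(4)
        ]
        summ = class_summary(_results_frame(rows), Direction.A_fed_to_B)
        row = summ.loc[summ["chem_class"] == "amino_acid"].iloc[0]
        assert row["percent_depleted"] == pytest.approx(75.0)

    def test_absent_class_omitted(self):
        rows = [("m1", "lipid", "A_fed_to_B", -1.0, 0.02, 0.02, "depleted")]
        summ = class_summary(_results_frame(rows))
        assert set(summ["chem_class"]) == {"lipid"}

    def test_all_unchanged_gives_zero_percent(self):
        rows = [(f"m{i}", "carbohydrate", "A_fed_to_B", 0.0, 1.0, 1.0, "unchanged")
                for i in range(3)]
        summ = class_summary(_results_frame(rows))
        assert summ["percent_depleted"].iloc[0] == 0.0

    def test_overall_depletion_53_of_100(self):
        rows = [(f"m{i}", "other", "A_fed_to_B", -1.0, 0.02, 0.02,
                 "depleted" if i < 53 else "unchanged") for i in range(100)]
        pct, n_dep, n_denom = overall_depletion_fraction(_results_frame(rows))
        assert (pct, n_dep, n_denom) == (pytest.approx(53.0), 53, 100)

    def test_zero_denominator_flagged(self):
        pct, _, n = overall_depletion_fraction(_results_frame([]), exuded_names=["x"])
        assert pct is None and n == 0


class TestGrowthSynergy:
    def test_identical_to_sums_is_null(self):
        a, b = np.array([5.0, 6, 7, 8]), np.array([5.0, 5, 5, 5])
        assert growth_synergy_test(a, b, a + b) == 1.0

    def test_complete_separation_6v6(self):
        ab = np.array([30.0, 31, 32, 33, 34, 35])
        a = np.array([5.0, 5.5, 6, 6.5, 7, 7.5])
        b = np.array([5.0, 5.5, 6, 6.5, 7, 7.5])
        assert growth_synergy_test(a, b, ab) == pytest.approx(0.0039, abs=0.0003)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            growth_synergy_test([1, 2, 3], [1, 2], [5, 6, 7])

    def test_panel_bh_across_conditions(self):
        """BH over (0.004, 0.5, 0.9) gives (0.012, 0.75, 0.9)."""
        np.testing.assert_allclose(bh_fdr([0.004, 0.5, 0.9]), [0.012, 0.75, 0.9])


class TestTestDirection:
    def test_families_are_per_direction(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame(
            {
                "metabolite": [f"m{i}" for i in range(6)],
                "chem_class": ["other"] * 6,
                "start": [rng.uniform(1e5, 2e5, 4) for _ in range(6)],
                "end": [rng.uniform(1e5, 2e5, 4) for _ in range(6)],
            }
        )
        res = differential_abundance(pairs, Direction.A_fed_to_B)
        assert len(res) == 6
        assert np.all(res["q_value"] >= res["p_value"] - 1e-12)

    def test_depleted_metabolite_called(self):
        pairs = pd.DataFrame(
            {
                "metabolite": [f"m{i}" for i in range(3)],
                "chem_class": ["carbohydrate"] * 3,
                "start": [np.array([1e6, 1.1e6, 0.9e6, 1.05e6])] * 3,
                "end": [np.array([1e5, 1.2e5, 0.8e5, 1.1e5])] * 3,
            }
        )
        res = differential_abundance(pairs, Direction.A_fed_to_B)
        assert (res["call"] == "depleted").all()
        assert res["lfc"].iloc[0] == pytest.approx(np.log2(0.1025 / 1.0125), abs=0.01)
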