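import numpy as np
import pytest
from hypothesis import given, strategies as st

from seedperf.inference import LSMeans, PairwiseContrast
from seedperf.tradeoffs import (
    Call,
    GrowthSurvival,
    PairOutcome,
    TradeoffError,
    classify_pair,
    growth_survival_tradeoff,
    light_cross_tradeoff,
    mean_wins,
    microhabitat_tradeoff,
    wins_proportion,
)


def make_contrast(a, b, diff, p_adj):
    return PairwiseContrast(
        species_a=a, species_b=b, estimate=diff, se=0.1,
        z=diff / 0.1, p_raw=p_adj, p_adjusted=p_adj,
    )


def make_lsmeans(values):
    species = sorted(values)
    return LSMeans(
        species=species,
        estimate=np.array([values[s] for s in species]),
        se=np.full(len(species), 0.1),
    )


class TestClassifyPair:
    def test_nonsignificant_is_tie(self):
        lsm = make_lsmeans({"A": 0.5, "B": 0.2})
        out = classify_pair(lsm, make_contrast("A", "B", 0.3, 0.20))
        assert out.call == Call.TIE

    def test_significant_larger_mean_wins(self):
        lsm = make_lsmeans({"A": 0.5, "B": 0.2})
        out = classify_pair(lsm, make_contrast("A", "B", 0.3, 0.01))
        assert out.call == Call.WIN_A

    @given(
        st.floats(min_value=-1, max_value=1),
        st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_antisymmetry_under_pair_swap(self, diff, p):
        lsm = make_lsmeans({"A": 0.3 + diff, "B": 0.3})
        fwd = classify_pair(lsm, make_contrast("A", "B", diff, p))
        rev = classify_pair(lsm, make_contrast("B", "A", -diff, p))
        mirror = {Call.WIN_A: Call.WIN_B, Call.WIN_B: Call.WIN_A, Call.TIE: Call.TIE}
        assert rev.call == mirror[fwd.call]


class TestMicrohabitatTradeoff:
    def test_one_sided_wins_no_tradeoff(self):
        assert not microhabitat_tradeoff([Call.WIN_A, Call.TIE, Call.TIE])

    def test_opposite_wins_is_tradeoff(self):
        assert microhabitat_tradeoff([Call.WIN_A, Call.WIN_B])

    def test_all_ties_equivalence(self):
        assert not microhabitat_tradeoff([Call.TIE] * 5)

    def test_invariant_to_order_and_added_ties(self, rng):
        calls = [Call.WIN_A, Call.WIN_B, Call.TIE]
        base = microhabitat_tradeoff(calls)
        for _ in range(5):
            perm = list(rng.permutation(np.array(calls, dtype=object)))
            assert microhabitat_tradeoff(perm + [Call.TIE] * 3) == base

    def test_empty_rejected(self):
        with pytest.raises(TradeoffError):
            microhabitat_tradeoff([])


class TestGrowthSurvival:
    @pytest.mark.parametrize(
        "growth,surv,expected",
        [
            (Call.WIN_A, Call.WIN_B, GrowthSurvival.WIN_LOSE),
            (Call.WIN_B, Call.WIN_A, GrowthSurvival.WIN_LOSE),
            (Call.WIN_A, Call.TIE, GrowthSurvival.WIN_TIE),
            (Call.TIE, Call.WIN_B, GrowthSurvival.WIN_TIE),
            (Call.WIN_A, Call.WIN_A, GrowthSurvival.NONE),
            (Call.TIE, Call.TIE, GrowthSurvival.NONE),
        ],
    )
    def test_classification(self, growth, surv, expected):
        assert growth_survival_tradeoff(growth, surv) == expected


class TestLightCross:
    def test_opposite_winners(self):
        assert light_cross_tradeoff(Call.WIN_A, Call.WIN_B) is True

    def test_same_winner(self):
        assert light_cross_tradeoff(Call.WIN_A, Call.WIN_A) is False

    def test_tie_in_either_cell(self):
        assert light_cross_tradeoff(Call.TIE, Call.WIN_B) is False
        assert light_cross_tradeoff(Call.WIN_A, Call.TIE) is False

    def test_undefined_cell_propagates(self):
        assert light_cross_tradeoff(None, Call.WIN_B) is None


def out(cat, metric, a, b, call):
    return PairOutcome(("substrate", cat), metric, a, b, call)


class TestWins:
    def test_no_wins_zero(self):
        outcomes = [out(f"c{i}", "rgr_ht", "A", "B", Call.TIE) for i in range(15)]
        assert wins_proportion(outcomes, "A", "rgr_ht") == 0.0

    def test_dominant_species_wins_everywhere(self):
        outcomes = [out(f"c{i}", "rgr_ht", "A", "B", Call.WIN_A) for i in range(6)]
        assert wins_proportion(outcomes, "A", "rgr_ht") == 1.0
        assert wins_proportion(outcomes, "B", "rgr_ht") == 0.0

    def test_hand_built_five_category_fixture(self):
        calls = [Call.WIN_A, Call.WIN_A, Call.TIE, Call.WIN_B, Call.TIE]
        outcomes = [
            out(f"c{i}", "survival", "A", "B", c) for i, c in enumerate(calls)
        ]
        assert wins_proportion(outcomes, "A", "survival") == pytest.approx(0.4)

    def test_excluded_categories_drop_from_denominator(self):
        # A analyzed in 4 categories (absent from c4); wins 2 of those 4
        outcomes = [
            out("c0", "rgr_ht", "A", "B", Call.WIN_A),
            out("c1", "rgr_ht", "A", "B", Call.WIN_A),
            out("c2", "rgr_ht", "A", "B", Call.TIE),
            out("c3", "rgr_ht", "A", "B", Call.TIE),
            out("c4", "rgr_ht", "B", "C", Call.WIN_B),
        ]
        assert wins_proportion(outcomes, "A", "rgr_ht") == pytest.approx(0.5)

    def test_species_absent_everywhere_undefined(self):
        outcomes = [out("c0", "rgr_ht", "A", "B", Call.TIE)]
        with pytest.raises(TradeoffError):
            wins_proportion(outcomes, "Z", "rgr_ht")


class TestMeanWins:
    def test_focal_species_worked_example(self):
        """Per-metric win proportions 0.04/0.22/0.00/0.02 average to 0.07."""
        per_metric = {
            "rgr_ht": 0.04, "rgr_pm": 0.22, "rgr_la": 0.00, "survival": 0.02,
        }
        assert mean_wins(per_metric) == pytest.approx(0.07)

    def test_all_ones(self):
        assert mean_wins(dict.fromkeys(
            ("rgr_ht", "rgr_pm", "rgr_la", "survival"), 1.0)) == 1.0

    def test_hand_arithmetic(self):
        per = {"rgr_ht": 0.2, "rgr_pm": 0.4, "rgr_la": 0.6, "survival": 0.8}
        assert mean_wins(per) == pytest.approx(0.5)

    def test_missing_metric_rejected(self):
        with pytest.raises(TradeoffError):
            mean_wins({"rgr_ht": 0.5})
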