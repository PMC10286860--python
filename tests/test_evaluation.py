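import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from pediecg.evaluation import (
    ConfusionTable2x2,
    PairedOutcomes,
    confusion_2x2,
    mcnemar_test,
    paired_outcomes_from_predictions,
    sensitivity,
    specificity,
)


def exact_binomial_two_sided(b: int, c: int) -> float:
    """Independent oracle: direct binomial enumeration at p = 1/2."""
    n = b + c
    k = min(b, c)
    tail = sum(special.comb(n, i, exact=True) for i in range(k + 1)) / 2**n
    return min(1.0, 2.0 * tail)


class TestConfusion:
    def test_all_pathological_correct(self):
        t = confusion_2x2(["pathological"] * 5, ["pathological"] * 5)
        assert (t.tp, t.fn, t.fp, t.tn) == (5, 0, 0, 0)

    def test_inconclusive_scored_as_false_on_both_classes(self):
        t = confusion_2x2(
            ["pathological", "healthy"], ["inconclusive", "inconclusive"]
        )
        assert (t.tp, t.fn, t.fp, t.tn) == (0, 1, 1, 0)

    def test_wrong_pathology_category_is_predicted_negative(self):
        t = confusion_2x2(["rbbb"], ["tachycardia"])
        assert (t.tp, t.fn) == (0, 1)
        # binary gold: any pathological prediction counts as detection
        t = confusion_2x2(["pathological"], ["tachycardia"])
        assert t.tp == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_2x2(["healthy"], [])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        gold=st.lists(st.sampled_from(["healthy", "pathological"]), min_size=1, max_size=60),
        data=st.data(),
    )
    def test_marginals_preserved(self, gold, data):
        pred = data.draw(
            st.lists(
                st.sampled_from(["healthy", "pathological", "inconclusive"]),
                min_size=len(gold),
                max_size=len(gold),
            )
        )
        t = confusion_2x2(gold, pred)
        assert t.tp + t.fn == gold.count("pathological")
        assert t.fp + t.tn == gold.count("healthy")
        assert t.n == len(gold)


class TestRates:
    @pytest.mark.parametrize(
        "tp,fn,expected",
        [(7, 11, 38.9), (12, 6, 66.7), (9, 9, 50.0), (10, 0, 100.0)],
    )
    def test_sensitivity(self, tp, fn, expected):
        assert sensitivity(ConfusionTable2x2(tp, fn, 0, 1)) == expected

    @pytest.mark.parametrize(
        "tn,fp,expected",
        [(23, 7, 76.7), (29, 1, 96.7), (30, 0, 100.0)],
    )
    def test_specificity(self, tn, fp, expected):
        assert specificity(ConfusionTable2x2(1, 0, fp, tn)) == expected

    def test_undefined_rates_raise(self):
        with pytest.raises(ZeroDivisionError):
            sensitivity(ConfusionTable2x2(0, 0, 1, 1))
        with pytest.raises(ZeroDivisionError):
            specificity(ConfusionTable2x2(1, 1, 0, 0))

    def test_rounding_is_half_up(self):
        # 1/16 = 6.25 % rounds up to 6.3, not banker's 6.2
        assert sensitivity(ConfusionTable2x2(1, 15, 0, 1)) == 6.3

    def test_order_invariance(self):
        gold = ["pathological", "healthy", "pathological", "healthy"]
        pred = ["pathological", "healthy", "healthy", "pathological"]
        t1 = confusion_2x2(gold, pred)
        t2 = confusion_2x2(gold[::-1], pred[::-1])
        assert sensitivity(t1) == sensitivity(t2)
        assert specificity(t1) == specificity(t2)


def _pairs(b: int, c: int, both: int = 3):
    a_corr = [True] * both + [True] * b + [False] * c
    b_corr = [True] * both + [False] * b + [True] * c
    return PairedOutcomes(a_corr, b_corr)


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        res = mcnemar_test(_pairs(5, 5), method="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_one_sided_discordance(self):
        res = mcnemar_test(_pairs(10, 0), method="exact")
        assert res.p_value == pytest.approx(2 * 0.5**10)
        assert (res.b, res.c) == (10, 0)

    def test_degenerate_no_discordance(self):
        res = mcnemar_test(_pairs(0, 0))
        assert res.p_value == 1.0
        assert "no discordant" in res.note

    def test_exact_matches_enumeration(self):
        for b in range(0, 11):
            for c in range(0, 11):
                if b + c == 0:
                    continue
                res = mcnemar_test(_pairs(b, c), method="exact")
                assert res.p_value == pytest.approx(
                    exact_binomial_two_sided(b, c), abs=1e-12
                )

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(3, 9), (1, 12), (7, 7), (0, 6)]:
            table = [[5, b], [c, 5]]
            ours = mcnemar_test(_pairs(b, c), method="exact")
            ref = sm_mcnemar(table, exact=True)
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)
            ours_asym = mcnemar_test(_pairs(b, c), method="asymptotic")
            ref_asym = sm_mcnemar(table, exact=False, correction=True)
            assert ours_asym.p_value == pytest.approx(float(ref_asym.pvalue), abs=1e-9)

    def test_auto_switches_on_discordant_count(self):
        assert mcnemar_test(_pairs(5, 5), method="auto").method == "exact"
        assert mcnemar_test(_pairs(20, 20), method="auto").method == "asymptotic"


class TestPairedOutcomes:
    def test_inconclusive_is_incorrect(self):
        gold = ["pathological", "healthy"]
        pairs = paired_outcomes_from_predictions(
            gold, ["inconclusive", "healthy"], ["pathological", "inconclusive"]
        )
        assert pairs.a_correct == [False, True]
        assert pairs.b_correct == [True, False]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PairedOutcomes([True], [True, False])
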