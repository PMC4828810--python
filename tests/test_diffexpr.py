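"""TPM, fold change, exact/chi-square tests, BH adjustment, DE calls, ddCt."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stemloop.diffexpr import (
    DifferentialResult,
    adjust_p,
    call_de,
    chisq_test,
    ddct,
    differential_expression,
    fisher_test,
    fold_change,
    round_ratio,
    tpm,
)
from stemloop.oracles import fisher_exact_enum


class TestTpm:
    def test_zero_count(self):
        assert tpm(0, 4133319) == 0.0

    def test_full_library(self):
        assert tpm(4133319, 4133319) == pytest.approx(1e6)

    def test_library_scale_example(self):
        assert tpm(245, 4133319) == pytest.approx(59.27, abs=0.01)

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            tpm(1, 0)


class TestFoldChange:
    @pytest.mark.parametrize(
        "f,m,ratio",
        [(59.22, 2.51, 23.594), (114.55, 51.14, 2.240), (5.0, 5.0, 1.0),
         (1.37, 6.27, 0.219), (5.72, 0.78, 7.333), (661.69, 1436.29, 0.461),
         (13.72, 5.80, 2.366)],
    )
    def test_published_ratio_arithmetic(self, f, m, ratio):
        r, _l2, _spec = fold_change(f, m)
        assert round(r, 3) == pytest.approx(ratio)

    def test_published_log2_value(self):
        r, l2, _ = fold_change(114.55, 51.14)
        assert round(l2, 4) == pytest.approx(1.1635)

    def test_equal_tpms_log2_zero(self):
        r, l2, spec = fold_change(5.0, 5.0)
        assert r == 1.0 and l2 == 0.0 and not spec

    def test_female_zero_flags_library_specific(self):
        r, l2, spec = fold_change(0.0, 10.04)
        assert r == 0.0 and l2 is None and spec

    def test_male_zero_gives_inf(self):
        r, l2, spec = fold_change(10.0, 0.0)
        assert math.isinf(r) and l2 is None and spec
        assert round_ratio(r) == "inf"

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.0)


class TestFisher:
    def test_equal_proportions_p_one(self):
        assert fisher_test(5, 100, 5, 100) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small(self):
        assert fisher_test(3, 1000, 0, 1000) == pytest.approx(
            fisher_exact_enum(3, 1000, 0, 1000), abs=1e-12
        )

    def test_back_derived_counts_significant(self):
        # counts at the scale of the two libraries' final clean totals
        p = fisher_test(245, 4133319, 15, 5883039)
        assert p < 0.05
        assert p == pytest.approx(fisher_exact_enum(245, 4133319, 15, 5883039), rel=1e-9)

    def test_oracle_agreement_on_random_tables(self):
        rng = random.Random(7)
        for _ in range(80):
            t1, t2 = rng.randint(1, 1000), rng.randint(1, 1000)
            a, b = rng.randint(0, min(60, t1)), rng.randint(0, min(60, t2))
            assert fisher_test(a, t1, b, t2) == pytest.approx(
                fisher_exact_enum(a, t1, b, t2), abs=1e-12
            )

    def test_cross_check_against_scipy(self):
        for (a, t1, b, t2) in [(5, 100, 15, 120), (0, 50, 9, 60), (30, 300, 10, 310)]:
            table = [[a, t1 - a], [b, t2 - b]]
            assert fisher_test(a, t1, b, t2) == pytest.approx(
                stats.fisher_exact(table).pvalue, rel=1e-8
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_test(-1, 10, 0, 10)


class TestChisq:
    def test_identical_proportions_p_one(self):
        assert chisq_test(10, 100, 10, 100) == pytest.approx(1.0)

    def test_closed_form_tail(self):
        a, t1, b, t2 = 50, 1000, 10, 1000
        n = t1 + t2
        chi2 = n * (a * (t2 - b) - (t1 - a) * b) ** 2 / (t1 * t2 * (a + b) * (n - a - b))
        assert chisq_test(a, t1, b, t2) == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-10)

    def test_agrees_with_fisher_for_large_counts(self):
        rng = random.Random(1)
        for _ in range(20):
            t1 = t2 = 2000
            a = rng.randint(50, 120)
            b = rng.randint(50, 120)
            pf = fisher_test(a, t1, b, t2)
            pc = chisq_test(a, t1, b, t2)
            # the asymptotic approximation is tight away from the extreme tail
            if 0.01 < pf < 0.95:
                assert pc == pytest.approx(pf, rel=0.2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_test(0, 10, 0, 10)

    def test_yates_correction_increases_p(self):
        assert chisq_test(12, 100, 4, 100, yates=True) >= chisq_test(12, 100, 4, 100)


class TestAdjustP:
    def test_single_p_unchanged(self):
        assert adjust_p([0.03]) == [pytest.approx(0.03)]

    def test_bh_hand_example(self):
        assert adjust_p([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_bonferroni(self):
        assert adjust_p([0.01, 0.4], method="bonferroni") == pytest.approx([0.02, 0.8])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_p([0.5, 1.5])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_order_preserved(self, ps):
        adj = adjust_p(ps)
        assert len(adj) == len(ps)
        for raw, a in zip(ps, adj):
            assert a >= raw - 1e-12
            assert a <= 1.0 + 1e-12


class TestCallDe:
    def _res(self, ratio, p, l2=0.0):
        return DifferentialResult(
            mirna_id="x", sequence="A" * 21, count_F=1, count_M=1,
            tpm_F=1.0, tpm_M=1.0, fold_change=ratio, log2_fc=l2, p_raw=p,
        )

    def test_high_ratio_significant_up_female(self):
        (r,) = call_de([self._res(23.594, 0.001)])
        assert r.de_call == "up_female"

    def test_sub_threshold_ratio_not_called(self):
        (r,) = call_de([self._res(1.5, 0.001)])
        assert r.de_call == "ns"

    def test_significant_down_called_up_male(self):
        (r,) = call_de([self._res(0.2, 0.001)])
        assert r.de_call == "up_male"

    def test_insignificant_p_not_called(self):
        (r,) = call_de([self._res(10.0, 0.5)])
        assert r.de_call == "ns"

    def test_library_specific_callable(self):
        res = self._res(math.inf, 0.0001)
        res.library_specific = True
        res.log2_fc = None
        (r,) = call_de([res])
        assert r.de_call == "up_female"

    def test_planted_de_directions_recovered(self, dataset, pipeline_result):
        truth = dataset.truth
        mature_of = {m.mirna_id: m.mature for m in truth.mirnas}
        id_of = {nm.mature: nm.mirna_id for nm in pipeline_result.novel_set}
        for mid, direction in truth.de_flags.items():
            if not direction:
                continue
            called_id = id_of[mature_of[mid]]
            (r,) = [x for x in pipeline_result.de_results if x.mirna_id == called_id]
            assert r.de_call == direction

    def test_non_de_mirnas_stay_ns(self, dataset, pipeline_result):
        truth = dataset.truth
        mature_of = {m.mirna_id: m.mature for m in truth.mirnas if not m.conserved_ref}
        id_of = {nm.mature: nm.mirna_id for nm in pipeline_result.novel_set}
        false_calls = []
        for mid, direction in truth.de_flags.items():
            if direction or mid.startswith("decoy") or mid not in mature_of:
                continue
            called_id = id_of.get(mature_of[mid])
            for x in pipeline_result.de_results:
                if x.mirna_id == called_id and x.de_call != "ns":
                    false_calls.append(mid)
        assert not false_calls


def test_direction_consistency_under_library_swap():
    counts = {"a": (60, 10), "b": (10, 60), "c": (30, 29)}
    fwd = differential_expression(counts, 1500, 1500)
    swapped = differential_expression({k: (m, f) for k, (f, m) in counts.items()}, 1500, 1500)
    flip = {"up_female": "up_male", "up_male": "up_female", "ns": "ns"}
    for f, s in zip(fwd, swapped):
        assert s.fold_change == pytest.approx(1.0 / f.fold_change)
        assert s.log2_fc == pytest.approx(-f.log2_fc)
        assert s.p_raw == pytest.approx(f.p_raw, rel=1e-12)
        assert s.de_call == flip[f.de_call]


class TestDdct:
    def test_zero_delta_delta(self):
        assert ddct(20, 15, 22, 17) == pytest.approx(1.0)

    def test_negative_ddct_doubles(self):
        assert ddct(20, 15, 22, 15) == pytest.approx(4.0)

    def test_positive_ddct_shrinks(self):
        assert ddct(25, 20, 20, 20) == pytest.approx(0.03125)
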