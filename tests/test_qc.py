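"""Per-SNP quality statistics: thresholding, call frequency, score
percentiles, MAF and Hardy-Weinberg, against hand-written oracles."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosschip import (
    CallMatrix,
    GenotypeCall,
    apply_no_call_threshold,
    call_frequency,
    compute_snp_metrics,
    gc_percentiles,
    hwe_test,
    minor_allele_frequency,
)
from ._oracles import hwe_chi2_exact, percentile_type7


def _calls(scores, snp="rs1"):
    return [
        GenotypeCall(snp, f"s{i}", "A", "A", s) for i, s in enumerate(scores)
    ]


class TestThreshold:
    def test_score_at_threshold_stays_a_call(self):
        out = apply_no_call_threshold(_calls([0.05, 0.15, 0.25]), 0.15)
        assert [c.is_vendor_nocall for c in out] == [True, False, False]

    def test_zero_threshold_keeps_everything(self):
        out = apply_no_call_threshold(_calls([0.0, 0.5, 1.0]), 0.0)
        assert not any(c.is_vendor_nocall for c in out)

    def test_vendor_nocall_survives_any_threshold(self):
        call = GenotypeCall("rs1", "s1", "-", "-", 0.99)
        (out,) = apply_no_call_threshold([call], 0.0)
        assert out.is_vendor_nocall

    @pytest.mark.parametrize("threshold", [0.05, 0.15, 0.25])
    def test_matches_brute_force_filter(self, threshold):
        rng = np.random.default_rng(42)
        scores = rng.random(100)
        out = apply_no_call_threshold(_calls(scores), threshold)
        expected_nocalls = sum(1 for s in scores if s < threshold)
        assert sum(c.is_vendor_nocall for c in out) == expected_nocalls


class TestCallFrequency:
    def test_published_ratio(self):
        calls = _calls([0.9] * 36) + [
            GenotypeCall("rs1", f"n{i}", "-", "-", 0.0) for i in range(4)
        ]
        assert call_frequency(calls) == 0.9

    def test_full_call_rate_is_exactly_one(self):
        assert call_frequency(_calls([0.5] * 40)) == 1.0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            call_frequency([])

    def test_matches_hand_count_on_simulated_data(self, sim500):
        matrix, manifest, _ = sim500
        metrics = compute_snp_metrics(matrix, manifest, 0.15)
        for snp_id in matrix.snps[:50]:
            calls = matrix.calls_for_snp(snp_id)
            n_called = sum(
                1 for c in calls if not c.is_vendor_nocall and c.score >= 0.15
            )
            assert metrics[snp_id].call_frequency == n_called / len(calls)


class TestGcPercentiles:
    def test_constant_distribution(self):
        assert gc_percentiles([0.8] * 10) == (0.8, 0.8, 0.8)

    def test_decile_grid_matches_order_statistic_oracle(self):
        scores = [i / 10 for i in range(1, 11)]
        gc10, gc50, avg = gc_percentiles(scores)
        assert gc10 == pytest.approx(percentile_type7(scores, 10), abs=1e-12)
        assert gc50 == pytest.approx(percentile_type7(scores, 50), abs=1e-12)
        assert avg == pytest.approx((gc10 + gc50) / 2, abs=0)

    def test_avg_gc_at_filter_boundary(self):
        # gc10=0.6, gc50=0.8 must average to 0.7 and pass a >= 0.7 cutoff
        scores = [0.6, 0.6, 0.6, 0.6, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8]
        gc10, gc50, avg = gc_percentiles(scores)
        assert (gc10, gc50) == (0.6, 0.8)
        assert avg >= 0.7

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_property_matches_oracle(self, scores):
        gc10, gc50, avg = gc_percentiles(scores)
        assert gc10 == pytest.approx(percentile_type7(scores, 10), abs=1e-9)
        assert gc50 == pytest.approx(percentile_type7(scores, 50), abs=1e-9)
        assert avg == (gc10 + gc50) / 2  # exact identity

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_percentiles([])


class TestMaf:
    def test_single_heterozygote_among_forty(self):
        assert minor_allele_frequency((39, 1, 0)) == 0.0125

    def test_monomorphic_is_zero(self):
        assert minor_allele_frequency((40, 0, 0)) == 0.0

    def test_hand_allele_count(self):
        assert minor_allele_frequency((30, 8, 2)) == 12 / 80 == 0.15

    def test_never_exceeds_half(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = tuple(rng.integers(0, 20, size=3))
            if sum(counts) == 0:
                continue
            assert 0.0 <= minor_allele_frequency(counts) <= 0.5


class TestHwe:
    def test_exact_hw_proportions(self):
        result = hwe_test((10, 20, 10))
        assert result.chi2 == pytest.approx(0.0, abs=1e-12)
        assert result.p == pytest.approx(1.0, abs=1e-12)
        assert result.in_equilibrium is True

    def test_out_of_equilibrium_closed_form(self):
        result = hwe_test((30, 4, 6))
        assert result.chi2 == pytest.approx(float(hwe_chi2_exact(30, 4, 6)), abs=1e-9)
        assert result.chi2 == pytest.approx(18.90625, abs=1e-9)
        assert result.p < 0.05 and result.in_equilibrium is False

    def test_single_het_closed_form(self):
        result = hwe_test((39, 1, 0))
        assert result.chi2 == pytest.approx(float(hwe_chi2_exact(39, 1, 0)), abs=1e-9)
        assert result.in_equilibrium is True

    def test_monomorphic_is_not_applicable(self):
        result = hwe_test((40, 0, 0))
        assert result.chi2 is None and result.in_equilibrium is None

    @settings(derandomize=True, max_examples=100)
    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
        ).filter(lambda c: sum(c) > 0)
    )
    def test_statistic_nonnegative_p_in_unit_interval(self, counts):
        result = hwe_test(counts)
        if result.applicable:
            assert result.chi2 >= 0
            assert 0.0 < result.p <= 1.0
            assert result.chi2 == pytest.approx(
                float(hwe_chi2_exact(*counts)), rel=1e-9, abs=1e-9
            )


class TestComputeSnpMetrics:
    def test_composition_equals_per_op_results(self, tiny_matrix, tiny_manifest):
        metrics = compute_snp_metrics(tiny_matrix, tiny_manifest, 0.15)
        rs1 = metrics["rs1"]
        assert rs1.genotype_counts == (1, 1, 0)
        assert rs1.call_frequency == 1.0
        assert rs1.maf == minor_allele_frequency((1, 1, 0))
        gc10, gc50, avg = gc_percentiles([0.9, 0.8])
        assert (rs1.gc10, rs1.gc50, rs1.avg_gc) == (gc10, gc50, avg)
        rs2 = metrics["rs2"]
        assert rs2.n_called == 1 and rs2.n_nocall == 1
        assert rs2.genotype_counts == (0, 1, 0) and rs2.maf == 0.5

    def test_empty_matrix_gives_empty_table(self, tiny_manifest):
        empty = CallMatrix(
            [], ["s1"],
            np.empty((0, 1), dtype="<U1"), np.empty((0, 1), dtype="<U1"),
            np.empty((0, 1)),
        )
        assert len(compute_snp_metrics(empty, tiny_manifest, 0.15)) == 0

    def test_zero_called_snp_has_undefined_fields(self, tiny_manifest):
        calls = [
            GenotypeCall("rs1", "s1", "-", "-", 0.0),
            GenotypeCall("rs2", "s1", "C", "C", 0.9),
        ]
        matrix = CallMatrix.from_calls(calls, snp_order=["rs1", "rs2"])
        m = compute_snp_metrics(matrix, tiny_manifest, 0.15)["rs1"]
        assert m.avg_gc is None and m.maf is None and m.call_frequency == 0.0

    def test_matches_brute_force_recomputation(self, sim500):
        matrix, manifest, _ = sim500
        threshold = 0.25
        metrics = compute_snp_metrics(matrix, manifest, threshold)
        by_id = {r.snp_id: r for r in manifest}
        for snp_id in matrix.snps:
            m = metrics[snp_id]
            calls = matrix.calls_for_snp(snp_id)
            called = [
                c for c in calls if not c.is_vendor_nocall and c.score >= threshold
            ]
            assert m.n_called == len(called)
            assert m.call_frequency == len(called) / len(calls)
            if called:
                scores = [c.score for c in called]
                assert m.gc10 == pytest.approx(percentile_type7(scores, 10), abs=1e-12)
                assert m.gc50 == pytest.approx(percentile_type7(scores, 50), abs=1e-12)
                assert m.avg_gc == (m.gc10 + m.gc50) / 2
                rec = by_id[snp_id]
                n_aa = sum(1 for c in called if {c.allele1, c.allele2} == {rec.allele_a})
                n_bb = sum(1 for c in called if {c.allele1, c.allele2} == {rec.allele_b})
                counts = (n_aa, len(called) - n_aa - n_bb, n_bb)
                assert m.genotype_counts == counts
                assert m.maf == minor_allele_frequency(counts)
                exact = hwe_chi2_exact(*counts)
                if exact is None:
                    assert m.hwe.chi2 is None
                else:
                    assert m.hwe.chi2 == pytest.approx(float(exact), rel=1e-9, abs=1e-9)

    def test_call_frequency_monotone_in_threshold(self, sim500):
        matrix, manifest, _ = sim500
        tables = {
            t: compute_snp_metrics(matrix, manifest, t) for t in (0.05, 0.15, 0.25)
        }
        full_call_sets = {
            t: {m.snp_id for m in table if m.n_nocall == 0}
            for t, table in tables.items()
        }
        # stricter thresholds can only shrink the fully-called set
        assert full_call_sets[0.25] <= full_call_sets[0.15] <= full_call_sets[0.05]
        for snp_id in matrix.snps:
            cf = [tables[t][snp_id].call_frequency for t in (0.05, 0.15, 0.25)]
            assert cf[0] >= cf[1] >= cf[2]
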