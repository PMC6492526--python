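"""Per-SNP genotype-quality statistics under a configurable no-call threshold.

For each SNP the module derives, from its 40-odd genotype calls: the call
frequency (calls / (calls + no-calls)), the 10th and 50th percentiles of the
GenCall-style quality scores across *called* genotypes (gc10 / gc50) and their
simple average (avg GC), genotype counts relative to the manifest allele pair,
minor allele frequency, and a 1-df chi-square test of Hardy-Weinberg
equilibrium.

Conventions, stated once and used consistently (including by test oracles):

* A genotype is a call iff its score is >= the threshold and it is not a
  vendor no-call — "scores less than the threshold are not assigned".
* Percentiles use linear interpolation between closest order statistics at
  rank p*(n-1) (the "type-7" rule, numpy's default).
* MAF and HWE are computed over called genotypes under the active threshold.
* HWE is a plain chi-square without continuity correction at alpha = 0.05;
  monomorphic SNPs are "not applicable", never "failed".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NO_CALL, CallMatrix, GenotypeCall, SnpManifestRecord

__all__ = [
    "SnpMetrics",
    "MetricsTable",
    "HweResult",
    "apply_no_call_threshold",
    "call_frequency",
    "gc_percentiles",
    "minor_allele_frequency",
    "hwe_test",
    "compute_snp_metrics",
]

HWE_ALPHA = 0.05


@dataclass(frozen=True)
class HweResult:
    """Chi-square Hardy-Weinberg test outcome for one SNP.

    ``in_equilibrium`` is None when the test is not applicable (monomorphic or
    no called genotypes).
    """

    chi2: Optional[float]
    p: Optional[float]
    in_equilibrium: Optional[bool]

    @property
    def applicable(self) -> bool:
        return self.chi2 is not None


@dataclass(frozen=True)
class SnpMetrics:
    """All per-SNP statistics the filter methods consume."""

    snp_id: str
    threshold_used: float
    n_called: int
    n_nocall: int
    call_frequency: float
    gc10: Optional[float]
    gc50: Optional[float]
    avg_gc: Optional[float]
    genotype_counts: tuple[int, int, int]  # (n_AA, n_AB, n_BB)
    maf: Optional[float]
    hwe: HweResult
    gentrain: float

    @property
    def n_samples(self) -> int:
        return self.n_called + self.n_nocall


class MetricsTable:
    """Ordered per-SNP metrics computed at one no-call threshold."""

    def __init__(self, threshold: float, metrics: Sequence[SnpMetrics]) -> None:
        self.threshold = threshold
        self._metrics = {m.snp_id: m for m in metrics}
        if len(self._metrics) != len(metrics):
            raise ValueError("duplicate SNP ids in metrics")

    def __getitem__(self, snp_id: str) -> SnpMetrics:
        return self._metrics[snp_id]

    def __iter__(self) -> Iterator[SnpMetrics]:
        return iter(self._metrics.values())

    def __len__(self) -> int:
        return len(self._metrics)

    @property
    def snp_ids(self) -> list[str]:
        return list(self._metrics)

    def to_frame(self) -> pd.DataFrame:
        """One row per SNP, all fields, suitable for a TSV audit dump."""
        rows = []
        for m in self:
            rows.append(
                {
                    "snp_id": m.snp_id,
                    "threshold": m.threshold_used,
                    "n_called": m.n_called,
                    "n_nocall": m.n_nocall,
                    "call_frequency": m.call_frequency,
                    "gc10": m.gc10,
                    "gc50": m.gc50,
                    "avg_gc": m.avg_gc,
                    "n_AA": m.genotype_counts[0],
                    "n_AB": m.genotype_counts[1],
                    "n_BB": m.genotype_counts[2],
                    "maf": m.maf,
                    "hwe_chi2": m.hwe.chi2,
                    "hwe_p": m.hwe.p,
                    "hwe_in_equilibrium": m.hwe.in_equilibrium,
                    "gentrain": m.gentrain,
                }
            )
        return pd.DataFrame(rows)


def apply_no_call_threshold(
    calls: Sequence[GenotypeCall], threshold: float
) -> list[GenotypeCall]:
    """Mark genotypes scoring strictly below ``threshold`` as no-calls.

    Scores exactly at the threshold remain calls; vendor no-calls stay
    no-calls at any threshold.  Scores are preserved on the masked calls.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    out: list[GenotypeCall] = []
    for call in calls:
        if not call.is_vendor_nocall and call.score < threshold:
            out.append(replace(call, allele1=NO_CALL, allele2=NO_CALL))
        else:
            out.append(call)
    return out


def call_frequency(calls: Sequence[GenotypeCall]) -> float:
    """Fraction of samples with a called genotype, calls / (calls + no-calls)."""
    if len(calls) == 0:
        raise ValueError("call frequency undefined for zero samples")
    n_called = sum(not c.is_vendor_nocall for c in calls)
    return n_called / len(calls)


def gc_percentiles(called_scores: Sequence[float]) -> tuple[float, float, float]:
    """(gc10, gc50, avg_gc) over the scores of called genotypes.

    avg_gc is the simple average of the two percentiles.
    """
    scores = np.asarray(called_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("percentiles undefined with zero called genotypes")
    gc10, gc50 = np.percentile(scores, [10, 50])  # linear / type-7
    return float(gc10), float(gc50), float((gc10 + gc50) / 2.0)


def minor_allele_frequency(genotype_counts: tuple[int, int, int]) -> float:
    """MAF from (n_AA, n_AB, n_BB): min allele count over 2 * n_called."""
    n_aa, n_ab, n_bb = genotype_counts
    n_called = n_aa + n_ab + n_bb
    if n_called < 1:
        raise ValueError("MAF undefined with zero called genotypes")
    count_a = 2 * n_aa + n_ab
    count_b = 2 * n_bb + n_ab
    return min(count_a, count_b) / (2 * n_called)


def hwe_test(
    genotype_counts: tuple[int, int, int], alpha: float = HWE_ALPHA
) -> HweResult:
    """1-df chi-square of observed genotype counts against Hardy-Weinberg
    expectations from the sample allele frequencies.

    No continuity correction.  Monomorphic SNPs (one allele absent) are not
    testable and return a not-applicable result.
    """
    n_aa, n_ab, n_bb = genotype_counts
    n = n_aa + n_ab + n_bb
    if n < 1:
        return HweResult(None, None, None)
    count_a = 2 * n_aa + n_ab
    count_b = 2 * n_bb + n_ab
    if count_a == 0 or count_b == 0:
        return HweResult(None, None, None)
    p = count_a / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pvalue = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2, pvalue, pvalue >= alpha)


def _classify_genotypes(
    allele1: np.ndarray, allele2: np.ndarray, record: SnpManifestRecord
) -> tuple[int, int, int]:
    """Count (AA, AB, BB) genotypes relative to the manifest allele pair."""
    n_aa = n_ab = n_bb = 0
    for a1, a2 in zip(allele1, allele2):
        pair = {a1, a2}
        if pair == {record.allele_a}:
            n_aa += 1
        elif pair == {record.allele_b}:
            n_bb += 1
        else:
            n_ab += 1
    return n_aa, n_ab, n_bb


def compute_snp_metrics(
    matrix: CallMatrix,
    manifest: Sequence[SnpManifestRecord],
    threshold: float,
) -> MetricsTable:
    """Compute :class:`SnpMetrics` for every SNP in ``matrix`` at one threshold.

    Per-SNP undefined states (no called genotypes, monomorphic) become None /
    not-applicable flags; the batch never aborts on them.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    by_id = {rec.snp_id: rec for rec in manifest}
    out: list[SnpMetrics] = []
    for snp_id in matrix.snps:
        record = by_id[snp_id]
        allele1, allele2, scores = matrix.snp_arrays(snp_id)
        vendor_nc = allele1 == NO_CALL
        called = (~vendor_nc) & (scores >= threshold)
        n_called = int(called.sum())
        n_total = matrix.n_samples

        if n_called > 0:
            gc10, gc50, avg_gc = gc_percentiles(scores[called])
            counts = _classify_genotypes(allele1[called], allele2[called], record)
            maf: Optional[float] = minor_allele_frequency(counts)
            hwe = hwe_test(counts)
        else:
            gc10 = gc50 = avg_gc = None
            counts = (0, 0, 0)
            maf = None
            hwe = HweResult(None, None, None)

        out.append(
            SnpMetrics(
                snp_id=snp_id,
                threshold_used=threshold,
                n_called=n_called,
                n_nocall=n_total - n_called,
                call_frequency=n_called / n_total,
                gc10=gc10,
                gc50=gc50,
                avg_gc=avg_gc,
                genotype_counts=counts,
                maf=maf,
                hwe=hwe,
                gentrain=record.gentrain,
            )
        )
    return MetricsTable(threshold, out)
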