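"""Independent brute-force oracles used across the suite.

These deliberately restate the published filter parameters and recompute every
quantity from raw calls with plain Python, without touching the qc/filters
implementations they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

# Published parameter table, restated here independently:
# name -> (no-call threshold, call-frequency rule, average-GC minimum or None)
ORACLE_METHODS = {
    "I": (0.05, ">=0.9", 0.7),
    "II": (0.05, "=1", 0.7),
    "III": (0.15, ">=0.9", 0.7),
    "IV": (0.15, "=1", 0.7),
    "V": (0.25, ">=0.9", 0.7),
    "VI": (0.25, "=1", 0.7),
    "VII": (0.25, "=1", None),
}
ORACLE_GENTRAIN_MIN = 0.25
ORACLE_MAF_LEVELS = (Fraction(1, 100), Fraction(5, 100))


def percentile_type7(values, p):
    """Linear interpolation between closest order statistics at rank p*(n-1)."""
    s = sorted(values)
    if not s:
        raise ValueError("empty")
    rank = (p / 100.0) * (len(s) - 1)
    lo = math.floor(rank)
    frac = rank - lo
    if lo + 1 < len(s):
        return s[lo] + (s[lo + 1] - s[lo]) * frac
    return s[lo]


def hwe_chi2_exact(n_aa, n_ab, n_bb):
    """Closed-form chi-square as an exact Fraction (None if not applicable)."""
    n = n_aa + n_ab + n_bb
    count_a = 2 * n_aa + n_ab
    count_b = 2 * n_bb + n_ab
    if n == 0 or count_a == 0 or count_b == 0:
        return None
    p = Fraction(count_a, 2 * n)
    q = 1 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (n_aa, n_ab, n_bb)
    return sum((Fraction(o) - e) ** 2 / e for o, e in zip(observed, expected))


def snp_filter_oracle(matrix, manifest_record, method_name):
    """Recompute one SNP's pass/fail decision at every cascade stage.

    Returns a dict stage -> bool where a stage's flag already includes all
    earlier stages (conjunctive cascade).
    """
    threshold, cf_rule, avg_gc_min = ORACLE_METHODS[method_name]
    snp_id = manifest_record.snp_id
    calls = matrix.calls_for_snp(snp_id)
    n = len(calls)
    called = [
        c for c in calls if c.allele1 != "-" and c.score >= threshold
    ]
    n_called = len(called)

    if cf_rule == "=1":
        pass_cf = n_called == n
    else:
        pass_cf = Fraction(n_called, n) >= Fraction(9, 10)

    if avg_gc_min is None:
        pass_gc = pass_cf
    elif n_called == 0:
        pass_gc = False
    else:
        scores = [c.score for c in called]
        avg_gc = (percentile_type7(scores, 10) + percentile_type7(scores, 50)) / 2.0
        pass_gc = pass_cf and avg_gc >= avg_gc_min

    pass_gt = pass_gc and manifest_record.gentrain >= ORACLE_GENTRAIN_MIN

    n_aa = sum(
        1 for c in called
        if c.allele1 == manifest_record.allele_a and c.allele2 == manifest_record.allele_a
    )
    n_bb = sum(
        1 for c in called
        if c.allele1 == manifest_record.allele_b and c.allele2 == manifest_record.allele_b
    )
    n_ab = n_called - n_aa - n_bb
    minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    maf = Fraction(minor, 2 * n_called) if n_called else None

    out = {"call_frequency": pass_cf, "avg_gc": pass_gc, "gentrain": pass_gt}
    passing = pass_gt
    for level in ORACLE_MAF_LEVELS:
        passing = passing and maf is not None and maf >= level
        out[f"maf_ge_{float(level):g}"] = passing
    return out


def cascade_oracle(matrix, manifest, method_name):
    """Per-stage surviving SNP-id sets recomputed by brute force."""
    stages = ["call_frequency", "avg_gc", "gentrain"] + [
        f"maf_ge_{float(level):g}" for level in ORACLE_MAF_LEVELS
    ]
    sets = {stage: set() for stage in stages}
    for record in manifest:
        flags = snp_filter_oracle(matrix, record, method_name)
        for stage in stages:
            if flags[stage]:
                sets[stage].add(record.snp_id)
    return sets


def naive_search(genome, query, revcomp):
    """Sliding-window exact search over both strands, for small genomes.

    Returns the same (scaffold, variant_pos, strand) triples as the
    implementation: variant at the query's 3' end.
    """
    L = len(query)
    rc = revcomp(query)
    hits = []
    for scaffold, seq in genome.sequences.items():
        for s in range(len(seq) - L + 1):
            window = seq[s : s + L]
            if window == query:
                hits.append((scaffold, s + L - 1, "+"))
            if window == rc:
                hits.append((scaffold, s, "-"))
    return hits
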