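"""Derived summary statistics: percentages of assayed SNPs, stage reductions,
and observed-vs-expected polymorphism proportions.

Rounding is half-away-from-zero throughout (1 decimal place for percentages,
6 for polymorphism fractions by default) — the convention that reproduces the
published derived values from their integer counts.  The expected polymorphic
fraction after ~42.7 Myr of divergence comes from an external exponential
decay model and is a configuration input, not recomputed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Mapping, Optional, Sequence

__all__ = [
    "ReportConfig",
    "round_half_away",
    "percent_of_total",
    "reduction_percent",
    "polymorphism_rate",
    "build_summary",
]


@dataclass(frozen=True)
class ReportConfig:
    """Constants the derived statistics are computed against.

    ``total_assayed`` defaults to the size of the bovine HD panel;
    ``expected_polymorphic_fraction`` is the external decay-model prediction,
    expressed on the same scale as the observed fraction n_poly/total (the
    source literature prints both with a stray percent sign; keeping them on
    one scale is what makes observed/expected a meaningful ratio).
    """

    total_assayed: int = 777_962
    divergence_time_myr: float = 42.7
    expected_polymorphic_fraction: float = 0.000515
    percent_dp: int = 1
    fraction_dp: int = 6

    def __post_init__(self) -> None:
        if self.total_assayed <= 0:
            raise ValueError("total_assayed must be positive")
        if not 0.0 < self.expected_polymorphic_fraction < 1.0:
            raise ValueError("expected fraction must be in (0, 1)")


def round_half_away(value: float, dp: int) -> float:
    """Round to ``dp`` decimals, ties away from zero (not banker's rounding)."""
    quantum = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_of_total(count: int, total: int, dp: int = 1) -> float:
    """100 * count / total, rounded half-away-from-zero to ``dp`` decimals."""
    if total == 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return round_half_away(100.0 * count / total, dp)


def reduction_percent(before: int, after: int, dp: int = 1) -> float:
    """Percentage drop from ``before`` to ``after``, 100 * (1 - after/before)."""
    if before == 0:
        raise ValueError("before must be positive")
    if not 0 <= after <= before:
        raise ValueError(f"after {after} outside [0, {before}]")
    return round_half_away(100.0 * (1.0 - after / before), dp)


def polymorphism_rate(
    n_poly: int,
    total_assayed: int,
    expected_fraction: float,
    dp: int = 6,
) -> tuple[float, float]:
    """(observed fraction of assayed SNPs, observed / expected ratio).

    The fraction is rounded to ``dp`` decimals; the ratio is computed on the
    unrounded fraction.
    """
    if expected_fraction == 0:
        raise ValueError("expected_fraction must be non-zero")
    if not 0 <= n_poly <= total_assayed:
        raise ValueError(f"n_poly {n_poly} outside [0, {total_assayed}]")
    observed = n_poly / total_assayed
    return round_half_away(observed, dp), observed / expected_fraction


def build_summary(
    cascades: Optional[Mapping[str, Any]] = None,
    uniqueness: Optional[Mapping[str, Mapping[str, Any]]] = None,
    retained: Optional[Sequence[str]] = None,
    assignments: Optional[Sequence[Any]] = None,
    annotations: Optional[Sequence[Any]] = None,
    conservation: Optional[Mapping[str, bool]] = None,
    hwe_flags: Optional[Mapping[str, Optional[bool]]] = None,
    config: ReportConfig = ReportConfig(),
) -> dict[str, Any]:
    """Assemble the full structured report from completed stage outputs.

    Any stage passed as None is recorded as an explicit gap rather than
    failing; field order is deterministic so regenerated reports are
    byte-identical.
    """
    report: dict[str, Any] = {
        "config": {
            "total_assayed": config.total_assayed,
            "divergence_time_myr": config.divergence_time_myr,
            "expected_polymorphic_fraction": config.expected_polymorphic_fraction,
        }
    }

    if cascades is None:
        report["methods"] = None
    else:
        methods: dict[str, Any] = {}
        for name in sorted(cascades):
            cascade = cascades[name]
            counts = cascade.counts
            methods[name] = {
                "stage_counts": {stage: counts[stage] for stage in cascade.stages},
                "percent_of_assayed": {
                    stage: percent_of_total(
                        min(counts[stage], config.total_assayed),
                        config.total_assayed,
                        config.percent_dp,
                    )
                    for stage in cascade.stages
                },
            }
        report["methods"] = methods

    if uniqueness is None:
        report["genomes"] = None
    else:
        genomes: dict[str, Any] = {}
        for genome_id in sorted(uniqueness):
            calls = uniqueness[genome_id]
            tally = {"absent": 0, "unique": 0, "multi_scaffold": 0, "multi_within_scaffold": 0}
            for call in calls.values():
                tally[call.classification] += 1
            genomes[genome_id] = {
                "multi_scaffold": tally["multi_scaffold"] + tally["multi_within_scaffold"],
                "unique": tally["unique"],
                "absent": tally["absent"],
            }
        report["genomes"] = genomes

    if retained is None:
        report["common_to_both"] = None
    else:
        report["common_to_both"] = len(retained)

    if assignments is None:
        report["chromosome_assignment"] = None
    else:
        from .annotate import chromosome_distribution

        n_assigned = sum(1 for a in assignments if a.assigned)
        distribution = chromosome_distribution(assignments)
        report["chromosome_assignment"] = {
            "assigned": n_assigned,
            "unassigned": len(assignments) - n_assigned,
            "distribution": {k: distribution[k] for k in sorted(distribution)},
        }

    if annotations is None:
        report["genes"] = None
    else:
        within = [a for a in annotations if a is not None and a.within_gene]
        report["genes"] = {
            "snps_within_genes": len(within),
            "distinct_genes_hit": len({a.gene_id for a in within}),
        }

    if conservation is None:
        report["conservation"] = None
    else:
        report["conservation"] = {
            "checked": len(conservation),
            "conserved": sum(bool(v) for v in conservation.values()),
        }

    if hwe_flags is None:
        report["hwe"] = None
    else:
        report["hwe"] = {
            "tested": sum(1 for v in hwe_flags.values() if v is not None),
            "out_of_equilibrium": sum(1 for v in hwe_flags.values() if v is False),
        }

    if retained is not None:
        observed, ratio = polymorphism_rate(
            len(retained), config.total_assayed, config.expected_polymorphic_fraction,
            config.fraction_dp,
        )
        report["polymorphism"] = {
            "observed_fraction": observed,
            "expected_fraction": config.expected_polymorphic_fraction,
            "observed_over_expected": round_half_away(ratio, 2),
        }
    else:
        report["polymorphism"] = None

    return report


def write_summary_json(report: Mapping[str, Any], path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
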