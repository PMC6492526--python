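"""The seven published filter configurations (Methods I-VII) and the
stage-wise cascade that produces per-method survivor counts.

Stages are applied in the order call-frequency -> average GC -> GenTrain ->
MAF >= 0.01 -> MAF >= 0.05; because each stage is a conjunctive filter, the
final set is order-independent — the order only shapes the intermediate
counts reported in the audit table.

Numeric conventions: "call frequency = 1" is the exact integer condition
`n_nocall == 0`, never a float comparison; the >= 0.9 rule and the MAF
cutoffs compare exact rationals built from integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import CallMatrix, SnpManifestRecord
from .qc import MetricsTable, SnpMetrics, compute_snp_metrics

__all__ = [
    "MethodConfig",
    "CascadeResult",
    "METHOD_NAMES",
    "method_config",
    "apply_method",
    "compare_methods",
    "cascade_table",
]

METHOD_NAMES = ("I", "II", "III", "IV", "V", "VI", "VII")

#: the two MAF retention levels reported for every method
MAF_LEVELS = (Fraction(1, 100), Fraction(5, 100))


@dataclass(frozen=True)
class MethodConfig:
    """One filter method: thresholds plus comparators.

    ``call_freq_comparator`` is ``'ge'`` (>= value) or ``'eq'`` (exactly 1,
    i.e. zero no-calls).  ``avg_gc_min`` of None disables the average-GC stage
    (Method VII).
    """

    name: str
    no_call_threshold: float
    call_freq_comparator: str
    call_freq_value: Fraction
    avg_gc_min: Optional[float]
    gentrain_min: float
    maf_levels: tuple[Fraction, ...] = MAF_LEVELS

    def __post_init__(self) -> None:
        if self.call_freq_comparator not in ("ge", "eq"):
            raise ValueError(f"unknown comparator {self.call_freq_comparator!r}")
        if self.call_freq_comparator == "eq" and self.call_freq_value != 1:
            raise ValueError("'eq' rule is only defined for call frequency = 1")

    def passes_call_frequency(self, m: SnpMetrics) -> bool:
        if self.call_freq_comparator == "eq":
            return m.n_nocall == 0
        return Fraction(m.n_called, m.n_samples) >= self.call_freq_value

    def passes_avg_gc(self, m: SnpMetrics) -> bool:
        if self.avg_gc_min is None:
            return True
        return m.avg_gc is not None and m.avg_gc >= self.avg_gc_min

    def passes_gentrain(self, m: SnpMetrics) -> bool:
        return m.gentrain >= self.gentrain_min

    def passes_maf(self, m: SnpMetrics, level: Fraction) -> bool:
        n_aa, n_ab, n_bb = m.genotype_counts
        n_called = n_aa + n_ab + n_bb
        if n_called == 0:
            return False
        minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
        return Fraction(minor, 2 * n_called) >= level


_TABLE: dict[str, tuple[float, str, Optional[float]]] = {
    # name: (no-call threshold, call-frequency rule, avg GC minimum)
    "I": (0.05, "ge", 0.7),
    "II": (0.05, "eq", 0.7),
    "III": (0.15, "ge", 0.7),
    "IV": (0.15, "eq", 0.7),
    "V": (0.25, "ge", 0.7),
    "VI": (0.25, "eq", 0.7),
    "VII": (0.25, "eq", None),
}


def method_config(name: str) -> MethodConfig:
    """Return the configuration of one of the seven published methods."""
    try:
        threshold, rule, avg_gc = _TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown method {name!r}; valid names are {', '.join(METHOD_NAMES)}"
        ) from None
    return MethodConfig(
        name=name,
        no_call_threshold=threshold,
        call_freq_comparator=rule,
        call_freq_value=Fraction(1) if rule == "eq" else Fraction(9, 10),
        avg_gc_min=avg_gc,
        gentrain_min=0.25,
    )


@dataclass
class CascadeResult:
    """Per-stage surviving SNP-id sets for one method on one dataset."""

    method: str
    stages: list[str]
    sets: dict[str, frozenset[str]]

    @property
    def counts(self) -> dict[str, int]:
        return {stage: len(self.sets[stage]) for stage in self.stages}

    def survivors(self, stage: Optional[str] = None) -> frozenset[str]:
        if stage is None:
            stage = self.stages[-1]
        return self.sets[stage]

    def __post_init__(self) -> None:
        previous: Optional[frozenset[str]] = None
        for stage in self.stages:
            current = self.sets[stage]
            if previous is not None and not current <= previous:
                raise ValueError(f"stage {stage!r} is not nested in its predecessor")
            previous = current


def stage_names(config: MethodConfig) -> list[str]:
    names = ["call_frequency", "avg_gc", "gentrain"]
    names += [f"maf_ge_{float(level):g}" for level in config.maf_levels]
    return names


def apply_method(metrics: MetricsTable, config: MethodConfig) -> CascadeResult:
    """Run one method's filter cascade over a metrics table.

    The metrics must have been computed at the method's own no-call threshold;
    a mismatch is rejected rather than silently producing shifted counts.
    """
    if metrics.threshold != config.no_call_threshold:
        raise ValueError(
            f"metrics computed at threshold {metrics.threshold} but method "
            f"{config.name} requires {config.no_call_threshold}"
        )
    surviving = [m for m in metrics if config.passes_call_frequency(m)]
    sets: dict[str, frozenset[str]] = {
        "call_frequency": frozenset(m.snp_id for m in surviving)
    }
    surviving = [m for m in surviving if config.passes_avg_gc(m)]
    sets["avg_gc"] = frozenset(m.snp_id for m in surviving)
    surviving = [m for m in surviving if config.passes_gentrain(m)]
    sets["gentrain"] = frozenset(m.snp_id for m in surviving)
    for level in config.maf_levels:
        surviving = [m for m in surviving if config.passes_maf(m, level)]
        sets[f"maf_ge_{float(level):g}"] = frozenset(m.snp_id for m in surviving)
    return CascadeResult(config.name, stage_names(config), sets)


def compare_methods(
    matrix: CallMatrix,
    manifest: Sequence[SnpManifestRecord],
    names: Sequence[str] = METHOD_NAMES,
) -> dict[str, CascadeResult]:
    """Run several methods, recomputing metrics once per distinct threshold."""
    if not names:
        raise ValueError("at least one method name is required")
    configs = [method_config(name) for name in names]
    metrics_by_threshold: dict[float, MetricsTable] = {}
    for config in configs:
        if config.no_call_threshold not in metrics_by_threshold:
            metrics_by_threshold[config.no_call_threshold] = compute_snp_metrics(
                matrix, manifest, config.no_call_threshold
            )
    return {
        config.name: apply_method(metrics_by_threshold[config.no_call_threshold], config)
        for config in configs
    }


def cascade_table(results: Mapping[str, CascadeResult]) -> pd.DataFrame:
    """Survivor counts as a stages x methods table (the audit-table shape)."""
    stages: list[str] = []
    for result in results.values():
        for stage in result.stages:
            if stage not in stages:
                stages.append(stage)
    data = {
        name: [result.counts.get(stage) for stage in stages]
        for name, result in results.items()
    }
    return pd.DataFrame(data, index=stages)
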