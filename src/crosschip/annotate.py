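"""Chromosome assignment via a scaffold synteny map, and nearest-gene lookup.

Scaffold-level assemblies carry no chromosome coordinates, so placement relies
on an external scaffold -> chromosome map built from cattle/camelid synteny or
cytogenetic mapping; scaffolds outside the map yield "unassigned".  Gene
proximity is measured from the variant base to the closest edge of a gene's
full span, strand-agnostic, distance 0 meaning the variant lies inside the
gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .flanks import SnpLocus
from .io import GeneSet, ScaffoldChromosomeMap

__all__ = [
    "UNASSIGNED",
    "ChromosomeAssignment",
    "GeneAnnotation",
    "assign_chromosome",
    "chromosome_distribution",
    "nearest_gene",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ChromosomeAssignment:
    snp_id: str
    chromosome: str  # chromosome label or UNASSIGNED
    evidence: Optional[str]  # synteny | cytogenetic | None

    @property
    def assigned(self) -> bool:
        return self.chromosome != UNASSIGNED


@dataclass(frozen=True)
class GeneAnnotation:
    snp_id: str
    gene_id: str
    distance: int  # bp from variant to gene span; 0 when inside
    within_gene: bool

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.within_gene != (self.distance == 0):
            raise ValueError("within_gene must hold exactly when distance is 0")


def assign_chromosome(
    cmap: ScaffoldChromosomeMap, locus: SnpLocus
) -> ChromosomeAssignment:
    """Look up the locus scaffold in the map; absent scaffolds are unassigned."""
    entry = cmap.chromosome_of(locus.scaffold)
    if entry is None:
        return ChromosomeAssignment(locus.snp_id, UNASSIGNED, None)
    chromosome, evidence = entry
    return ChromosomeAssignment(locus.snp_id, chromosome, evidence)


def chromosome_distribution(
    assignments: Sequence[ChromosomeAssignment],
) -> dict[str, int]:
    """Tally of SNPs per chromosome label, including the unassigned bucket."""
    return dict(Counter(a.chromosome for a in assignments))


def _distance_to_interval(pos: int, start: int, end: int) -> int:
    """bp distance from a position to a 0-based half-open interval."""
    if start <= pos < end:
        return 0
    if pos < start:
        return start - pos
    return pos - (end - 1)


def nearest_gene(geneset: GeneSet, locus: SnpLocus) -> Optional[GeneAnnotation]:
    """The gene minimizing distance to the variant on the locus scaffold.

    Ties break to the smaller start coordinate, then lexicographic gene id.
    Returns None when the scaffold carries no annotated gene.
    """
    genes = geneset.on_scaffold(locus.scaffold)
    if not genes:
        return None
    best = min(
        genes,
        key=lambda g: (
            _distance_to_interval(locus.variant_pos, g.start, g.end),
            g.start,
            g.gene_id,
        ),
    )
    distance = _distance_to_interval(locus.variant_pos, best.start, best.end)
    return GeneAnnotation(locus.snp_id, best.gene_id, distance, distance == 0)
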