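"""Anchor array SNPs in genome assemblies by perfect-match flank queries.

Probe hybridization tolerates mismatches far from the variant but not close to
it, so a SNP is anchored by two short queries per allele: the last 20 or 25 nt
of the upstream flank plus the allele base (read 5'->3', variant at the 3'
end), and — read on the negative strand — the allele base plus the first 20 or
25 nt of the downstream flank.  Only perfect matches count, which makes exact
substring search a faithful, dependency-free replacement for short-read BLAST:
any hit it reports is a perfect alignment and vice versa.

A locus requires an upstream and a downstream query to imply the *same*
(scaffold, variant position, strand); the co-located 21-mer pair is the
default minimum evidence, with 26-mer support recorded when present.
Matching is case-insensitive at read time (genomes are stored uppercase);
``N`` never matches anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import reverse_complement

from .io import Genome, SnpManifestRecord

__all__ = [
    "FlankQuery",
    "GenomeHit",
    "SnpLocus",
    "SnpContext",
    "UniquenessCall",
    "DEFAULT_LENGTHS",
    "build_flank_queries",
    "search_exact",
    "locate_snp",
    "classify_uniqueness",
    "intersect_genomes",
    "extract_context",
    "conservation_check",
    "write_loci_bed",
]

#: query lengths implied by "the 20th or 25th nucleotide plus the variant base"
DEFAULT_LENGTHS = (21, 26)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class FlankQuery:
    """One allele-terminated flank query.

    The variant base sits at the 3' end of the query *as constructed*;
    downstream queries are already reverse-complemented, so their stored
    sequence ends in the complement of the allele.
    """

    snp_id: str
    side: str  # 'upstream' | 'downstream'
    allele_label: str  # 'A' | 'B'
    allele: str  # the actual base
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError(f"{self.snp_id}: query length mismatch")


@dataclass(frozen=True)
class GenomeHit:
    """A perfect match of one flank query, reduced to the implied variant base.

    ``strand`` is the strand of the *locus* (the strand on which the manifest
    source sequence reads forward), already corrected for downstream queries
    having been built on the negative strand.
    """

    genome_id: str
    scaffold: str
    variant_pos: int  # 0-based coordinate of the variant base
    strand: str  # '+' | '-'
    side: str
    allele_label: str
    length: int


@dataclass(frozen=True)
class SnpLocus:
    """A genomic placement supported by co-located upstream + downstream queries."""

    snp_id: str
    genome_id: str
    scaffold: str
    variant_pos: int
    strand: str
    supported_lengths: frozenset[int]
    matched_alleles: frozenset[str]


@dataclass(frozen=True)
class UniquenessCall:
    """Uniqueness classification of one SNP against one genome."""

    snp_id: str
    genome_id: str
    classification: str  # absent | unique | multi_scaffold | multi_within_scaffold
    loci: tuple[SnpLocus, ...]

    @property
    def is_unique(self) -> bool:
        return self.classification == "unique"


@dataclass(frozen=True)
class SnpContext:
    """Sequence window around a located variant, variant-centred when full."""

    snp_id: str
    sequence: str
    center_index: int
    truncated: bool


def build_flank_queries(
    record: SnpManifestRecord, lengths: Sequence[int] = DEFAULT_LENGTHS
) -> list[FlankQuery]:
    """Build up to ``2 * len(lengths) * 2`` allele-terminated queries for one SNP.

    For length L and allele X: the upstream query is the last L-1 nt of the
    upstream flank followed by X; the downstream query is the reverse
    complement of X followed by the first L-1 nt of the downstream flank.
    A flank too short for a length yields no query for that (side, length).
    """
    queries: list[FlankQuery] = []
    for length in lengths:
        need = length - 1
        for label, base in (("A", record.allele_a), ("B", record.allele_b)):
            if len(record.flank_up) >= need:
                queries.append(
                    FlankQuery(
                        record.snp_id, "upstream", label, base, length,
                        record.flank_up[-need:] + base,
                    )
                )
            if len(record.flank_down) >= need:
                queries.append(
                    FlankQuery(
                        record.snp_id, "downstream", label, base, length,
                        reverse_complement(base + record.flank_down[:need]),
                    )
                )
    return queries


def _occurrences(haystack: str, needle: str) -> Iterable[int]:
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def search_exact(
    genome: Genome, query: str
) -> list[tuple[str, int, str]]:
    """All perfect occurrences of ``query`` in a genome, on either strand.

    Returns (scaffold, variant_pos, raw_strand) triples where ``variant_pos``
    is the 0-based coordinate of the query's 3'-end (variant) base: for a
    ``+`` occurrence at offset s that is s + L - 1; for a ``-`` occurrence
    (the reverse complement found on the forward sequence at offset s) it is
    s itself.  ``N`` in the genome never matches because queries are
    restricted to A/C/G/T.
    """
    query = query.upper()
    if not set(query) <= _ACGT:
        raise ValueError(f"query must be over A/C/G/T, got {query!r}")
    rc = reverse_complement(query)
    L = len(query)
    hits: list[tuple[str, int, str]] = []
    for scaffold, seq in genome.sequences.items():
        for s in _occurrences(seq, query):
            hits.append((scaffold, s + L - 1, "+"))
        for s in _occurrences(seq, rc):
            hits.append((scaffold, s, "-"))
    return hits


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def locate_snp(
    genomes: Mapping[str, Genome] | Sequence[Genome],
    queries: Sequence[FlankQuery],
    required_length: int = 21,
) -> dict[str, list[SnpLocus]]:
    """Consolidate flank-query hits into loci, per genome.

    A locus is emitted where an upstream hit and a downstream hit imply the
    same (scaffold, variant position, strand).  ``required_length`` is the
    minimum evidence: both sides must co-match at that length (21 by default;
    26 makes the criterion strictly stricter).  Queries containing N are
    skipped — N never matches.
    """
    if required_length not in {q.length for q in queries} and queries:
        raise ValueError(f"no queries of required length {required_length}")
    genome_map: Mapping[str, Genome]
    if isinstance(genomes, Mapping):
        genome_map = genomes
    else:
        genome_map = {g.name: g for g in genomes}
    snp_ids = {q.snp_id for q in queries}
    if len(snp_ids) > 1:
        raise ValueError("locate_snp consolidates queries of a single SNP")
    snp_id = next(iter(snp_ids)) if snp_ids else ""

    out: dict[str, list[SnpLocus]] = {}
    for genome_id, genome in genome_map.items():
        # (scaffold, variant_pos, locus_strand) -> side -> set of (length, allele_label)
        support: dict[tuple[str, int, str], dict[str, set[tuple[int, str]]]] = {}
        for query in queries:
            if not set(query.sequence) <= _ACGT:
                continue  # N never matches
            for scaffold, variant_pos, raw_strand in search_exact(genome, query.sequence):
                locus_strand = raw_strand if query.side == "upstream" else _flip(raw_strand)
                key = (scaffold, variant_pos, locus_strand)
                support.setdefault(key, {"upstream": set(), "downstream": set()})
                support[key][query.side].add((query.length, query.allele_label))
        loci: list[SnpLocus] = []
        for (scaffold, variant_pos, strand), sides in sorted(support.items()):
            up_lengths = {length for length, _ in sides["upstream"]}
            down_lengths = {length for length, _ in sides["downstream"]}
            both = up_lengths & down_lengths
            if required_length not in both:
                continue
            alleles = {label for _, label in sides["upstream"]} & {
                label for _, label in sides["downstream"]
            }
            loci.append(
                SnpLocus(
                    snp_id=snp_id,
                    genome_id=genome_id,
                    scaffold=scaffold,
                    variant_pos=variant_pos,
                    strand=strand,
                    supported_lengths=frozenset(both),
                    matched_alleles=frozenset(alleles),
                )
            )
        out[genome_id] = loci
    return out


def classify_uniqueness(
    snp_id: str, genome_id: str, loci: Sequence[SnpLocus]
) -> UniquenessCall:
    """absent / unique / multi_scaffold / multi_within_scaffold for one genome.

    Only a single locus counts as unique; several loci on one scaffold are
    still non-unique (multi_within_scaffold).
    """
    loci = tuple(sorted(loci, key=lambda l: (l.scaffold, l.variant_pos, l.strand)))
    if len(loci) == 0:
        classification = "absent"
    elif len(loci) == 1:
        classification = "unique"
    elif len({l.scaffold for l in loci}) > 1:
        classification = "multi_scaffold"
    else:
        classification = "multi_within_scaffold"
    return UniquenessCall(snp_id, genome_id, classification, loci)


def intersect_genomes(
    calls_a: Mapping[str, UniquenessCall], calls_b: Mapping[str, UniquenessCall]
) -> set[str]:
    """SNPs unique in both genomes — the retention rule for cross-assembly support."""
    return {
        snp_id
        for snp_id, call in calls_a.items()
        if call.is_unique and snp_id in calls_b and calls_b[snp_id].is_unique
    }


def extract_context(genome: Genome, locus: SnpLocus, flank: int = 50) -> SnpContext:
    """Extract the (2*flank + 1)-nt window centred on the variant base.

    The window is reverse-complemented for negative-strand loci so it reads in
    the source orientation.  Variants within ``flank`` of a scaffold edge get
    a truncated window and a flag; flagged contexts are excluded from
    conservation checks.
    """
    seq = genome[locus.scaffold]
    v = locus.variant_pos
    lo = max(0, v - flank)
    hi = min(len(seq), v + flank + 1)
    window = seq[lo:hi]
    truncated = len(window) < 2 * flank + 1
    if locus.strand == "-":
        window = reverse_complement(window)
        center = (hi - 1) - v
    else:
        center = v - lo
    return SnpContext(locus.snp_id, window, center, truncated)


def conservation_check(
    context: SnpContext,
    other_genome: Genome,
    alleles: Optional[tuple[str, str]] = None,
) -> bool:
    """True iff the full context occurs perfectly in another genome.

    Either strand counts, and either allele may be substituted at the centre
    (the other assembly is haploid and may carry the alternative base).
    Truncated contexts are never conserved — the evidence is incomplete.
    """
    if context.truncated:
        return False
    center_bases = {context.sequence[context.center_index]}
    if alleles is not None:
        center_bases.update(alleles)
    for base in sorted(center_bases):
        candidate = (
            context.sequence[: context.center_index]
            + base
            + context.sequence[context.center_index + 1 :]
        )
        if not set(candidate) <= _ACGT:
            continue
        rc = reverse_complement(candidate)
        for seq in other_genome.sequences.values():
            if candidate in seq or rc in seq:
                return True
    return False


def write_loci_bed(loci: Sequence[SnpLocus], path: str | Path) -> None:
    """Write loci as BED (0-based half-open, variant as a 1-bp interval)."""
    with open(path, "w") as fh:
        for locus in sorted(loci, key=lambda l: (l.scaffold, l.variant_pos, l.snp_id)):
            fh.write(
                "\t".join(
                    [
                        locus.scaffold,
                        str(locus.variant_pos),
                        str(locus.variant_pos + 1),
                        locus.snp_id,
                        str(max(locus.supported_lengths)),
                        locus.strand,
                    ]
                )
                + "\n"
            )
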