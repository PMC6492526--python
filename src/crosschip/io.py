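"""Readers and writers for every external file the pipeline touches.

Formats handled: long-format genotype report (TSV, one row per SNP x sample,
mirroring the column roles of an Illumina "Final Report"), SNP manifest (CSV
with the source sequence in ``LEFT[A/B]RIGHT`` bracket notation), genome FASTA,
scaffold-to-chromosome synteny map (TSV) and gene annotation (GFF3).

All internal coordinates are 0-based half-open; file interfaces keep each
format's native convention (GFF3 is 1-based inclusive).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "StructuralError",
    "ValidationError",
    "GenotypeCall",
    "SnpManifestRecord",
    "CallMatrix",
    "Genome",
    "ScaffoldChromosomeMap",
    "Gene",
    "GeneSet",
    "read_genotype_report",
    "write_genotype_report",
    "read_snp_manifest",
    "write_snp_manifest",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_synteny_map",
    "write_synteny_map",
    "read_gene_annotation",
    "write_gene_annotation",
]

NO_CALL = "-"
_VALID_BASES = frozenset("ACGT")
_FLANK_BASES = frozenset("ACGTN")
# full nucleotide ambiguity alphabet accepted in genome sequence
_IUPAC_BASES = frozenset("ACGTNRYSWKMBDHV")

#: flanks shorter than this cannot anchor the longer (26-mer) flank query
MIN_FLANK_LEN = 25


class ParseError(ValueError):
    """A file could not be parsed into the expected structure."""


class StructuralError(ValueError):
    """A parsed file is structurally incomplete (e.g. missing SNP x sample pairs)."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant (range, allele pair, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    """One genotype for one SNP in one sample, with its per-genotype quality score.

    A vendor-level no-call is encoded as ``('-', '-')``; the score is kept as
    reported.  Threshold-induced no-calls are applied downstream and never
    stored here.
    """

    snp_id: str
    sample_id: str
    allele1: str
    allele2: str
    score: float

    @property
    def is_vendor_nocall(self) -> bool:
        return self.allele1 == NO_CALL

    def __post_init__(self) -> None:
        if (self.allele1 == NO_CALL) != (self.allele2 == NO_CALL):
            raise ValidationError(
                f"{self.snp_id}/{self.sample_id}: half no-call "
                f"({self.allele1}/{self.allele2}) is not a valid genotype"
            )
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(
                f"{self.snp_id}/{self.sample_id}: score {self.score} outside [0, 1]"
            )


@dataclass(frozen=True)
class SnpManifestRecord:
    """Per-SNP manifest entry: allele pair, probe flanks and GenTrain score.

    ``flank_up`` is 5' of the variant and ``flank_down`` 3' of it, both on the
    source strand as given in the manifest's bracket notation.
    """

    snp_id: str
    allele_a: str
    allele_b: str
    flank_up: str
    flank_down: str
    gentrain: float
    source_chrom: Optional[str] = None
    source_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.snp_id}: allele pair must differ")
        for allele in (self.allele_a, self.allele_b):
            if allele not in _VALID_BASES:
                raise ValidationError(f"{self.snp_id}: invalid allele {allele!r}")
        for name, flank in (("flank_up", self.flank_up), ("flank_down", self.flank_down)):
            if not flank:
                raise ValidationError(f"{self.snp_id}: empty {name} (flanks required)")
            if not set(flank) <= _FLANK_BASES:
                raise ValidationError(f"{self.snp_id}: {name} has non-ACGTN characters")
        if not 0.0 <= self.gentrain <= 1.0:
            raise ValidationError(f"{self.snp_id}: gentrain {self.gentrain} outside [0, 1]")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def source_seq(self) -> str:
        """Bracket-notation source sequence, ``LEFT[A/B]RIGHT``."""
        return f"{self.flank_up}[{self.allele_a}/{self.allele_b}]{self.flank_down}"


class CallMatrix:
    """Complete SNP x sample genotype matrix with per-genotype scores.

    Rows (SNPs) and columns (samples) are held in canonical order so that two
    reports differing only in row order compare equal.
    """

    def __init__(
        self,
        snps: Sequence[str],
        samples: Sequence[str],
        allele1: np.ndarray,
        allele2: np.ndarray,
        scores: np.ndarray,
    ) -> None:
        self.snps = list(snps)
        self.samples = list(samples)
        shape = (len(self.snps), len(self.samples))
        if allele1.shape != shape or allele2.shape != shape or scores.shape != shape:
            raise StructuralError(f"array shapes do not match {shape}")
        if len(self.samples) < 1:
            raise StructuralError("a call matrix needs at least one sample")
        self.allele1 = allele1
        self.allele2 = allele2
        self.scores = scores
        self._snp_index = {s: i for i, s in enumerate(self.snps)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    @classmethod
    def from_calls(
        cls, calls: Iterable[GenotypeCall], snp_order: Optional[Sequence[str]] = None
    ) -> "CallMatrix":
        """Build a matrix from calls; every (snp, sample) pair must occur exactly once."""
        by_key: dict[tuple[str, str], GenotypeCall] = {}
        snps_seen: dict[str, None] = {}  # insertion-ordered set
        samples_seen: set[str] = set()
        for call in calls:
            key = (call.snp_id, call.sample_id)
            if key in by_key:
                raise StructuralError(f"duplicate genotype row for {key}")
            by_key[key] = call
            snps_seen.setdefault(call.snp_id)
            samples_seen.add(call.sample_id)
        if snp_order is not None:
            order_set = set(snp_order)
            extra = [s for s in snps_seen if s not in order_set]
            if extra:
                raise ValidationError(f"SNPs not in manifest: {extra[:5]}")
            snps = [s for s in snp_order if s in snps_seen]
        else:
            snps = sorted(snps_seen)
        samples = sorted(samples_seen)
        n, m = len(snps), len(samples)
        allele1 = np.full((n, m), NO_CALL, dtype="<U1")
        allele2 = np.full((n, m), NO_CALL, dtype="<U1")
        scores = np.zeros((n, m), dtype=float)
        for i, snp in enumerate(snps):
            for j, sample in enumerate(samples):
                call = by_key.get((snp, sample))
                if call is None:
                    raise StructuralError(f"missing genotype row for ({snp}, {sample})")
                allele1[i, j] = call.allele1
                allele2[i, j] = call.allele2
                scores[i, j] = call.score
        return cls(snps, samples, allele1, allele2, scores)

    def call(self, snp_id: str, sample_id: str) -> GenotypeCall:
        i = self._snp_index[snp_id]
        j = self._sample_index[sample_id]
        return GenotypeCall(
            snp_id, sample_id, str(self.allele1[i, j]), str(self.allele2[i, j]),
            float(self.scores[i, j]),
        )

    def calls_for_snp(self, snp_id: str) -> list[GenotypeCall]:
        return [self.call(snp_id, sample) for sample in self.samples]

    def snp_arrays(self, snp_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(allele1, allele2, scores) rows for one SNP, in sample order."""
        i = self._snp_index[snp_id]
        return self.allele1[i], self.allele2[i], self.scores[i]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame, one row per SNP x sample."""
        n, m = self.allele1.shape
        return pd.DataFrame(
            {
                "SNP Name": np.repeat(self.snps, m),
                "Sample ID": np.tile(self.samples, n),
                "Allele1": self.allele1.ravel(),
                "Allele2": self.allele2.ravel(),
                "GC Score": self.scores.ravel(),
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallMatrix):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.samples == other.samples
            and bool(np.array_equal(self.allele1, other.allele1))
            and bool(np.array_equal(self.allele2, other.allele2))
            and bool(np.allclose(self.scores, other.scores, rtol=0, atol=1e-12))
        )

    def __repr__(self) -> str:
        return f"CallMatrix({self.n_snps} SNPs x {self.n_samples} samples)"


@dataclass
class Genome:
    """A genome assembly as a mapping of scaffold id to uppercase sequence."""

    name: str
    sequences: dict[str, str]

    def __getitem__(self, scaffold: str) -> str:
        return self.sequences[scaffold]

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(v) for v in self.sequences.values())


@dataclass
class ScaffoldChromosomeMap:
    """Scaffold -> (chromosome label, evidence tag) synteny/cytogenetic map."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def chromosome_of(self, scaffold: str) -> Optional[tuple[str, str]]:
        return self.entries.get(scaffold)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Gene:
    """Gene interval, 0-based half-open internal coordinates."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"{self.gene_id}: end must exceed start")


@dataclass
class GeneSet:
    """All annotated genes, indexable by scaffold."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        self._by_scaffold: dict[str, list[Gene]] = {}
        for gene in self.genes:
            self._by_scaffold.setdefault(gene.scaffold, []).append(gene)

    def on_scaffold(self, scaffold: str) -> list[Gene]:
        return self._by_scaffold.get(scaffold, [])

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# genotype report
# ---------------------------------------------------------------------------


def _find_column(columns: Sequence[str], *needles: str) -> str:
    for needle in needles:
        for col in columns:
            if needle in col.lower().replace(" ", "").replace("_", ""):
                return col
    raise ParseError(f"no column matching {needles!r} among {list(columns)}")


def read_genotype_report(
    path: str | Path, manifest: Sequence[SnpManifestRecord]
) -> CallMatrix:
    """Read a long-format genotype report TSV into a complete :class:`CallMatrix`.

    Alleles are validated against the manifest allele pair, scores against
    [0, 1]; errors cite the 1-based file line.  SNP order in the matrix
    follows the manifest, samples are sorted, so the result is independent
    of row order in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    snp_col = _find_column(df.columns, "snpname", "snp")
    sample_col = _find_column(df.columns, "sampleid", "sample")
    a1_col = _find_column(df.columns, "allele1")
    a2_col = _find_column(df.columns, "allele2")
    score_col = _find_column(df.columns, "gcscore", "score")

    pairs = {rec.snp_id: {rec.allele_a, rec.allele_b} for rec in manifest}
    columns = list(df.columns)
    idx_of = {col: columns.index(col) for col in (snp_col, sample_col, a1_col, a2_col, score_col)}
    calls: list[GenotypeCall] = []
    for idx, row in enumerate(df.itertuples(index=False, name=None)):
        line_no = idx + 2  # header is line 1
        snp = row[idx_of[snp_col]]
        sample = row[idx_of[sample_col]]
        a1 = str(row[idx_of[a1_col]]).upper()
        a2 = str(row[idx_of[a2_col]]).upper()
        try:
            score = float(row[idx_of[score_col]])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"line {line_no}: unreadable score") from exc
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"line {line_no}: score {score} outside [0, 1]")
        if snp not in pairs:
            raise ValidationError(f"line {line_no}: SNP {snp!r} not in manifest")
        for allele in (a1, a2):
            if allele != NO_CALL and allele not in pairs[snp]:
                raise ValidationError(
                    f"line {line_no}: allele {allele!r} not in manifest pair for {snp}"
                )
        try:
            calls.append(GenotypeCall(snp, sample, a1, a2, score))
        except ValidationError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
    return CallMatrix.from_calls(calls, snp_order=[rec.snp_id for rec in manifest])


def write_genotype_report(matrix: CallMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# SNP manifest
# ---------------------------------------------------------------------------

_BRACKET_RE = re.compile(
    r"^(?P<left>[ACGTNacgtn]*)\[(?P<a>[ACGTacgt])/(?P<b>[ACGTacgt])\](?P<right>[ACGTNacgtn]*)$"
)


def parse_source_seq(source_seq: str) -> tuple[str, str, str, str]:
    """Split ``LEFT[X/Y]RIGHT`` into (flank_up, allele_a, allele_b, flank_down)."""
    match = _BRACKET_RE.match(source_seq.strip())
    if match is None:
        raise ParseError(f"malformed source sequence {source_seq!r}")
    left = match.group("left").upper()
    right = match.group("right").upper()
    if not left or not right:
        raise ParseError(f"source sequence {source_seq!r} has an empty flank (flanks required)")
    return left, match.group("a").upper(), match.group("b").upper(), right


def read_snp_manifest(path: str | Path) -> list[SnpManifestRecord]:
    """Read a manifest CSV; records are returned in file order.

    A flank shorter than 25 nt triggers a warning — the record stays but
    cannot anchor 26-mer flank queries.
    """
    df = pd.read_csv(path, dtype=str)
    snp_col = _find_column(df.columns, "snpid", "snpname", "snp")
    seq_col = _find_column(df.columns, "sourceseq", "sequence")
    gt_col = _find_column(df.columns, "gentrain")
    chrom_col = pos_col = None
    try:
        chrom_col = _find_column(df.columns, "chrom")
        pos_col = _find_column(df.columns, "pos")
    except ParseError:
        pass

    records: list[SnpManifestRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        try:
            left, a, b, right = parse_source_seq(row[seq_col])
        except ParseError as exc:
            raise ParseError(f"line {line_no}: {exc}") from exc
        gentrain = float(row[gt_col])
        chrom = row[chrom_col] if chrom_col and pd.notna(row[chrom_col]) else None
        pos = int(row[pos_col]) if pos_col and pd.notna(row[pos_col]) else None
        record = SnpManifestRecord(
            snp_id=str(row[snp_col]),
            allele_a=a,
            allele_b=b,
            flank_up=left,
            flank_down=right,
            gentrain=gentrain,
            source_chrom=chrom,
            source_pos=pos,
        )
        if min(len(left), len(right)) < MIN_FLANK_LEN:
            warnings.warn(
                f"{record.snp_id}: flank shorter than {MIN_FLANK_LEN} nt; "
                "ineligible for 26-mer flank queries",
                stacklevel=2,
            )
        records.append(record)
    return records


def write_snp_manifest(records: Sequence[SnpManifestRecord], path: str | Path) -> None:
    rows = [
        {
            "snp_id": rec.snp_id,
            "source_seq": rec.source_seq,
            "gentrain": f"{rec.gentrain:.6f}",
            "source_chrom": rec.source_chrom if rec.source_chrom is not None else "",
            "source_pos": rec.source_pos if rec.source_pos is not None else "",
        }
        for rec in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genome FASTA
# ---------------------------------------------------------------------------


def read_genome_fasta(path: str | Path, name: Optional[str] = None) -> Genome:
    """Read an assembly FASTA; duplicate scaffold ids and non-IUPAC characters are errors."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"duplicate scaffold id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _IUPAC_BASES
        if bad:
            raise ValidationError(
                f"scaffold {record.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    return Genome(name=name or Path(path).stem, sequences=sequences)


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=scaffold, description="")
        for scaffold, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# synteny map and gene annotation
# ---------------------------------------------------------------------------


def read_synteny_map(path: str | Path) -> ScaffoldChromosomeMap:
    """Read a scaffold/chromosome/evidence TSV; conflicting duplicate rows are errors."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    scaffold_col = _find_column(df.columns, "scaffold")
    chrom_col = _find_column(df.columns, "chromosome", "chrom")
    evidence_col = _find_column(df.columns, "evidence")
    entries: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        scaffold = row[scaffold_col]
        value = (row[chrom_col], row[evidence_col])
        existing = entries.get(scaffold)
        if existing is not None and existing[0] != value[0]:
            raise ValidationError(
                f"scaffold {scaffold!r} mapped to both {existing[0]} and {value[0]}"
            )
        entries.setdefault(scaffold, value)
    return ScaffoldChromosomeMap(entries)


def write_synteny_map(cmap: ScaffoldChromosomeMap, path: str | Path) -> None:
    rows = [
        {"scaffold": scaffold, "chromosome": chrom, "evidence": evidence}
        for scaffold, (chrom, evidence) in cmap.entries.items()
    ]
    pd.DataFrame(rows, columns=["scaffold", "chromosome", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_annotation(path: str | Path) -> GeneSet:
    """Read gene features from a GFF3 file into a :class:`GeneSet`.

    GFF3 coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention; a feature with end <= start is rejected.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes: list[Gene] = []
    for feature in db.features_of_type("gene", order_by=("seqid", "start")):
        if feature.end <= feature.start:
            raise ValidationError(
                f"gene {feature.id!r}: end ({feature.end}) <= start ({feature.start})"
            )
        genes.append(
            Gene(
                gene_id=feature.id,
                scaffold=feature.seqid,
                start=feature.start - 1,
                end=feature.end,
                strand=feature.strand if feature.strand in "+-" else "+",
            )
        )
    return GeneSet(genes)


def write_gene_annotation(geneset: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in geneset.genes:
            fh.write(
                "\t".join(
                    [
                        gene.scaffold,
                        "crosschip",
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={gene.gene_id}",
                    ]
                )
                + "\n"
            )
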