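"""Synthetic genotype reports, manifests, genome triples and annotations with
full ground truth, so every pipeline stage is testable without any download.

The generator emulates a 40-sample cross-species chip experiment in which most
assayed markers fail to convert: each simulated SNP is drawn from one of four
archetypes — clean polymorphic (tight, high quality-score clusters),
monomorphic (clean clusters but a single allele in the population), noisy
(broad score distribution, ambiguous clusters) and low-call (score mass below
the usual no-call cutoffs).  Quality scores are Beta-distributed within
archetype-specific bounds, chosen for [0, 1] support and easy analytic pass
probabilities; genotype values and scores are independent within archetype.

Each SNP additionally carries a flank fate governing how its 101-nt context is
planted into a pair of target assemblies and an outgroup: planted once in each
genome (unique), twice (duplicated), with a substitution inside the 21-mer
window (near-mutated, unmappable), with a substitution 26-50 nt away
(far-mutated: mappable but not conserved at 101 nt), not planted at all, or
additionally copied verbatim into the outgroup (conserved).  Background
sequence is i.i.d. uniform A/C/G/T, so at simulated sizes a 21-mer false
match is vanishingly unlikely and the planted truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import (
    CallMatrix,
    Gene,
    GeneSet,
    Genome,
    GenotypeCall,
    ScaffoldChromosomeMap,
    SnpManifestRecord,
)

__all__ = [
    "SnpArchetype",
    "ARCHETYPES",
    "DEFAULT_MIX",
    "SnpTruth",
    "SyntheticTruth",
    "ScaffoldPlan",
    "simulate_genotype_report",
    "simulate_genomes",
    "simulate_annotation",
]

_BASES = np.array(list("ACGT"))

ARCHETYPE_LABELS = ("clean_polymorphic", "monomorphic", "noisy_cluster", "low_call")

FATE_LABELS = (
    "unique_both",
    "duplicated",
    "near_mutated",
    "far_mutated",
    "absent",
    "conserved_in_outgroup",
)


@dataclass(frozen=True)
class SnpArchetype:
    """Generative description of one SNP class.

    ``score_beta`` are Beta(a, b) shape parameters; draws are affinely mapped
    into ``score_range``.  ``fate_weights`` gives the flank-fate distribution
    for SNPs of this archetype.
    """

    label: str
    score_beta: tuple[float, float]
    score_range: tuple[float, float]
    gentrain_range: tuple[float, float]
    vendor_nocall_rate: float
    fate_weights: Mapping[str, float]


#: Stated-world archetypes.  The noisy class is the only one whose scores can
#: stay below 0.7 *and* whose GenTrain range dips below 0.25; every SNP able
#: to reach average GC >= 0.7 therefore has GenTrain >= 0.25 by construction,
#: reproducing the observation that the GenTrain filter removes nothing once
#: the average-GC filter has been applied.
ARCHETYPES: dict[str, SnpArchetype] = {
    "clean_polymorphic": SnpArchetype(
        label="clean_polymorphic",
        score_beta=(6.0, 1.0),
        score_range=(0.4, 1.0),
        gentrain_range=(0.4, 0.95),
        vendor_nocall_rate=0.0,
        fate_weights={
            "unique_both": 0.55,
            "conserved_in_outgroup": 0.15,
            "duplicated": 0.10,
            "near_mutated": 0.10,
            "far_mutated": 0.05,
            "absent": 0.05,
        },
    ),
    "monomorphic": SnpArchetype(
        label="monomorphic",
        score_beta=(6.0, 1.0),
        score_range=(0.4, 1.0),
        gentrain_range=(0.4, 0.95),
        vendor_nocall_rate=0.0,
        # sequence-context fate is a property of the locus, not of whether the
        # site is polymorphic in the sample: same distribution as clean SNPs
        fate_weights={
            "unique_both": 0.55,
            "conserved_in_outgroup": 0.15,
            "duplicated": 0.10,
            "near_mutated": 0.10,
            "far_mutated": 0.05,
            "absent": 0.05,
        },
    ),
    "noisy_cluster": SnpArchetype(
        label="noisy_cluster",
        score_beta=(2.0, 2.0),
        score_range=(0.05, 0.68),
        gentrain_range=(0.05, 0.9),
        vendor_nocall_rate=0.05,
        fate_weights={"unique_both": 0.4, "absent": 0.6},
    ),
    "low_call": SnpArchetype(
        label="low_call",
        score_beta=(1.3, 4.0),
        score_range=(0.0, 1.0),
        gentrain_range=(0.25, 0.6),
        vendor_nocall_rate=0.1,
        fate_weights={"unique_both": 0.5, "absent": 0.5},
    ),
}

#: Default archetype mix, emulating the low conversion rate of cross-species
#: hybridization (a few percent of assayed SNPs yield clean polymorphic calls).
DEFAULT_MIX: dict[str, float] = {
    "clean_polymorphic": 0.05,
    "monomorphic": 0.45,
    "noisy_cluster": 0.30,
    "low_call": 0.20,
}


@dataclass
class SnpTruth:
    """Ground truth attached to one simulated SNP."""

    snp_id: str
    archetype: str
    true_maf: float
    genotypes: list[str]  # per sample: 'AA' | 'AB' | 'BB' | 'NC'
    flank_fate: str
    planted_base: Optional[str] = None
    planted_loci: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    expected_uniqueness: dict[str, str] = field(default_factory=dict)
    expected_conserved: Optional[bool] = None


@dataclass
class SyntheticTruth:
    """Ground truth for every SNP of a simulated dataset."""

    per_snp: dict[str, SnpTruth]

    def __getitem__(self, snp_id: str) -> SnpTruth:
        return self.per_snp[snp_id]

    def with_fate(self, fate: str) -> list[SnpTruth]:
        return [t for t in self.per_snp.values() if t.flank_fate == fate]

    def with_archetype(self, label: str) -> list[SnpTruth]:
        return [t for t in self.per_snp.values() if t.archetype == label]


def _random_flank(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _hw_counts(n: int, minor_copies: int) -> tuple[int, int, int]:
    """Deterministic genotype counts closest to Hardy-Weinberg for a planted
    number of minor-allele copies (allele B minor by convention)."""
    q = minor_copies / (2 * n)
    n_bb = min(int(round(n * q * q)), minor_copies // 2)
    n_ab = minor_copies - 2 * n_bb
    n_aa = n - n_bb - n_ab
    return n_aa, n_ab, n_bb


def simulate_genotype_report(
    n_snps: int,
    n_samples: int = 40,
    archetype_mix: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
    clean_true_maf: Optional[float] = None,
) -> tuple[CallMatrix, list[SnpManifestRecord], SyntheticTruth]:
    """Simulate a complete genotype report plus manifest and ground truth.

    Clean polymorphic SNPs carry an exact planted minor-allele count: when
    ``clean_true_maf`` is given the count is ``2 * n_samples * maf`` (e.g.
    0.0125 with 40 samples plants exactly one heterozygote), otherwise it is
    drawn uniformly on the k / (2n) grid, k = 1..n.  Genotype counts follow
    the nearest Hardy-Weinberg configuration; noisy and low-call SNPs draw
    per-sample genotypes from Hardy-Weinberg proportions instead.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    mix = dict(archetype_mix) if archetype_mix is not None else dict(DEFAULT_MIX)
    unknown = set(mix) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
    weights = np.array([mix.get(label, 0.0) for label in ARCHETYPE_LABELS], dtype=float)
    if weights.min() < 0 or not np.isclose(weights.sum(), 1.0):
        raise ValueError("archetype mix must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    samples = [f"ALP{i + 1:03d}" for i in range(n_samples)]
    calls: list[GenotypeCall] = []
    manifest: list[SnpManifestRecord] = []
    truth: dict[str, SnpTruth] = {}

    for i in range(n_snps):
        snp_id = f"SNP{i + 1:05d}"
        label = str(rng.choice(list(ARCHETYPE_LABELS), p=weights / weights.sum()))
        archetype = ARCHETYPES[label]

        allele_a, allele_b = rng.choice(_BASES, size=2, replace=False)
        record = SnpManifestRecord(
            snp_id=snp_id,
            allele_a=str(allele_a),
            allele_b=str(allele_b),
            flank_up=_random_flank(rng),
            flank_down=_random_flank(rng),
            # rounded to file precision so write-then-read is exact
            gentrain=round(float(rng.uniform(*archetype.gentrain_range)), 6),
        )
        manifest.append(record)

        # genotype vector
        if label == "clean_polymorphic":
            if clean_true_maf is not None:
                copies = int(round(clean_true_maf * 2 * n_samples))
                if copies < 1:
                    raise ValueError("clean_true_maf plants no minor allele copies")
            else:
                copies = int(rng.integers(1, n_samples + 1))
            true_maf = copies / (2 * n_samples)
            n_aa, n_ab, n_bb = _hw_counts(n_samples, copies)
            genotypes = ["AA"] * n_aa + ["AB"] * n_ab + ["BB"] * n_bb
            rng.shuffle(genotypes)
        elif label == "monomorphic":
            true_maf = 0.0
            genotypes = [str(rng.choice(["AA", "BB"]))] * n_samples
        else:
            q = float(rng.uniform(0.05, 0.5))
            true_maf = q
            p = 1.0 - q
            genotypes = list(
                rng.choice(["AA", "AB", "BB"], size=n_samples, p=[p * p, 2 * p * q, q * q])
            )

        # vendor no-calls
        if archetype.vendor_nocall_rate > 0:
            mask = rng.random(n_samples) < archetype.vendor_nocall_rate
            genotypes = ["NC" if m else g for g, m in zip(genotypes, mask)]

        # quality scores
        a, b = archetype.score_beta
        lo, hi = archetype.score_range
        scores = np.round(lo + (hi - lo) * rng.beta(a, b, size=n_samples), 6)

        genotype_alleles = {
            "AA": (record.allele_a, record.allele_a),
            "AB": (record.allele_a, record.allele_b),
            "BB": (record.allele_b, record.allele_b),
            "NC": ("-", "-"),
        }
        for sample, genotype, score in zip(samples, genotypes, scores):
            a1, a2 = genotype_alleles[genotype]
            calls.append(GenotypeCall(snp_id, sample, a1, a2, float(score)))

        fates = list(archetype.fate_weights)
        fate = str(rng.choice(fates, p=np.array([archetype.fate_weights[f] for f in fates])))
        truth[snp_id] = SnpTruth(
            snp_id=snp_id,
            archetype=label,
            true_maf=true_maf,
            genotypes=genotypes,
            flank_fate=fate,
        )

    matrix = CallMatrix.from_calls(calls, snp_order=[r.snp_id for r in manifest])
    return matrix, manifest, SyntheticTruth(truth)


@dataclass(frozen=True)
class ScaffoldPlan:
    """Layout of the simulated assemblies.

    Planting slots are laid out on a fixed grid (context length + spacing)
    so planted 101-nt contexts never overlap and always admit a full,
    untruncated window around the variant.
    """

    n_scaffolds: int = 8
    scaffold_length: int = 8000
    outgroup_scaffolds: int = 4
    within_scaffold_duplicate_fraction: float = 0.25
    context_flank: int = 50
    spacing: int = 20

    @property
    def context_length(self) -> int:
        return 2 * self.context_flank + 1

    def slots_per_scaffold(self) -> list[int]:
        step = self.context_length + self.spacing
        margin = 2  # keep planted windows clear of scaffold edges
        starts = list(range(margin, self.scaffold_length - self.context_length - margin, step))
        if not starts:
            raise ValueError("scaffold too short for the planting plan")
        return starts


class _SlotPool:
    """Non-overlapping planting slots for one genome, consumed at random."""

    def __init__(self, plan: ScaffoldPlan, n_scaffolds: int, prefix: str,
                 rng: np.random.Generator) -> None:
        self.free: dict[str, list[int]] = {}
        for k in range(n_scaffolds):
            starts = plan.slots_per_scaffold()
            rng.shuffle(starts)
            self.free[f"{prefix}{k + 1:02d}"] = starts
        self._rng = rng

    def take(self, scaffold: Optional[str] = None, min_free: int = 1) -> tuple[str, int]:
        if scaffold is None:
            candidates = [s for s, slots in self.free.items() if len(slots) >= min_free]
            if not candidates:
                raise ValueError("scaffold too short for the planting plan (slots exhausted)")
            scaffold = candidates[int(self._rng.integers(len(candidates)))]
        if not self.free.get(scaffold):
            raise ValueError("scaffold too short for the planting plan (slots exhausted)")
        return scaffold, self.free[scaffold].pop()


def _mutate(context: str, center: int, offset: int, rng: np.random.Generator) -> str:
    """Substitute one base at ``center + offset`` (sign chosen by caller)."""
    pos = center + offset
    old = context[pos]
    new = str(rng.choice([b for b in "ACGT" if b != old]))
    return context[:pos] + new + context[pos + 1 :]


def simulate_genomes(
    manifest: Sequence[SnpManifestRecord],
    truth: SyntheticTruth,
    plan: Optional[ScaffoldPlan] = None,
    seed: Optional[int] = None,
) -> tuple[Genome, Genome, Genome]:
    """Plant each SNP's 101-nt context into two target assemblies plus an
    outgroup, according to its flank fate, over i.i.d. random background.

    Fills ``planted_loci``, ``expected_uniqueness`` and ``expected_conserved``
    on the ground truth in place and returns (genomeA, genomeB, outgroup).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    plan = plan or ScaffoldPlan()
    rng = np.random.default_rng(seed)
    flank = plan.context_flank

    pools = {
        "genomeA": _SlotPool(plan, plan.n_scaffolds, "scafA_", rng),
        "genomeB": _SlotPool(plan, plan.n_scaffolds, "scafB_", rng),
        "outgroup": _SlotPool(plan, plan.outgroup_scaffolds, "scafO_", rng),
    }
    plantings: dict[str, list[tuple[str, int, str]]] = {g: [] for g in pools}
    planted_seqs: dict[str, list[tuple[str, int, str]]] = {g: [] for g in pools}

    from Bio.Seq import reverse_complement

    for record in manifest:
        t = truth[record.snp_id]
        fate = t.flank_fate
        if len(record.flank_up) < flank or len(record.flank_down) < flank:
            raise ValueError(f"{record.snp_id}: flanks too short for a {2 * flank + 1}-nt context")
        base = str(rng.choice([record.allele_a, record.allele_b]))
        t.planted_base = base
        pristine = record.flank_up[-flank:] + base + record.flank_down[:flank]

        if fate == "absent":
            for g in ("genomeA", "genomeB"):
                t.expected_uniqueness[g] = "absent"
            t.expected_conserved = False
            continue

        if fate == "near_mutated":
            side = int(rng.choice([-1, 1]))
            offset = side * int(rng.integers(1, 21))
            planted = _mutate(pristine, flank, offset, rng)
            expected_class = "absent"
            conserved = False
        elif fate == "far_mutated":
            side = int(rng.choice([-1, 1]))
            offset = side * int(rng.integers(26, flank + 1))
            planted = _mutate(pristine, flank, offset, rng)
            expected_class = "unique"
            conserved = False
        else:
            planted = pristine
            expected_class = "unique"
            conserved = fate == "conserved_in_outgroup"

        n_copies = 2 if fate == "duplicated" else 1
        same_scaffold = (
            fate == "duplicated"
            and rng.random() < plan.within_scaffold_duplicate_fraction
        )
        if fate == "duplicated":
            expected_class = "multi_within_scaffold" if same_scaffold else "multi_scaffold"

        for g in ("genomeA", "genomeB"):
            loci: list[tuple[str, int, str]] = []
            first_scaffold: Optional[str] = None
            for copy in range(n_copies):
                if same_scaffold and copy == 0:
                    scaffold, start = pools[g].take(min_free=2)
                elif same_scaffold:
                    scaffold, start = pools[g].take(scaffold=first_scaffold)
                elif fate == "duplicated" and copy == 1:
                    # force a different scaffold
                    candidates = [
                        s for s, slots in pools[g].free.items()
                        if slots and s != first_scaffold
                    ]
                    if not candidates:
                        raise ValueError("no second scaffold available for duplication")
                    scaffold = candidates[int(rng.integers(len(candidates)))]
                    scaffold, start = pools[g].take(scaffold=scaffold)
                else:
                    scaffold, start = pools[g].take()
                first_scaffold = first_scaffold or scaffold
                strand = str(rng.choice(["+", "-"]))
                seq = planted if strand == "+" else reverse_complement(planted)
                planted_seqs[g].append((scaffold, start, seq))
                loci.append((scaffold, start + flank, strand))
            t.planted_loci[g] = loci
            t.expected_uniqueness[g] = expected_class

        if fate in ("conserved_in_outgroup", "far_mutated"):
            scaffold, start = pools["outgroup"].take()
            strand = str(rng.choice(["+", "-"]))
            seq = pristine if strand == "+" else reverse_complement(pristine)
            planted_seqs["outgroup"].append((scaffold, start, seq))
            t.planted_loci["outgroup"] = [(scaffold, start + flank, strand)]
        t.expected_conserved = conserved

    genomes: dict[str, Genome] = {}
    for g, pool in pools.items():
        sequences: dict[str, str] = {}
        for scaffold in sorted(pool.free):
            arr = rng.integers(0, 4, size=plan.scaffold_length)
            chars = _BASES[arr]
            for scaf, start, seq in planted_seqs[g]:
                if scaf == scaffold:
                    chars[start : start + len(seq)] = list(seq)
            sequences[scaffold] = "".join(chars)
        genomes[g] = Genome(name=g, sequences=sequences)
    return genomes["genomeA"], genomes["genomeB"], genomes["outgroup"]


def simulate_annotation(
    genome: Genome,
    gene_density: float = 0.52,
    map_coverage: float = 0.73,
    seed: Optional[int] = None,
    chromosomes: Optional[Sequence[str]] = None,
) -> tuple[ScaffoldChromosomeMap, GeneSet]:
    """Random synteny map and gene annotation over one assembly.

    ``gene_density`` is the target fraction of scaffold bases covered by
    non-overlapping gene intervals; ``map_coverage`` the fraction of scaffolds
    that receive a chromosome label.  Labels follow the camelid convention
    VPA1..VPA36 plus VPAX.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if not 0.0 <= map_coverage <= 1.0:
        raise ValueError("map_coverage must be in [0, 1]")
    if not 0.0 < gene_density < 1.0:
        raise ValueError("gene_density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = list(chromosomes) if chromosomes else [f"VPA{i}" for i in range(1, 37)] + ["VPAX"]

    entries: dict[str, tuple[str, str]] = {}
    genes: list[Gene] = []
    gene_no = 0
    mean_len = 600.0
    mean_gap = max(1.0, mean_len * (1.0 - gene_density) / gene_density)
    for scaffold in sorted(genome.sequences):
        length = len(genome[scaffold])
        if rng.random() < map_coverage:
            entries[scaffold] = (
                str(rng.choice(labels)),
                str(rng.choice(["synteny", "cytogenetic"])),
            )
        pos = int(rng.integers(0, max(1, int(2 * mean_gap))))
        while True:
            glen = int(rng.integers(300, 901))
            if pos + glen > length:
                break
            gene_no += 1
            genes.append(
                Gene(
                    gene_id=f"GENE{gene_no:05d}",
                    scaffold=scaffold,
                    start=pos,
                    end=pos + glen,
                    strand=str(rng.choice(["+", "-"])),
                )
            )
            pos += glen + 1 + int(rng.integers(0, max(2, int(2 * mean_gap))))
    return ScaffoldChromosomeMap(entries), GeneSet(genes)
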