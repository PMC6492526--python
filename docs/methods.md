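# Methods

## Problem and model

A SNP chip designed for one species is hybridized against DNA of a related
species. Each assayed marker yields, per sample, a genotype call and a
quality score in [0, 1] (a distance-from-cluster-centre measure produced by
the genotyping software), plus one per-marker cluster-shape score (GenTrain).
Cross-species hybridization degrades both: most markers are monomorphic in
the target species, fail to hybridize, or produce diffuse clusters. The
package's job is to separate genuinely polymorphic, uniquely mappable markers
from that background, using only (i) score-based filters and (ii) exact
sequence anchoring of the probe flanks in target-species assemblies.

Scores are treated strictly as inputs; the package never recomputes them
from intensities (out of scope by design, as is the genotyping chemistry).

## Quality metrics and conventions

For a no-call threshold *t*, a genotype is a call iff it is not a vendor
no-call and its score ≥ *t* (scores *less than* the threshold are dropped —
boundary scores survive). All downstream per-SNP statistics are computed on
the called genotypes under the active threshold, including MAF and HWE; the
alternative (MAF on pre-threshold calls) is defensible but less consistent
with "across all called genotypes", and is not offered.

- **Percentiles** (10%GC, 50%GC) use linear interpolation between closest
  order statistics at rank p·(n−1) — the "type-7" rule, numpy's default. The
  genotyping software's exact rule is undocumented; type-7 is declared once
  and used identically by the implementation (numpy) and the test oracle
  (hand-written order-statistic formula), so the choice is visible and
  checkable.
- **Call frequency = 1** is the integer condition `n_nocall == 0`. The
  ≥ 0.9 rule and the MAF cutoffs compare exact rationals
  (`Fraction(n_called, n) ≥ 9/10`), never float equality.
- **HWE** is a plain 1-df χ² of observed genotype counts against p², 2pq, q²
  from the sample allele frequencies, no continuity correction, α = 0.05.
  Monomorphic markers are *not applicable*, never "failed". An exact test
  would be preferable at these sample sizes for very rare alleles; χ² is kept
  as the simplest method consistent with spreadsheet-style practice in this
  literature, and equilibrium flags are reported, never used as a filter.

## Filter cascade

Seven method configurations combine threshold ∈ {0.05, 0.15, 0.25} with call
frequency (≥ 0.9 or = 1); average GC ≥ 0.7 and GenTrain ≥ 0.25 apply to all,
except that method VII drops the average-GC stage. Stages run in the order
call-frequency → average GC → GenTrain → MAF ≥ 0.01 → MAF ≥ 0.05. The
filters are conjunctive, so the final set is order-independent; the order
only shapes the intermediate counts in the audit table. `apply_method`
refuses a metrics table computed at a different threshold than the method's
own — a cheap guard against a silent class of wrong-count bugs.

## Flank anchoring

Hybridization tolerates probe/target mismatches far from the variant but not
adjacent to it, so anchoring uses short perfect matches only: for lengths
21 and 26 and each allele X, the upstream query is the last L−1 flank
nucleotides + X (variant at the 3′ end), and the downstream query is the
reverse complement of X + the first L−1 downstream nucleotides (i.e. the same
structure read on the negative strand). Because only perfect matches of fixed
short length count, exact substring search is equivalent to short-read BLAST
restricted to 100%-identity full-length hits, and is used instead —
deliberately, as a dependency-free substitution.

Conventions, where the underlying procedure is underdetermined:

- A locus requires an upstream and a downstream hit implying the *same*
  (scaffold, variant coordinate, strand) — the only reading that
  reconstructs a single variant site.
- Minimum evidence is the co-located 21-mer pair; 26-mer support is recorded
  in `supported_lengths`. Requiring 26 instead is strictly stricter and
  available via `required_length=26`.
- Either allele may anchor a locus (assemblies are haploid); matched alleles
  are recorded.
- Matching is case-insensitive; `N` (in genome or flank) never matches.
- Uniqueness: exactly one locus. Multiple loci on one scaffold are
  `multi_within_scaffold` and are just as disqualifying as `multi_scaffold`.
- The 101-nt context is extracted from the first assembly, reverse-
  complemented for negative-strand loci; variants within 50 nt of a scaffold
  edge yield truncated, flagged contexts that are excluded from conservation
  checks. Conservation means the full 101-mer (either strand, either allele
  at the centre) occurs at least once in the outgroup assembly.

## Annotation

Chromosome labels come from an external scaffold→chromosome table (synteny
or cytogenetic evidence); scaffolds outside the table are "unassigned", and
assigned + unassigned always equals the retained total. Nearest-gene distance
is measured from the variant base to the closest edge of the gene's full
span, strand-agnostic, ties broken by smaller start then gene id; no maximum
distance is imposed. Two SNPs may share one nearest gene.

## Derived statistics

Percentages are rounded half-away-from-zero (1 dp by default), the convention
that reproduces the published derived values from their integer counts.
The expected polymorphic fraction after divergence comes from an external
exponential-decay model whose formula is not reimplemented; it enters as a
configuration constant. Both the observed fraction (n/total) and that
expectation are kept on the same raw-fraction scale (the source literature
attaches a spurious percent sign to both), which is what makes the
observed/expected ratio meaningful — on that scale a validated set of 400 of
777,962 assayed SNPs sits at ratio ≈ 1.0 of the decay expectation.

## The synthetic world

The generator emulates a 40-sample cross-species chip experiment
(`n_samples=40`; four archetypes mixed 5% clean polymorphic, 45% monomorphic,
30% noisy, 20% low-call by default, reflecting the few-percent conversion
rate such experiments report). Scores are Beta draws scaled into archetype-
specific ranges:

| archetype | Beta(a, b) | range | GenTrain | vendor no-call |
|---|---|---|---|---|
| clean polymorphic | (6, 1) | [0.4, 1] | [0.4, 0.95] | 0 |
| monomorphic | (6, 1) | [0.4, 1] | [0.4, 0.95] | 0 |
| noisy cluster | (2, 2) | [0.05, 0.68] | [0.05, 0.9] | 0.05 |
| low-call | (1.3, 4) | [0, 1] | [0.25, 0.6] | 0.10 |

Two couplings are structural, not statistical: the noisy range is capped
below 0.7 so noisy SNPs can never reach average GC ≥ 0.7 under any
threshold, and noisy is the only archetype whose GenTrain range dips below
0.25 — so every SNP that can pass the average-GC stage has GenTrain ≥ 0.25
by construction, reproducing the observation that the GenTrain cutoff is
redundant once average GC has been applied. Clean-SNP minor-allele counts
are planted exactly on the k/(2·40) grid (k = 1..40, so the floor is the
single-heterozygote MAF of 0.0125) in the nearest Hardy–Weinberg
configuration; noisy/low-call genotypes are per-sample Hardy–Weinberg draws.
Scores and genotypes are independent within archetype — no intensity model.

Flank fates (unique in both assemblies 55%, conserved-in-outgroup 15%,
duplicated 10%, near-mutated 10%, far-mutated 5%, absent 5% for clean and
monomorphic SNPs — context fate is a property of the locus, not of
polymorphism status; noisy and low-call SNPs are mostly absent or unique)
drive the planting of each 101-nt context into i.i.d. uniform background
sequence on a non-overlapping slot grid. A near mutation (≤ 20 nt from the
variant) breaks both query lengths on one side, so the SNP becomes
unmappable; a far mutation (26–50 nt away) leaves both queries intact but
breaks 101-nt conservation against the pristine outgroup copy. Background
false matches of a 21-mer have probability ≈ L·4⁻²¹ per query at the
simulated sizes (≤ a few hundred kb), so the planted truth is exact for all
practical purposes, and the recovery tests assert it exactly.

What a green synthetic run does **not** establish: the generator has no
linkage disequilibrium, population structure, batch effects or
intensity-space cluster geometry, and its archetypes separate more cleanly
than real cross-species data (real datasets have borderline SNPs that make
the seven methods disagree more richly). Green tests certify the *logic* —
metric definitions, cascade semantics, anchoring coordinates, bookkeeping —
not any field-realistic discovery rate.

## Numerical and degenerate-input choices

- Zero called genotypes: average GC and MAF are undefined (`None`); such a
  SNP auto-fails average-GC and MAF stages but never aborts a batch.
- Report/manifest writers emit 6-decimal scores; the generator draws scores
  already rounded to 6 dp, so write-then-read round-trips are bit-exact and
  pipeline reruns are byte-identical.
- All internal coordinates are 0-based half-open; GFF3 I/O converts at the
  boundary (1-based inclusive on file). BED output is 0-based half-open with
  the variant as a 1-bp interval.
- Manifest flanks shorter than 25 nt trigger a warning and silently lack the
  26-mer queries; shorter than 20 nt, the 21-mer queries too, making the SNP
  unmappable (which is reported as `absent`, the honest answer).

## Known limitations

- The χ² HWE test is anti-conservative for very rare alleles at n = 40.
- Exact matching cannot model the partial-mismatch hybridization the probe
  chemistry actually tolerates beyond the 21/26-nt perfect core; markers
  mappable only with mismatches inside that core are lost by construction.
- The uniqueness rule treats a two-copy perfect repeat as non-unique even if
  only one copy carries the variant context in reality; with scaffold-level
  assemblies there is no way to distinguish these cases.
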