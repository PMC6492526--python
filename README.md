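# crosschip

Cross-species SNP discovery from a genotyping array: quality-filter the
genotype calls a commercial SNP chip produces in a *non-target* species,
validate the surviving markers by perfect-match flank alignment against
genome assemblies of that species, and report how many genuinely polymorphic,
uniquely mappable SNPs the experiment delivered.

The motivating setting is livestock genomics for species without their own
chip — e.g. genotyping alpacas (*Vicugna pacos*) on a high-density bovine
BeadChip despite ~42.7 Myr of divergence. Most probes fail to hybridize
cleanly across species, so everything hinges on (a) principled filtering of
per-genotype quality scores and (b) sequence-level validation that a "positive"
SNP actually maps to exactly one place in the target genome.

## What it computes

**Per-SNP quality metrics** (module `crosschip.qc`), under a configurable
no-call threshold *t* (a genotype is a call iff its GenCall-style score ≥ *t*):

- call frequency = calls / (calls + no-calls)
- 10%GC and 50%GC — the 10th/50th percentiles of scores across called
  genotypes — and average GC = (10%GC + 50%GC)/2
- genotype counts (n_AA, n_AB, n_BB), minor allele frequency
  MAF = min(2·n_AA + n_AB, 2·n_BB + n_AB)/(2·n_called)
- 1-df χ² test of Hardy–Weinberg equilibrium against p², 2pq, q²

**Seven filter methods** (`crosschip.filters`) combining no-call threshold
∈ {0.05, 0.15, 0.25}, call frequency (≥ 0.9 or exactly 1), average GC ≥ 0.7
(disabled in method VII) and GenTrain ≥ 0.25, with MAF retention at ≥ 0.01 and
≥ 0.05, applied as a nested cascade with per-stage survivor counts.

**Flank validation** (`crosschip.flanks`): for each SNP, eight allele-
terminated queries (last 20/25 nt of the upstream flank + allele; reverse
complement of allele + first 20/25 nt of the downstream flank) are exact-
matched against two assemblies. A locus exists where an upstream and a
downstream query imply the same (scaffold, position, strand); a SNP is kept
when it is *unique* in both assemblies. For kept SNPs the 101-nt variant-
centred context is extracted and checked for perfect conservation in an
outgroup genome.

**Annotation and reporting** (`crosschip.annotate`, `crosschip.report`):
scaffold→chromosome assignment through a synteny/cytogenetic map, nearest
annotated gene per variant, and the derived statistics (percent of assayed
SNPs per stage, stage reductions, observed vs expected polymorphism fraction
under an exponential divergence-decay expectation).

**Synthetic data** (`crosschip.simulate`): ground-truthed generators for the
genotype report (four SNP archetypes: clean polymorphic, monomorphic, noisy,
low-call, each with its own Beta score distribution), the genome triple with
planted probe contexts (unique / duplicated / near-mutated / far-mutated /
absent / conserved-in-outgroup fates), and the synteny map + GFF3 annotation.

## Worked example

```python
from crosschip import simulate_inputs, run_pipeline

config, truth = simulate_inputs("scratch/demo", seed=13, n_snps=500)
summary = run_pipeline(config)
```

prints (via `results/pipeline.log`):

```
[input] 500 SNPs x 40 samples
[filter] method VI: call_frequency=248, avg_gc=248, gentrain=248, maf_ge_0.01=23, maf_ge_0.05=22
[select] method VI maf_ge_0.01: 23 SNPs
[flankmap] genomeA: 15 unique of 23 searched
[flankmap] genomeB: 15 unique of 23 searched
[intersect] 15 SNPs unique in both assemblies
[conserve] 4 of 15 conserved
[hwe] 0 retained SNPs out of Hardy-Weinberg equilibrium
[assign] 7 of 15 assigned to chromosomes
[annotate] 5 retained SNPs within annotated genes
```

Reading it: of 500 assayed SNPs, 248 survive the strictest quality filters
(threshold 0.25, call frequency = 1, average GC ≥ 0.7) but only 23 are
polymorphic at MAF ≥ 0.01. Flank validation anchors 15 of those uniquely in
*both* assemblies — the validated SNP set. Seven sit on scaffolds with a
chromosome label, five inside annotated genes, four have a perfectly conserved
101-nt context in the outgroup, and none deviate from Hardy–Weinberg.

The `examples/` directory holds one narrative script per capability
(`simulate_dataset.py`, `qc_and_filter_methods.py`, `flank_mapping.py`,
`reporting_arithmetic.py`, `end_to_end_pipeline.py`); each builds or loads a
small input, runs the method and explains the numbers it prints.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a complete synthetic input set from the seed, executes the full
pipeline on it (the summary is written beside the output as
`pipeline_summary.json`), and writes the results JSON.

See `docs/methods.md` for the model, its assumptions, the generator's stated
world and the package's numerical conventions.
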