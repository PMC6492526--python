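"""Generate a fully synthetic cross-species genotyping dataset.

Writes a 500-SNP x 40-sample genotype report, the matching SNP manifest, two
target assemblies plus an outgroup with every probe context planted according
to its fate, a scaffold->chromosome synteny map and a GFF3 gene annotation —
then prints the archetype and fate composition, which is the ground truth the
rest of the pipeline can be scored against.
"""

from collections import Counter
from pathlib import Path

from crosschip import simulate_inputs

out = Path("scratch/example_dataset")
config, truth = simulate_inputs(out, seed=13, n_snps=500)

archetypes = Counter(t.archetype for t in truth.per_snp.values())
fates = Counter(t.flank_fate for t in truth.per_snp.values())

print(f"wrote inputs under {out}/")
print("archetype composition (how each SNP's genotype clusters behave):")
for label, n in archetypes.most_common():
    print(f"  {label:18s} {n:4d}")
print("flank fates (how each probe context was planted into the assemblies):")
for label, n in fates.most_common():
    print(f"  {label:22s} {n:4d}")
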