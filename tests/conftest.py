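"""Shared fixtures: a hand-built micro dataset and a session-scoped simulated
cohort (500 SNPs x 40 samples, seed 13) with planted genomes."""

from __future__ import annotations

import pytest

from crosschip import (
    CallMatrix,
    GenotypeCall,
    SnpManifestRecord,
    simulate_genomes,
    simulate_genotype_report,
)

SIM_SEED = 13
SIM_N_SNPS = 500


@pytest.fixture()
def tiny_manifest() -> list[SnpManifestRecord]:
    return [
        SnpManifestRecord(
            snp_id="rs1",
            allele_a="A",
            allele_b="G",
            flank_up="ACGTACGTACGTACGTACGTACGTA",
            flank_down="GGGGGCCCCCAAAAATTTTTGGGGG",
            gentrain=0.8,
        ),
        SnpManifestRecord(
            snp_id="rs2",
            allele_a="C",
            allele_b="T",
            flank_up="TTTTTTTTTTTTTTTTTTTTTTTTT",
            flank_down="AAAAAAAAAAAAAAAAAAAAAAAAA",
            gentrain=0.5,
        ),
    ]


@pytest.fixture()
def tiny_matrix(tiny_manifest) -> CallMatrix:
    calls = [
        GenotypeCall("rs1", "s1", "A", "A", 0.9),
        GenotypeCall("rs1", "s2", "A", "G", 0.8),
        GenotypeCall("rs2", "s1", "C", "T", 0.7),
        GenotypeCall("rs2", "s2", "-", "-", 0.1),
    ]
    return CallMatrix.from_calls(calls, snp_order=[r.snp_id for r in tiny_manifest])


@pytest.fixture(scope="session")
def sim500():
    """(matrix, manifest, truth) for the standard simulated cohort."""
    return simulate_genotype_report(SIM_N_SNPS, n_samples=40, seed=SIM_SEED)


@pytest.fixture(scope="session")
def sim500_genomes(sim500):
    """(genomeA, genomeB, outgroup) with every SNP's context planted per fate.

    Planting mutates the shared truth in place, so downstream fixtures see the
    planted loci and expected classes.
    """
    _, manifest, truth = sim500
    return simulate_genomes(manifest, truth, seed=SIM_SEED + 1)
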