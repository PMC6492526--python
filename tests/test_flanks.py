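"""Flank-query construction, exact search, locus consolidation, uniqueness,
intersection, context extraction and conservation — largely against planted
ground truth."""

from __future__ import annotations

import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from crosschip import (
    Genome,
    SnpManifestRecord,
    build_flank_queries,
    classify_uniqueness,
    conservation_check,
    extract_context,
    intersect_genomes,
    locate_snp,
    search_exact,
)
from crosschip.flanks import SnpContext, SnpLocus, UniquenessCall
from ._oracles import naive_search

UP = "ACGTACGTACGTACGTACGTACGTA"  # 25 nt
DOWN = "GGGGGCCCCCAAAAATTTTTGGGGG"  # 25 nt


@pytest.fixture()
def record():
    return SnpManifestRecord(
        snp_id="rs1", allele_a="A", allele_b="G",
        flank_up=UP, flank_down=DOWN, gentrain=0.9,
    )


class TestBuildFlankQueries:
    def test_upstream_query_by_hand(self, record):
        queries = build_flank_queries(record, lengths=(21,))
        up_a = next(q for q in queries if q.side == "upstream" and q.allele_label == "A")
        assert up_a.sequence == "CGTACGTACGTACGTACGTAA"

    def test_downstream_query_by_hand(self, record):
        queries = build_flank_queries(record, lengths=(21,))
        down_a = next(q for q in queries if q.side == "downstream" and q.allele_label == "A")
        # reverse complement of allele + first 20 nt of the downstream flank
        assert down_a.sequence == "AAAAATTTTTGGGGGCCCCCT"

    def test_eight_queries_terminated_by_allele(self, record):
        queries = build_flank_queries(record)
        assert len(queries) == 8
        for q in queries:
            assert len(q.sequence) == q.length
            if q.side == "upstream":
                assert q.sequence[-1] == q.allele
            else:
                assert q.sequence[-1] == reverse_complement(q.allele)

    def test_short_flank_omits_that_side_and_length(self):
        record = SnpManifestRecord(
            snp_id="rs1", allele_a="A", allele_b="G",
            flank_up=UP, flank_down=DOWN[:22], gentrain=0.9,
        )
        queries = build_flank_queries(record)
        # downstream 26-mers need 25 nt of flank; only 22 available
        assert not any(q.side == "downstream" and q.length == 26 for q in queries)
        assert sum(q.side == "downstream" for q in queries) == 2


def _plant(background: str, insert: str, at: int) -> str:
    return background[:at] + insert + background[at + len(insert):]


class TestSearchExact:
    def test_planted_query_found_once(self):
        import numpy as np
        rng = np.random.default_rng(21)
        background = "".join(rng.choice(list("ACGT"), size=10_000))
        query = "".join(rng.choice(list("ACGT"), size=21))
        genome = Genome("g", {"s1": _plant(background, query, 4000)})
        hits = search_exact(genome, query)
        assert hits == [("s1", 4000 + len(query) - 1, "+")]

    def test_forward_and_reverse_planted(self):
        import numpy as np
        rng = np.random.default_rng(22)
        query = "".join(rng.choice(list("ACGT"), size=21))
        s1 = _plant("".join(rng.choice(list("ACGT"), 2000)), query, 500)
        s2 = _plant("".join(rng.choice(list("ACGT"), 2000)), reverse_complement(query), 700)
        genome = Genome("g", {"s1": s1, "s2": s2})
        hits = sorted(search_exact(genome, query))
        assert hits == [("s1", 500 + 20, "+"), ("s2", 700, "-")]

    def test_absent_query_yields_empty(self):
        genome = Genome("g", {"s1": "ACGT" * 100})
        assert search_exact(genome, "TTTTTTTTTTTTTTTTTTTTT") == []

    def test_n_in_genome_never_matches(self):
        genome = Genome("g", {"s1": "AAAANAAAA"})
        assert search_exact(genome, "AAAAA") == []

    def test_non_acgt_query_rejected(self):
        genome = Genome("g", {"s1": "ACGT"})
        with pytest.raises(ValueError):
            search_exact(genome, "AANAA")

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_equivalence_with_naive_scan(self, data):
        bases = st.sampled_from("ACGT")
        genome_seq = data.draw(st.text(bases, min_size=50, max_size=400))
        query = data.draw(st.text(bases, min_size=4, max_size=8))
        genome = Genome("g", {"s1": genome_seq})
        assert sorted(search_exact(genome, query)) == sorted(
            naive_search(genome, query, reverse_complement)
        )


def _genome_with_context(record, base="A", strand="+", scaffold="s1", at=300,
                         mutate_offset=None, seed=33, length=1000):
    """A random genome with the record's 101-nt context planted once."""
    import numpy as np
    rng = np.random.default_rng(seed)
    context = record.flank_up + base + record.flank_down
    if mutate_offset is not None:
        center = len(record.flank_up)
        pos = center + mutate_offset
        old = context[pos]
        new = "A" if old != "A" else "C"
        context = context[:pos] + new + context[pos + 1:]
    if strand == "-":
        context = reverse_complement(context)
    background = "".join(rng.choice(list("ACGT"), size=length))
    variant_pos = at + len(record.flank_up) if strand == "+" else at + len(record.flank_down)
    return Genome("g", {scaffold: _plant(background, context, at)}), variant_pos


class TestLocateSnp:
    def test_intact_context_gives_both_lengths(self, record):
        genome, variant_pos = _genome_with_context(record)
        queries = build_flank_queries(record)
        (locus,) = locate_snp({"g": genome}, queries)["g"]
        assert (locus.scaffold, locus.variant_pos, locus.strand) == ("s1", variant_pos, "+")
        assert locus.supported_lengths == frozenset({21, 26})
        assert locus.matched_alleles == frozenset({"A"})

    def test_minus_strand_context_recovered(self, record):
        genome, variant_pos = _genome_with_context(record, strand="-")
        queries = build_flank_queries(record)
        (locus,) = locate_snp({"g": genome}, queries)["g"]
        assert (locus.variant_pos, locus.strand) == (variant_pos, "-")
        assert locus.supported_lengths == frozenset({21, 26})

    def test_mutation_inside_21mer_window_kills_locus(self, record):
        genome, _ = _genome_with_context(record, mutate_offset=10)
        assert locate_snp({"g": genome}, build_flank_queries(record))["g"] == []

    def test_mutation_between_windows_supports_21_only(self, record):
        genome, variant_pos = _genome_with_context(record, mutate_offset=23)
        (locus,) = locate_snp({"g": genome}, build_flank_queries(record))["g"]
        assert locus.supported_lengths == frozenset({21})
        assert locus.variant_pos == variant_pos

    def test_requiring_26_is_strictly_stricter(self, record):
        genome, _ = _genome_with_context(record, mutate_offset=23)
        queries = build_flank_queries(record)
        assert locate_snp({"g": genome}, queries, required_length=26)["g"] == []

    def test_26mer_support_implies_21mer_support(self, sim500, sim500_genomes):
        _, manifest, truth = sim500
        genome_a, _, _ = sim500_genomes
        checked = 0
        for record in manifest[:80]:
            loci = locate_snp(
                {"genomeA": genome_a}, build_flank_queries(record)
            )["genomeA"]
            for locus in loci:
                if 26 in locus.supported_lengths:
                    assert 21 in locus.supported_lengths
                    checked += 1
        assert checked > 0

    def test_strand_symmetry(self, record):
        genome, variant_pos = _genome_with_context(record)
        mirrored = Genome("g", {
            scaffold: reverse_complement(seq) for scaffold, seq in genome.sequences.items()
        })
        queries = build_flank_queries(record)
        (locus,) = locate_snp({"g": genome}, queries)["g"]
        (mirror,) = locate_snp({"g": mirrored}, queries)["g"]
        length = len(genome["s1"])
        assert mirror.variant_pos == length - 1 - locus.variant_pos
        assert mirror.strand != locus.strand
        assert mirror.supported_lengths == locus.supported_lengths


class TestUniquenessAndIntersection:
    def _locus(self, scaffold="s1", pos=100):
        return SnpLocus("rs1", "g", scaffold, pos, "+", frozenset({21}), frozenset({"A"}))

    def test_single_locus_is_unique(self):
        call = classify_uniqueness("rs1", "g", [self._locus()])
        assert call.classification == "unique" and call.is_unique

    def test_two_scaffolds_is_multi_scaffold(self):
        call = classify_uniqueness(
            "rs1", "g", [self._locus("s1"), self._locus("s2")]
        )
        assert call.classification == "multi_scaffold"

    def test_repeat_within_scaffold_is_still_non_unique(self):
        call = classify_uniqueness(
            "rs1", "g", [self._locus("s1", 100), self._locus("s1", 900)]
        )
        assert call.classification == "multi_within_scaffold"
        assert not call.is_unique

    def test_no_locus_is_absent(self):
        assert classify_uniqueness("rs1", "g", []).classification == "absent"

    def test_intersection_requires_unique_in_both(self):
        unique = classify_uniqueness("rs1", "a", [self._locus()])
        multi = classify_uniqueness("rs2", "a", [self._locus("s1"), self._locus("s2")])
        unique_b = classify_uniqueness("rs1", "b", [self._locus()])
        unique2_b = classify_uniqueness("rs2", "b", [self._locus()])
        retained = intersect_genomes(
            {"rs1": unique, "rs2": multi}, {"rs1": unique_b, "rs2": unique2_b}
        )
        assert retained == {"rs1"}


class TestContextAndConservation:
    def test_window_coordinates(self):
        seq = "".join("ACGT"[(i // 1) % 4] for i in range(200))
        genome = Genome("g", {"s1": seq})
        locus = SnpLocus("rs1", "g", "s1", 60, "+", frozenset({21}), frozenset({"A"}))
        context = extract_context(genome, locus)
        assert context.sequence == seq[10:111]
        assert len(context.sequence) == 101 and context.center_index == 50
        assert not context.truncated

    def test_near_edge_is_truncated_and_flagged(self):
        genome = Genome("g", {"s1": "ACGT" * 50})
        locus = SnpLocus("rs1", "g", "s1", 10, "+", frozenset({21}), frozenset({"A"}))
        context = extract_context(genome, locus)
        assert context.truncated
        assert context.sequence == genome["s1"][:61]
        assert context.center_index == 10

    def test_minus_strand_is_revcomp_of_plus_window(self):
        import numpy as np
        rng = np.random.default_rng(44)
        seq = "".join(rng.choice(list("ACGT"), 300))
        genome = Genome("g", {"s1": seq})
        plus = SnpLocus("rs1", "g", "s1", 150, "+", frozenset({21}), frozenset({"A"}))
        minus = SnpLocus("rs1", "g", "s1", 150, "-", frozenset({21}), frozenset({"A"}))
        assert extract_context(genome, minus).sequence == reverse_complement(
            extract_context(genome, plus).sequence
        )
        assert extract_context(genome, minus).center_index == 50

    def test_verbatim_copy_is_conserved(self):
        import numpy as np
        rng = np.random.default_rng(45)
        context_seq = "".join(rng.choice(list("ACGT"), 101))
        context = SnpContext("rs1", context_seq, 50, False)
        outgroup = Genome("o", {"s1": _plant("".join(rng.choice(list("ACGT"), 1000)), context_seq, 300)})
        assert conservation_check(context, outgroup)

    def test_other_allele_at_center_still_conserved(self):
        import numpy as np
        rng = np.random.default_rng(46)
        context_seq = "".join(rng.choice(list("ACGT"), 101))
        swapped = context_seq[:50] + ("A" if context_seq[50] != "A" else "C") + context_seq[51:]
        outgroup = Genome("o", {"s1": _plant("".join(rng.choice(list("ACGT"), 1000)), swapped, 300)})
        context = SnpContext("rs1", context_seq, 50, False)
        assert conservation_check(context, outgroup, alleles=("A", "C"))

    def test_single_substitution_breaks_conservation(self):
        import numpy as np
        rng = np.random.default_rng(47)
        context_seq = "".join(rng.choice(list("ACGT"), 101))
        mutated = context_seq[:30] + ("A" if context_seq[30] != "A" else "C") + context_seq[31:]
        outgroup = Genome("o", {"s1": _plant("".join(rng.choice(list("ACGT"), 1000)), mutated, 300)})
        context = SnpContext("rs1", context_seq, 50, False)
        assert not conservation_check(context, outgroup)

    def test_absent_context_not_conserved(self):
        context = SnpContext("rs1", "ACGT" * 25 + "A", 50, False)
        assert not conservation_check(context, Genome("o", {"s1": "TTTT" * 300}))


@pytest.fixture(scope="module")
def recovered(sim500, sim500_genomes):
    _, manifest, truth = sim500
    genome_a, genome_b, outgroup = sim500_genomes
    genomes = {"genomeA": genome_a, "genomeB": genome_b}
    calls = {g: {} for g in genomes}
    for record in manifest:
        located = locate_snp(genomes, build_flank_queries(record))
        for g, loci in located.items():
            calls[g][record.snp_id] = classify_uniqueness(record.snp_id, g, loci)
    return manifest, truth, calls, genome_a, outgroup


class TestPlantedTruthRecovery:
    def test_uniqueness_classes_match_planted_fates(self, recovered):
        manifest, truth, calls, _, _ = recovered
        for record in manifest:
            t = truth[record.snp_id]
            for g in ("genomeA", "genomeB"):
                assert calls[g][record.snp_id].classification == t.expected_uniqueness[g], (
                    f"{record.snp_id} ({t.flank_fate}) in {g}"
                )

    def test_retained_set_equals_planted_intersection(self, recovered):
        manifest, truth, calls, _, _ = recovered
        retained = intersect_genomes(calls["genomeA"], calls["genomeB"])
        expected = {
            t.snp_id
            for t in truth.per_snp.values()
            if t.expected_uniqueness.get("genomeA") == "unique"
            and t.expected_uniqueness.get("genomeB") == "unique"
        }
        assert retained == expected

    def test_located_coordinates_match_planting(self, recovered):
        manifest, truth, calls, _, _ = recovered
        for record in manifest:
            t = truth[record.snp_id]
            if t.expected_uniqueness.get("genomeA") != "unique":
                continue
            (locus,) = calls["genomeA"][record.snp_id].loci
            (planted,) = t.planted_loci["genomeA"]
            assert (locus.scaffold, locus.variant_pos, locus.strand) == planted

    def test_far_mutated_found_full_length_but_not_conserved(self, recovered):
        manifest, truth, calls, genome_a, outgroup = recovered
        by_id = {r.snp_id: r for r in manifest}
        n_checked = 0
        for t in truth.with_fate("far_mutated"):
            call = calls["genomeA"][t.snp_id]
            assert call.is_unique
            (locus,) = call.loci
            assert locus.supported_lengths == frozenset({21, 26})
            context = extract_context(genome_a, locus)
            assert not conservation_check(
                context, outgroup, alleles=by_id[t.snp_id].alleles
            )
            n_checked += 1
        assert n_checked > 0

    def test_conserved_fate_confirmed_in_outgroup(self, recovered):
        manifest, truth, calls, genome_a, outgroup = recovered
        by_id = {r.snp_id: r for r in manifest}
        n_checked = 0
        for t in truth.with_fate("conserved_in_outgroup"):
            (locus,) = calls["genomeA"][t.snp_id].loci
            context = extract_context(genome_a, locus)
            assert conservation_check(context, outgroup, alleles=by_id[t.snp_id].alleles)
            n_checked += 1
        assert n_checked > 0
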