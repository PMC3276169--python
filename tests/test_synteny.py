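import random

import pytest

from eremosyn.genome_model import OrthologMap
from eremosyn.synteny import (
    SyntenyAnchor,
    assign_centromeric_chromosome_ids,
    block_statistics,
    build_anchors,
    chain_blocks,
    compare_locus_neighborhood,
    summarize_block_counts,
)

from conftest import identity_map, toy_genome


def make_anchor(i_a, i_b, chrom_a="A1", chrom_b="B1", orientation="same"):
    return SyntenyAnchor(
        gene_a=f"a{i_a}", gene_b=f"b{i_b}", chrom_a=chrom_a, chrom_b=chrom_b,
        index_a=i_a, index_b=i_b,
        span_a=(i_a * 1000, i_a * 1000 + 500), span_b=(i_b * 1000, i_b * 1000 + 500),
        orientation=orientation,
    )


# --- independent oracle: interval-validity based maximal-run enumeration ----

def _interval_valid(anchors, i, j, max_gap):
    """Whether anchors[i..j] (sorted by index_a) form one colinear run."""
    for k in range(i, j):
        p, q = anchors[k], anchors[k + 1]
        if (p.chrom_a, p.chrom_b, p.orientation) != (q.chrom_a, q.chrom_b, q.orientation):
            return False
        if q.index_a - p.index_a - 1 > max_gap:
            return False
        d = 1 if p.orientation == "same" else -1
        step = (q.index_b - p.index_b) * d
        if not (1 <= step <= max_gap + 1):
            return False
    return True


def brute_force_runs(anchors, max_gap):
    """Greedy maximal valid intervals, checked by whole-interval validity."""
    ordered = sorted(anchors, key=lambda a: (a.chrom_a, a.index_a))
    runs = []
    i = 0
    while i < len(ordered):
        j = i
        while j + 1 < len(ordered) and _interval_valid(ordered, i, j + 1, max_gap):
            j += 1
        runs.append(tuple(ordered[i: j + 1]))
        i = j + 1
    return runs


def random_instance(rng, n):
    perm = list(range(n))
    rng.shuffle(perm)
    return [
        make_anchor(
            i, perm[i],
            chrom_a=rng.choice(["A1", "A2"]),
            chrom_b=rng.choice(["B1", "B2"]),
            orientation=rng.choice(["same", "inverted"]),
        )
        for i in range(n)
    ]


class TestChainBlocks:
    def test_perfectly_colinear_pair_gives_one_block(self):
        anchors = [make_anchor(i, i) for i in range(10)]
        blocks, leftovers = chain_blocks(anchors, max_gap_genes=0)
        assert len(blocks) == 1 and not leftovers
        assert blocks[0].n_anchors == 10 and blocks[0].orientation == "same"

    def test_internal_inversion_of_three_genes_gives_three_blocks(self):
        # genes 0-3 colinear, genes 4-6 inverted in B, genes 7-9 colinear
        anchors = (
            [make_anchor(i, i) for i in range(4)]
            + [make_anchor(i, 10 - i, orientation="inverted") for i in range(4, 7)]
            + [make_anchor(i, i) for i in range(7, 10)]
        )
        blocks, leftovers = chain_blocks(anchors, max_gap_genes=0)
        assert len(blocks) == 3 and not leftovers
        assert [b.orientation for b in blocks] == ["same", "inverted", "same"]

    def test_min_anchors_below_two_rejected(self):
        with pytest.raises(ValueError, match="min_anchors"):
            chain_blocks([], min_anchors=1)

    def test_blocks_and_singletons_partition_anchor_set(self, default_sim):
        _, ancestor, descendant, omap, _ = default_sim
        anchors = build_anchors(ancestor.genome, descendant.genome, omap)
        blocks, leftovers = chain_blocks(anchors, max_gap_genes=2)
        assigned = [a for b in blocks for a in b.anchors] + list(leftovers)
        assert len(assigned) == len(anchors)
        assert len({(a.gene_a, a.gene_b) for a in assigned}) == len(anchors)

    @pytest.mark.parametrize("max_gap", [0, 1, 3])
    def test_matches_brute_force_runs_on_random_instances(self, max_gap):
        rng = random.Random(42 + max_gap)
        for _ in range(200):
            anchors = random_instance(rng, rng.randint(2, 30))
            blocks, leftovers = chain_blocks(anchors, max_gap_genes=max_gap)
            runs = brute_force_runs(anchors, max_gap)
            expected_blocks = [r for r in runs if len(r) >= 2]
            assert len(blocks) == len(expected_blocks)
            for blk, run in zip(blocks, sorted(expected_blocks,
                                               key=lambda r: (r[0].chrom_a, r[0].span_a))):
                assert blk.anchors == run
            assert len(leftovers) == sum(1 for r in runs if len(r) == 1)

    def test_reversing_b_chromosomes_flips_orientations_only(self, default_sim):
        _, ancestor, descendant, omap, _ = default_sim
        anchors = build_anchors(ancestor.genome, descendant.genome, omap)
        blocks, _ = chain_blocks(anchors, max_gap_genes=1)

        def reverse_b(anchor, n_genes):
            return SyntenyAnchor(
                anchor.gene_a, anchor.gene_b, anchor.chrom_a, anchor.chrom_b,
                anchor.index_a, n_genes[anchor.chrom_b] - 1 - anchor.index_b,
                anchor.span_a, anchor.span_b,
                "inverted" if anchor.orientation == "same" else "same",
            )

        n_genes = {
            c.id: len(c.genes("protein_coding"))
            for c in descendant.genome.chromosomes
        }
        flipped = [reverse_b(a, n_genes) for a in anchors]
        blocks_f, _ = chain_blocks(flipped, max_gap_genes=1)
        assert len(blocks_f) == len(blocks)
        assert sorted(b.length_a for b in blocks_f) == sorted(b.length_a for b in blocks)
        assert sorted(b.orientation for b in blocks_f) == sorted(
            "inverted" if b.orientation == "same" else "same" for b in blocks
        )


class TestBuildAnchors:
    def test_identical_order_gives_same_orientation_anchors(self):
        ga = toy_genome("A", {"A1": [("a1", "+"), ("a2", "+"), ("a3", "-")]})
        gb = toy_genome("B", {"B1": [("b1", "+"), ("b2", "+"), ("b3", "-")]})
        omap = identity_map(["a1", "a2", "a3"], ["b1", "b2", "b3"])
        anchors = build_anchors(ga, gb, omap)
        assert len(anchors) == 3
        assert all(a.orientation == "same" for a in anchors)

    def test_empty_map_gives_no_anchors(self):
        ga = toy_genome("A", {"A1": [("a1", "+")]})
        gb = toy_genome("B", {"B1": [("b1", "+")]})
        assert build_anchors(ga, gb, OrthologMap([])) == []

    def test_anchor_count_equals_surviving_orthologs(self, default_sim):
        _, ancestor, descendant, omap, _ = default_sim
        anchors = build_anchors(ancestor.genome, descendant.genome, omap)
        assert len(anchors) == len(omap)

    def test_many_to_many_map_rejected_at_construction(self):
        with pytest.raises(ValueError, match="one-to-one"):
            OrthologMap([("a1", "b1", 50.0), ("a1", "b2", 50.0)])


class TestBlockStatistics:
    def test_single_half_genome_block(self):
        ga = toy_genome("A", {"A1": [(f"a{i}", "+") for i in range(2)]},
                        gene_bp=250_000, spacer_bp=0)
        anchors = [
            SyntenyAnchor(f"a{i}", f"b{i}", "A1", "B1", i, i,
                          (i * 250_000, (i + 1) * 250_000), None, "same")
            for i in range(2)
        ]
        blocks, _ = chain_blocks(anchors)
        # genome is 500 kb, single block covers all of it
        assert block_statistics(blocks, ga).half_genome_blocks == 1

    def test_half_genome_number_matches_exhaustive_subset_check(self, default_sim):
        from itertools import combinations

        _, ancestor, descendant, omap, _ = default_sim
        anchors = build_anchors(ancestor.genome, descendant.genome, omap)
        blocks, _ = chain_blocks(anchors, max_gap_genes=1)
        blocks = blocks[:18]  # keep the exhaustive check tractable
        stats = block_statistics(blocks, ancestor.genome)
        genome_bp = sum(c.length for c in ancestor.genome.chromosomes)
        lengths = [b.length_a for b in blocks]
        brute = None
        for k in range(1, len(lengths) + 1):
            if any(sum(c) * 2 >= genome_bp for c in combinations(lengths, k)):
                brute = k
                break
        assert stats.half_genome_blocks == brute

    def test_totals_from_tabulated_counts(self):
        counts = dict(c1=3, c2=5, c3=2)
        assert summarize_block_counts(counts).total == 10


class TestLocusNeighborhood:
    def _pair(self):
        genes_a = [(f"a{i}", "+") for i in range(9)]
        genes_b = [(f"b{i}", "+") for i in range(9)]
        ga = toy_genome("A", {"A1": genes_a})
        gb = toy_genome("B", {"B1": genes_b})
        omap = identity_map([g for g, _ in genes_a], [g for g, _ in genes_b])
        return ga, gb, omap

    def test_identical_neighborhoods_fully_conserved(self):
        ga, gb, omap = self._pair()
        rep = compare_locus_neighborhood(ga, gb, omap, ["a4"], flank_k=3)
        assert not rep.missing_in_b and not rep.rearranged
        assert set(rep.conserved) == {"a1", "a2", "a3", "a5", "a6", "a7"}

    def test_deleted_flank_genes_reported_missing(self):
        ga, gb, omap = self._pair()
        kept = [(a, b, i) for a, b, i in omap.pairs if a not in ("a2", "a3")]
        rep = compare_locus_neighborhood(ga, gb, OrthologMap(kept), ["a4"], flank_k=3)
        assert set(rep.missing_in_b) == {"a2", "a3"}

    def test_truncated_flank_flagged_not_fatal(self):
        ga, gb, omap = self._pair()
        rep = compare_locus_neighborhood(ga, gb, omap, ["a0"], flank_k=3)
        assert rep.truncated_flank

    def test_translocated_flank_gene_reported_rearranged(self):
        genes_a = [(f"a{i}", "+") for i in range(9)]
        ga = toy_genome("A", {"A1": genes_a})
        gb = toy_genome("B", {
            "B1": [(f"b{i}", "+") for i in range(9) if i != 2],
            "B2": [("b2", "+")] + [(f"x{i}", "+") for i in range(5)],
        })
        omap = identity_map([f"a{i}" for i in range(9)], [f"b{i}" for i in range(9)])
        rep = compare_locus_neighborhood(ga, gb, omap, ["a4"], flank_k=3)
        assert rep.rearranged == ("a2",)


class TestCentromereAssignment:
    def test_identical_genomes_identity_mapping(self, zero_event_sim):
        _, ancestor, descendant, omap, _ = zero_event_sim
        from eremosyn.synteny import build_anchors, chain_blocks

        anchors = build_anchors(ancestor.genome, descendant.genome, omap)
        blocks, _ = chain_blocks(anchors)
        res = assign_centromeric_chromosome_ids(
            ancestor.genome, descendant.genome, blocks,
            ancestor.centromeres, descendant.centromeres,
        )
        assert not res.orphans_a and not res.orphans_b
        assert sorted(res.mapping) == sorted(ancestor.centromeres)
        # chromosome numbering is preserved in a zero-event history
        for a_chrom, b_chrom in res.mapping.items():
            assert a_chrom.split("chr")[1] == b_chrom.split("chr")[1]
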