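import pytest

from eremosyn.gene_content import (
    classify_presence_absence,
    conserved_duplications,
    find_tandem_duplications,
    identity_distribution,
    percent_identity,
    validate_intron,
)
from eremosyn.genome_model import OrthologMap

from conftest import identity_map, toy_genome


class TestPresenceAbsence:
    def _toy(self):
        # 10 + 10 genes; 7 mapped; a7, a8 have outgroup homologs; a9 orphan
        ga = toy_genome("A", {"A1": [(f"a{i}", "+") for i in range(10)]})
        gb = toy_genome("B", {"B1": [(f"b{i}", "+") for i in range(10)]})
        omap = identity_map([f"a{i}" for i in range(7)], [f"b{i}" for i in range(7)])
        outgroup = {"a7", "a8", "b7", "b8", "b9"}
        return ga, gb, omap, outgroup

    def test_toy_counts(self):
        ga, gb, omap, outgroup = self._toy()
        rep = classify_presence_absence(ga, gb, omap, outgroup)
        assert rep.shared == 7
        assert rep.a_specific_with_outgroup == ("a7", "a8")
        assert rep.a_orphans == ("a9",)
        assert rep.b_specific_with_outgroup == ("b7", "b8", "b9")
        assert rep.b_orphans == ()

    def test_all_mapped_leaves_no_specific_genes(self):
        ga = toy_genome("A", {"A1": [("a1", "+"), ("a2", "+")]})
        gb = toy_genome("B", {"B1": [("b1", "+"), ("b2", "+")]})
        omap = identity_map(["a1", "a2"], ["b1", "b2"])
        rep = classify_presence_absence(ga, gb, omap, set())
        assert rep.shared == 2
        assert not rep.a_specific_with_outgroup and not rep.a_orphans
        assert not rep.b_specific_with_outgroup and not rep.b_orphans

    def test_categories_partition_gene_sets(self, default_sim):
        _, ancestor, descendant, omap, _ = default_sim
        rep = classify_presence_absence(ancestor.genome, descendant.genome, omap, set())
        counts = rep.counts()
        n_a = len(ancestor.genome.all_gene_ids())
        n_b = len(descendant.genome.all_gene_ids())
        assert counts["shared"] + counts["a_specific_with_outgroup"] + counts["a_orphans"] == n_a
        assert counts["shared"] + counts["b_specific_with_outgroup"] + counts["b_orphans"] == n_b

    def test_simulated_gene_set_loss_classified_with_outgroup(self, default_sim):
        # genes lost in the descendant but with an outgroup homolog: the
        # signature of a lineage-specific gene-family loss
        _, ancestor, descendant, omap, log = default_sim
        outgroup = set(ancestor.genome.all_gene_ids())
        rep = classify_presence_absence(ancestor.genome, descendant.genome, omap, outgroup)
        lost_mapped = [g for g in log.lost_genes if not g.endswith(tuple("x123"))]
        assert set(rep.a_specific_with_outgroup) >= set(
            g for g in lost_mapped if g in outgroup
        )


class TestTandemDuplications:
    def test_adjacent_paralogs_form_one_locus(self):
        g = toy_genome("A", {"A1": [("a1", "+"), ("a2", "+"), ("a3", "+")]})
        dups = find_tandem_duplications(g, [("a1", "a2", 85.0)])
        assert len(dups) == 1 and dups[0].member_genes == ("a1", "a2")

    def test_triplication_detected_as_single_locus_of_three(self):
        g = toy_genome("A", {"A1": [(f"a{i}", "+") for i in range(5)]})
        pairs = [("a1", "a2", 80.0), ("a2", "a3", 80.0), ("a1", "a3", 80.0)]
        dups = find_tandem_duplications(g, pairs)
        assert len(dups) == 1 and dups[0].size == 3

    def test_distant_paralogs_do_not_form_a_locus(self):
        g = toy_genome("A", {"A1": [(f"a{i}", "+") for i in range(6)]})
        dups = find_tandem_duplications(g, [("a0", "a5", 90.0)], max_intervening=1)
        assert dups == []

    def test_identity_threshold_applies(self):
        g = toy_genome("A", {"A1": [("a1", "+"), ("a2", "+")]})
        assert find_tandem_duplications(g, [("a1", "a2", 20.0)]) == []

    def test_one_intervening_gene_allowed_by_default(self):
        g = toy_genome("A", {"A1": [("a1", "+"), ("x", "+"), ("a2", "+")]})
        dups = find_tandem_duplications(g, [("a1", "a2", 70.0)])
        assert len(dups) == 1 and dups[0].member_genes == ("a1", "a2")


class TestConservedDuplications:
    def test_identical_genomes_conserve_all(self):
        g = toy_genome("A", {"A1": [("a1", "+"), ("a2", "+")]})
        h = toy_genome("B", {"B1": [("b1", "+"), ("b2", "+")]})
        da = find_tandem_duplications(g, [("a1", "a2", 80.0)])
        db = find_tandem_duplications(h, [("b1", "b2", 80.0)])
        omap = identity_map(["a1", "a2"], ["b1", "b2"])
        assert conserved_duplications(da, db, omap) == da

    def test_empty_ortholog_map_conserves_none(self):
        g = toy_genome("A", {"A1": [("a1", "+"), ("a2", "+")]})
        da = find_tandem_duplications(g, [("a1", "a2", 80.0)])
        assert conserved_duplications(da, [], OrthologMap([])) == []

    def test_dissolved_loci_not_conserved(self):
        # 3 ancestral loci; one dissolved in B by losing a member
        ga = toy_genome("A", {"A1": [(g, "+") for g in
                                     ("a1", "a2", "x1", "a3", "a4", "x2", "a5", "a6")]})
        gb = toy_genome("B", {"B1": [(g, "+") for g in
                                     ("b1", "b2", "y1", "b3", "b4", "y2", "b5")]})
        pairs_a = [("a1", "a2", 80.0), ("a3", "a4", 80.0), ("a5", "a6", 80.0)]
        pairs_b = [("b1", "b2", 80.0), ("b3", "b4", 80.0)]
        da = find_tandem_duplications(ga, pairs_a)
        db = find_tandem_duplications(gb, pairs_b)
        omap = identity_map(["a1", "a2", "a3", "a4", "a5"],
                            ["b1", "b2", "b3", "b4", "b5"])
        conserved = conserved_duplications(da, db, omap)
        assert [d.member_genes for d in conserved] == [("a1", "a2"), ("a3", "a4")]

    def test_simulated_truth_log_matches(self, default_sim):
        _, ancestor, descendant, omap, log = default_sim
        da = find_tandem_duplications(ancestor.genome, ancestor.paralog_pairs)
        db = find_tandem_duplications(descendant.genome, descendant.paralog_pairs)
        conserved = conserved_duplications(da, db, omap)
        lost = set(log.lost_genes)
        expected = [
            d for d in da
            if sum(1 for g in d.member_genes if g not in lost) >= 2
        ]
        assert conserved == expected


class TestIdentityDistribution:
    def test_identical_sequences_are_100_percent(self):
        assert percent_identity("MSTKQ", "MSTKQ") == 100.0

    def test_single_substitution_identity(self):
        assert percent_identity("ACDEFG", "ACDEFA") == pytest.approx(83.33, abs=0.01)

    def test_symmetry_and_order_invariance(self):
        seqs = {"a1": "MSTKQLVNN", "a2": "MSTAQLVHN", "b1": "MSTKQLVNN", "b2": "MSTAQAVNN"}
        d1 = identity_distribution([("a1", "b1"), ("a2", "b2")], seqs)
        d2 = identity_distribution([("a2", "b2"), ("a1", "b1")], seqs)
        assert d1.mean == d2.mean
        assert percent_identity(seqs["a2"], seqs["b2"]) == percent_identity(
            seqs["b2"], seqs["a2"]
        )

    def test_missing_sequence_skipped_with_warning_entry(self):
        d = identity_distribution([("a", "b"), ("c", "d")], {"a": "MST", "b": "MST"})
        assert d.skipped == (("c", "d"),)
        assert d.mean == 100.0

    def test_histogram_covers_20_to_100_in_5_percent_bins(self):
        d = identity_distribution([("a", "b")], {"a": "MST", "b": "MST"})
        assert len(d.bin_counts) == 16
        assert d.bin_counts[-1] == 1

    def test_simulated_divergence_matches_configured_rate(self, default_sim):
        cfg, ancestor, descendant, omap, _ = default_sim
        pairs = [(a, b) for a, b, _ in omap.pairs][:120]
        seqs = dict(ancestor.proteins)
        seqs.update(descendant.proteins)
        d = identity_distribution(pairs, seqs)
        assert d.mean == pytest.approx(100 * (1 - cfg.protein_mutation_rate), abs=2.0)


class TestIntronRule:
    def test_valid_synthetic_intron(self):
        intron = "GTAAGT" + "ACGT" * 5 + "TACTAAC" + "ACGTACGTAC" + "CAG"
        valid, violations = validate_intron(intron)
        assert valid and violations == []

    def test_aaaa_violates_all_three_rules(self):
        valid, violations = validate_intron("AAAA")
        assert not valid and len(violations) == 3

    def test_missing_branch_motif_is_the_only_violation(self):
        valid, violations = validate_intron("GT" + "ACGT" * 10 + "AG")
        assert not valid
        assert violations == ["branch_TACTAAC_missing_or_too_close_to_acceptor"]

    def test_branch_too_close_to_acceptor_rejected(self):
        valid, violations = validate_intron("GT" + "A" * 20 + "TACTAAC" + "AG")
        assert not valid

    def test_simulated_introns_all_valid(self, default_sim):
        _, ancestor, *_ = default_sim
        n_checked = 0
        for c in ancestor.genome.chromosomes:
            for f in c.features:
                for s, e in f.introns:
                    valid, _ = validate_intron(c.sequence[s:e])
                    assert valid
                    n_checked += 1
        assert n_checked > 0
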