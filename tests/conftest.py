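import pytest

from eremosyn.genome_model import Chromosome, GeneFeature, Genome, OrthologMap
from eremosyn.synthetic_genomes import SimConfig, evolve, simulate_ancestor


def toy_genome(genome_id, chrom_genes, gene_bp=1000, spacer_bp=500, sequence=None):
    """Build a sequence-less genome from {chrom: [(gene_id, strand), ...]}."""
    chroms = []
    for chrom_id, genes in chrom_genes.items():
        feats = []
        pos = spacer_bp
        for gene_id, strand in genes:
            feats.append(GeneFeature(gene_id, pos, pos + gene_bp, strand))
            pos += gene_bp + spacer_bp
        chroms.append(Chromosome(chrom_id, pos, None, feats))
    return Genome(genome_id, chroms)


def identity_map(genes_a, genes_b, identity=80.0):
    return OrthologMap([(a, b, identity) for a, b in zip(genes_a, genes_b)])


@pytest.fixture(scope="session")
def default_sim():
    """Default study-condition simulation: 8x60 genes, full event mix."""
    cfg = SimConfig(seed=11)
    ancestor = simulate_ancestor(cfg)
    descendant, omap, log = evolve(ancestor, cfg)
    return cfg, ancestor, descendant, omap, log


@pytest.fixture(scope="session")
def zero_event_sim():
    """No rearrangements, no loss, no duplication, no contraction."""
    cfg = SimConfig(
        seed=7,
        n_inversions=0,
        n_reciprocal_translocations=0,
        n_telomeric_translocations=0,
        n_centromere_loss_events=0,
        gene_loss_rate=0.0,
        tandem_dup_count=0,
        n_ancestral_tandem_dups=0,
        intergenic_contraction=1.0,
        protein_mutation_rate=0.0,
    )
    ancestor = simulate_ancestor(cfg)
    descendant, omap, log = evolve(ancestor, cfg)
    return cfg, ancestor, descendant, omap, log


@pytest.fixture(scope="session")
def lossless_rearranged_sim():
    """Rearrangements only: gene content identical, order shuffled."""
    cfg = SimConfig(
        seed=13,
        n_inversions=6,
        n_reciprocal_translocations=2,
        n_telomeric_translocations=1,
        n_centromere_loss_events=0,
        gene_loss_rate=0.0,
        tandem_dup_count=0,
        n_ancestral_tandem_dups=0,
    )
    ancestor = simulate_ancestor(cfg)
    descendant, omap, log = evolve(ancestor, cfg)
    return cfg, ancestor, descendant, omap, log
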