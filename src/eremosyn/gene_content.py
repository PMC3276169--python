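"""Cross-species gene content: presence/absence, tandem duplications,
protein-identity distribution, and intron splice-rule validation.

Presence/absence follows the three-way logic of a species pair plus an
outgroup: genes shared between the pair, genes specific to one species but
with an outgroup homolog (species-specific losses in the other lineage),
and orphans with no homolog anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align

from .genome_model import Genome, OrthologMap

__all__ = [
    "PresenceAbsenceReport",
    "TandemDuplication",
    "IdentityDistribution",
    "classify_presence_absence",
    "find_tandem_duplications",
    "conserved_duplications",
    "percent_identity",
    "identity_distribution",
    "validate_intron",
]


@dataclass(frozen=True)
class PresenceAbsenceReport:
    shared: int  # ortholog pair count
    a_specific_with_outgroup: tuple[str, ...]
    b_specific_with_outgroup: tuple[str, ...]
    a_orphans: tuple[str, ...]
    b_orphans: tuple[str, ...]

    def counts(self) -> dict[str, int]:
        return {
            "shared": self.shared,
            "a_specific_with_outgroup": len(self.a_specific_with_outgroup),
            "b_specific_with_outgroup": len(self.b_specific_with_outgroup),
            "a_orphans": len(self.a_orphans),
            "b_orphans": len(self.b_orphans),
        }


def classify_presence_absence(
    genome_a: Genome,
    genome_b: Genome,
    ab_orthologs: OrthologMap,
    outgroup_homologs: Iterable[str],
) -> PresenceAbsenceReport:
    """Partition both protein-coding gene sets by homology.

    ``outgroup_homologs`` is the set of gene ids (from either genome; ids
    are assumed globally unique) that have a homolog in an outgroup species.
    Genes unmapped in ``ab_orthologs`` split into species-specific-with-
    outgroup versus orphans.  The five categories partition both gene sets;
    an inconsistency (a mapped gene also flagged species-specific) raises.
    """
    genes_a = set(genome_a.all_gene_ids())
    genes_b = set(genome_b.all_gene_ids())
    outgroup = set(outgroup_homologs)

    # pairs referencing genes absent from the genomes are ignored
    shared_pairs = [
        (a, b) for a, b, _ in ab_orthologs.pairs if a in genes_a and b in genes_b
    ]
    shared_a = {a for a, _ in shared_pairs}
    shared_b = {b for _, b in shared_pairs}

    a_spec = sorted((genes_a - shared_a) & outgroup)
    b_spec = sorted((genes_b - shared_b) & outgroup)
    a_orph = sorted(genes_a - shared_a - outgroup)
    b_orph = sorted(genes_b - shared_b - outgroup)

    if set(a_spec) & shared_a or set(b_spec) & shared_b:
        raise RuntimeError("internal consistency error: gene both shared and specific")
    assert len(shared_pairs) + len(a_spec) + len(a_orph) == len(genes_a)
    assert len(shared_pairs) + len(b_spec) + len(b_orph) == len(genes_b)
    return PresenceAbsenceReport(
        len(shared_pairs), tuple(a_spec), tuple(b_spec), tuple(a_orph), tuple(b_orph)
    )


@dataclass(frozen=True)
class TandemDuplication:
    chrom: str
    member_genes: tuple[str, ...]
    locus_span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.member_genes) < 2:
            raise ValueError("a tandem duplication needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.member_genes)


def find_tandem_duplications(
    genome: Genome,
    paralog_pairs: Sequence[tuple[str, str, float]],
    max_intervening: int = 1,
    min_identity: float = 30.0,
) -> list[TandemDuplication]:
    """Maximal runs of mutually paralogous near-adjacent genes.

    ``paralog_pairs`` are within-genome homolog pairs with percent identity;
    pairs below ``min_identity`` are ignored.  A gene joins the current locus
    when it is paralogous to every current member and at most
    ``max_intervening`` unrelated genes separate it from the previous member.
    Loci are sorted by (chrom, start).
    """
    related: dict[str, set[str]] = {}
    for a, b, ident in paralog_pairs:
        if ident >= min_identity:
            related.setdefault(a, set()).add(b)
            related.setdefault(b, set()).add(a)

    loci: list[TandemDuplication] = []
    for chrom in genome.chromosomes:
        genes = chrom.genes("protein_coding")
        current: list[int] = []

        def close() -> None:
            if len(current) >= 2:
                members = tuple(genes[i].gene_id for i in current)
                span = (genes[current[0]].start, genes[current[-1]].end)
                loci.append(TandemDuplication(chrom.id, members, span))
            current.clear()

        for i, f in enumerate(genes):
            if current and i - current[-1] - 1 > max_intervening:
                close()
            if f.gene_id not in related:
                continue  # unrelated gene: may still be an allowed gap
            if current and all(
                f.gene_id in related.get(genes[j].gene_id, ()) for j in current
            ):
                current.append(i)
            else:
                close()
                current.append(i)
        close()
    loci.sort(key=lambda d: (d.chrom, d.locus_span[0]))
    return loci


def conserved_duplications(
    dups_a: Sequence[TandemDuplication],
    dups_b: Sequence[TandemDuplication],
    ab_orthologs: OrthologMap,
) -> list[TandemDuplication]:
    """Duplication loci of A whose structure survives in B.

    A locus in A is conserved when at least two of its members have
    orthologs that are members of one and the same duplication locus in B.
    """
    a2b = ab_orthologs.a_to_b()
    b_locus_of: dict[str, int] = {}
    for i, d in enumerate(dups_b):
        for g in d.member_genes:
            b_locus_of[g] = i
    out = []
    for d in dups_a:
        hits: dict[int, int] = {}
        for g in d.member_genes:
            b = a2b.get(g)
            if b is not None and b in b_locus_of:
                hits[b_locus_of[b]] = hits.get(b_locus_of[b], 0) + 1
        if hits and max(hits.values()) >= 2:
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# Protein identity


def _make_aligner() -> Align.PairwiseAligner:
    # Fixed scoring so identities are bit-exactly reproducible:
    # match +1, mismatch 0, gap open -10, gap extend -1, global mode.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity: matches / alignment columns * 100."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = alignment.length
    return 100.0 * counts.identities / columns


@dataclass(frozen=True)
class IdentityDistribution:
    identities: tuple[float, ...]
    mean: float
    bin_edges: tuple[float, ...]  # 5%-wide bins over [20, 100]
    bin_counts: tuple[int, ...]
    skipped: tuple[tuple[str, str], ...]  # pairs lacking a sequence


def identity_distribution(
    ortholog_pairs: Sequence[tuple[str, str]] | OrthologMap,
    protein_sequences: Mapping[str, str],
) -> IdentityDistribution:
    """Percent identity per ortholog pair, histogrammed in 5% bins.

    Pairs missing a sequence (or with an empty one) are skipped and listed.
    Identities below the 20% bin floor are clipped into the first bin.
    """
    if isinstance(ortholog_pairs, OrthologMap):
        pairs = [(a, b) for a, b, _ in ortholog_pairs.pairs]
    else:
        pairs = [(a, b) for a, b in ortholog_pairs]
    identities = []
    skipped = []
    for a, b in pairs:
        sa = protein_sequences.get(a)
        sb = protein_sequences.get(b)
        if not sa or not sb:
            skipped.append((a, b))
            continue
        identities.append(percent_identity(sa, sb))
    edges = np.arange(20.0, 100.0 + 5.0, 5.0)
    counts, _ = np.histogram(np.clip(identities, 20.0, 100.0), bins=edges)
    mean = float(np.mean(identities)) if identities else float("nan")
    return IdentityDistribution(
        tuple(identities), mean, tuple(edges), tuple(int(c) for c in counts),
        tuple(skipped),
    )


# ---------------------------------------------------------------------------
# Intron splice rule


BRANCH_MOTIF = "TACTAAC"


def validate_intron(intron_sequence: str) -> tuple[bool, list[str]]:
    """Check the 5'-GT ... TACTAAC ... AG-3' splice rule.

    Valid introns start with the GT donor, end with the AG acceptor, and
    carry the TACTAAC branch motif ending at least 3 bp before the terminal
    AG.  Returns ``(valid, violations)``.
    """
    seq = intron_sequence.upper()
    violations = []
    if len(seq) < 4:
        return False, ["too_short"]
    if not seq.startswith("GT"):
        violations.append("donor_not_GT")
    if not seq.endswith("AG"):
        violations.append("acceptor_not_AG")
    # the branch motif must end at least 3 bp before the terminal AG
    if BRANCH_MOTIF not in seq[: max(0, len(seq) - 5)]:
        violations.append("branch_TACTAAC_missing_or_too_close_to_acceptor")
    return not violations, violations
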