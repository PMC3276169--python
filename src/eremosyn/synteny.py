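"""Synteny-block detection by ortholog anchor chaining.

An *anchor* is a one-to-one ortholog pair placed at its ordinal gene
position on each genome (or on an ancestral gene order).  A *block* is a
maximal run of anchors, consecutive in genome-A order, that stay on one
chromosome pair, keep a consistent relative orientation, and whose ordinal
index gaps on both sides do not exceed ``max_gap_genes``.  Gap tolerance
absorbs small species-specific insertions; anchors that end up alone are
reported separately as singletons (orphan-gene loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .genome_model import AncestralOrder, GeneFeature, Genome, OrthologMap

__all__ = [
    "SyntenyAnchor",
    "SyntenyBlock",
    "BlockStatistics",
    "build_anchors",
    "chain_blocks",
    "block_statistics",
    "summarize_block_counts",
    "compare_locus_neighborhood",
    "NeighborhoodReport",
    "assign_centromeric_chromosome_ids",
    "CentromereAssignment",
    "write_blocks_tsv",
]


@dataclass(frozen=True)
class SyntenyAnchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    index_a: int  # ordinal gene position on chrom_a
    index_b: int  # ordinal gene position on chrom_b (or ancestral chromosome)
    span_a: tuple[int, int]  # bp span of the gene on genome A
    span_b: Optional[tuple[int, int]]  # bp span on B; None for ancestors
    orientation: str  # "same" | "inverted" relative strand of the pair

    def __post_init__(self) -> None:
        if self.index_a < 0 or self.index_b < 0:
            raise ValueError("anchor indices must be non-negative")
        if self.orientation not in ("same", "inverted"):
            raise ValueError("orientation must be 'same' or 'inverted'")


@dataclass(frozen=True)
class SyntenyBlock:
    anchors: tuple[SyntenyAnchor, ...]
    chrom_a: str
    chrom_b: str
    span_a: tuple[int, int]
    span_b: Optional[tuple[int, int]]
    orientation: str  # "same" | "inverted": direction of index_b along the block

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("a synteny block needs at least 2 anchors")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def length_a(self) -> int:
        return self.span_a[1] - self.span_a[0]


def _gene_orders(genome: Genome) -> dict[str, tuple[str, int, GeneFeature]]:
    """gene_id -> (chrom, ordinal index among protein-coding genes, feature)."""
    out = {}
    for c in genome.chromosomes:
        for i, f in enumerate(c.genes("protein_coding")):
            out[f.gene_id] = (c.id, i, f)
    return out


def build_anchors(
    genome_a: Genome,
    genome_b: Union[Genome, AncestralOrder],
    ortholog_map: OrthologMap,
) -> list[SyntenyAnchor]:
    """One anchor per mapped ortholog pair, at ordinal gene positions.

    ``genome_b`` may be a second annotated genome or an ancestral gene
    order (labels with strand signs, no coordinates).  Pairs whose genes are
    missing from either side are skipped.  The one-to-one property is
    enforced by :class:`OrthologMap` itself; many-to-many tables must be
    resolved before constructing the map.
    """
    pos_a = _gene_orders(genome_a)
    if isinstance(genome_b, AncestralOrder):
        pos_b = {
            label: (chrom, idx, strand)
            for label, (chrom, idx, strand) in genome_b.gene_positions().items()
        }
        b_is_ancestor = True
    else:
        pos_b = {g: (c, i, f) for g, (c, i, f) in _gene_orders(genome_b).items()}
        b_is_ancestor = False

    anchors = []
    for a, b, _ident in ortholog_map.pairs:
        if a not in pos_a or b not in pos_b:
            continue
        chrom_a, idx_a, feat_a = pos_a[a]
        if b_is_ancestor:
            chrom_b, idx_b, strand_b = pos_b[b]
            span_b = None
        else:
            chrom_b, idx_b, feat_b = pos_b[b]
            strand_b = feat_b.strand
            span_b = feat_b.span
        orientation = "same" if feat_a.strand == strand_b else "inverted"
        anchors.append(
            SyntenyAnchor(a, b, chrom_a, chrom_b, idx_a, idx_b, feat_a.span, span_b, orientation)
        )
    anchors.sort(key=lambda x: (x.chrom_a, x.index_a))
    return anchors


def _pair_extends(
    prev: SyntenyAnchor, nxt: SyntenyAnchor, direction: int, max_gap: int
) -> bool:
    """Can ``nxt`` follow ``prev`` in a chain running in ``direction`` on B?"""
    if nxt.chrom_a != prev.chrom_a or nxt.chrom_b != prev.chrom_b:
        return False
    if nxt.orientation != prev.orientation:
        return False
    if nxt.index_a - prev.index_a - 1 > max_gap:
        return False
    step = (nxt.index_b - prev.index_b) * direction
    return 1 <= step <= max_gap + 1


def _chain_direction(anchor: SyntenyAnchor) -> int:
    return 1 if anchor.orientation == "same" else -1


def _make_block(chain: Sequence[SyntenyAnchor]) -> SyntenyBlock:
    direction = _chain_direction(chain[0])
    span_a = (min(a.span_a[0] for a in chain), max(a.span_a[1] for a in chain))
    if chain[0].span_b is not None:
        span_b = (min(a.span_b[0] for a in chain), max(a.span_b[1] for a in chain))
    else:
        span_b = None
    return SyntenyBlock(
        anchors=tuple(chain),
        chrom_a=chain[0].chrom_a,
        chrom_b=chain[0].chrom_b,
        span_a=span_a,
        span_b=span_b,
        orientation="same" if direction == 1 else "inverted",
    )


def chain_blocks(
    anchors: Sequence[SyntenyAnchor],
    max_gap_genes: int = 3,
    min_anchors: int = 2,
) -> tuple[list[SyntenyBlock], list[SyntenyAnchor]]:
    """Partition anchors into maximal colinear runs plus singletons.

    Anchors are processed in genome-A order; a run extends while consecutive
    anchors share both chromosomes, keep one orientation, and ordinal gaps on
    both genomes stay within ``max_gap_genes``.  The direction on B is fixed
    by the shared orientation (same -> increasing, inverted -> decreasing),
    so a run is colinear by construction.  Runs shorter than ``min_anchors``
    go to the leftovers list.  Returns ``(blocks, leftovers)`` with blocks
    sorted by (chrom_a, span_a).
    """
    if min_anchors < 2:
        raise ValueError("min_anchors must be >= 2: a block needs at least 2 anchors")
    ordered = sorted(anchors, key=lambda x: (x.chrom_a, x.index_a))
    blocks: list[SyntenyBlock] = []
    leftovers: list[SyntenyAnchor] = []
    chain: list[SyntenyAnchor] = []

    def close() -> None:
        if len(chain) >= min_anchors:
            blocks.append(_make_block(chain))
        else:
            leftovers.extend(chain)
        chain.clear()

    for anc in ordered:
        if chain and _pair_extends(chain[-1], anc, _chain_direction(chain[-1]), max_gap_genes):
            chain.append(anc)
        else:
            if chain:
                close()
            chain.append(anc)
    if chain:
        close()
    blocks.sort(key=lambda b: (b.chrom_a, b.span_a))
    return blocks, leftovers


@dataclass(frozen=True)
class BlockStatistics:
    per_chromosome: dict[str, int]
    total: int
    mean_length_kb: Optional[float]  # mean block span on A, 1 decimal
    half_genome_blocks: Optional[int]  # smallest k largest blocks covering >= 50%

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_block_counts(per_chromosome: Mapping[str, int]) -> BlockStatistics:
    """Totals for an externally tabulated per-chromosome block count."""
    return BlockStatistics(
        per_chromosome=dict(per_chromosome),
        total=sum(per_chromosome.values()),
        mean_length_kb=None,
        half_genome_blocks=None,
    )


def block_statistics(blocks: Sequence[SyntenyBlock], genome_a: Genome) -> BlockStatistics:
    """Per-chromosome counts, mean block length, and the half-genome number.

    The half-genome block number H is the smallest k such that the k largest
    blocks (by span on genome A) cover at least 50% of the genome-A length
    (rDNA excluded, as in the genome-size convention).
    """
    per_chrom = {c.id: 0 for c in genome_a.chromosomes}
    for b in blocks:
        per_chrom[b.chrom_a] = per_chrom.get(b.chrom_a, 0) + 1
    total = len(blocks)
    mean_kb = round(sum(b.length_a for b in blocks) / total / 1000.0, 1) if total else None

    genome_bp = sum(
        c.length - sum(f.length for f in c.features if f.feature_class == "rDNA")
        for c in genome_a.chromosomes
    )
    half = None
    if total:
        covered = 0
        for k, b in enumerate(sorted(blocks, key=lambda b: -b.length_a), start=1):
            covered += b.length_a
            if covered * 2 >= genome_bp:
                half = k
                break
    return BlockStatistics(per_chrom, total, mean_kb, half)


# ---------------------------------------------------------------------------
# Locus-neighborhood comparison


@dataclass(frozen=True)
class NeighborhoodReport:
    focal_genes: tuple[str, ...]
    flank_genes: tuple[str, ...]  # genome-A order, upstream then downstream
    conserved: tuple[str, ...]
    missing_in_b: tuple[str, ...]
    rearranged: tuple[str, ...]
    truncated_flank: bool  # focal span too close to a chromosome end


def compare_locus_neighborhood(
    genome_a: Genome,
    genome_b: Genome,
    ortholog_map: OrthologMap,
    focal_genes_a: Sequence[str],
    flank_k: int = 5,
    window_slack: int = 2,
) -> NeighborhoodReport:
    """Classify the genes flanking a focal locus as conserved / missing / moved.

    For the ``flank_k`` genes on each side of the focal span on genome A,
    a flank gene is *conserved* when its ortholog lies on the B chromosome
    holding the locus, within the ordinal window spanned by the neighborhood's
    orthologs (plus ``window_slack``); *missing-in-B* when it has no ortholog;
    *rearranged* otherwise.  A focal locus at a chromosome end yields a
    truncated flank, flagged but not fatal.
    """
    if flank_k < 1:
        raise ValueError("flank_k must be >= 1")
    pos_a = _gene_orders(genome_a)
    pos_b = _gene_orders(genome_b)
    a2b = ortholog_map.a_to_b()

    missing_focals = [g for g in focal_genes_a if g not in pos_a]
    if missing_focals:
        raise KeyError(f"focal genes not in genome {genome_a.id}: {missing_focals}")
    chroms = {pos_a[g][0] for g in focal_genes_a}
    if len(chroms) != 1:
        raise ValueError("focal genes must lie on a single chromosome")
    chrom_a = chroms.pop()
    order = [f.gene_id for f in genome_a.chromosome(chrom_a).genes("protein_coding")]
    idxs = sorted(order.index(g) for g in focal_genes_a)
    lo, hi = idxs[0], idxs[-1]

    left = order[max(0, lo - flank_k): lo]
    right = order[hi + 1: hi + 1 + flank_k]
    truncated = len(left) < flank_k or len(right) < flank_k
    flank = left + right

    # Anchor the homologous locus on B via the neighborhood's orthologs.
    neighborhood = order[max(0, lo - flank_k): hi + 1 + flank_k]
    b_hits = [pos_b[a2b[g]] for g in neighborhood if g in a2b and a2b[g] in pos_b]
    if b_hits:
        from collections import Counter

        locus_chrom_b = Counter(c for c, _, _ in b_hits).most_common(1)[0][0]
        on_chrom = [i for c, i, _ in b_hits if c == locus_chrom_b]
        b_lo, b_hi = min(on_chrom) - window_slack, max(on_chrom) + window_slack
    else:
        locus_chrom_b, b_lo, b_hi = None, 0, -1

    conserved, missing, rearranged = [], [], []
    for g in flank:
        b = a2b.get(g)
        if b is None or b not in pos_b:
            missing.append(g)
        else:
            chrom_b, idx_b, _ = pos_b[b]
            if chrom_b == locus_chrom_b and b_lo <= idx_b <= b_hi:
                conserved.append(g)
            else:
                rearranged.append(g)
    return NeighborhoodReport(
        tuple(focal_genes_a), tuple(flank), tuple(conserved),
        tuple(missing), tuple(rearranged), truncated,
    )


# ---------------------------------------------------------------------------
# Centromere-based chromosome assignment


@dataclass(frozen=True)
class CentromereAssignment:
    mapping: dict[str, str]  # chrom of A -> chrom of B
    orphans_a: tuple[str, ...]  # A chromosomes whose centromere has no match
    orphans_b: tuple[str, ...]


def assign_centromeric_chromosome_ids(
    genome_a: Genome,
    genome_b: Genome,
    blocks: Sequence[SyntenyBlock],
    centromeres_a: Mapping[str, tuple[int, int]],
    centromeres_b: Mapping[str, tuple[int, int]],
    window_bp: int = 25_000,
) -> CentromereAssignment:
    """Pair chromosomes by centromeres that share a synteny block.

    A chromosome of A maps to the chromosome of B whose centromere lies in
    (or within ``window_bp`` of) a block that also covers the A centromere.
    Unmatched centromeres are reported as orphans — the signature of a
    centromere-loss arm translocation.  An A centromere matching two
    different B chromosomes raises an error listing the candidates.
    """

    def near(span: tuple[int, int], point_span: tuple[int, int]) -> bool:
        return point_span[0] < span[1] + window_bp and point_span[1] > span[0] - window_bp

    mapping: dict[str, str] = {}
    matched_b: set[str] = set()
    orphans_a = []
    for chrom_a, cen_a in sorted(centromeres_a.items()):
        candidates = set()
        for blk in blocks:
            if blk.chrom_a != chrom_a or blk.span_b is None:
                continue
            if near(blk.span_a, cen_a) and blk.chrom_b in centromeres_b:
                if near(blk.span_b, centromeres_b[blk.chrom_b]):
                    candidates.add(blk.chrom_b)
        if len(candidates) > 1:
            raise ValueError(
                f"centromere of {chrom_a} matches multiple chromosomes of "
                f"{genome_b.id}: {sorted(candidates)}"
            )
        if candidates:
            target = candidates.pop()
            mapping[chrom_a] = target
            matched_b.add(target)
        else:
            orphans_a.append(chrom_a)
    orphans_b = tuple(sorted(set(centromeres_b) - matched_b))
    return CentromereAssignment(mapping, tuple(orphans_a), orphans_b)


def write_blocks_tsv(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    """BED-like table on genome-A coordinates with paired B coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\t"
            "orientation\tn_anchors\n"
        )
        for b in blocks:
            sb = b.span_b if b.span_b is not None else (".", ".")
            fh.write(
                f"{b.chrom_a}\t{b.span_a[0]}\t{b.span_a[1]}\t{b.chrom_b}\t"
                f"{sb[0]}\t{sb[1]}\t{b.orientation}\t{b.n_anchors}\n"
            )
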