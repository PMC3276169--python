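"""Genome-evolution simulator with a replayable ground-truth log.

``simulate_ancestor`` builds a multichromosome yeast-like genome: ordered
protein-coding genes with sampled intergenic spacing, a few tRNAs, planted
point centromeres (CDEI + AT-rich CDEII + CDEIII) inside an AT-rich trough
of >= 15 kb, tandem telomere arrays at both ends, and i.i.d. background
sequence at a target GC.  ``evolve`` derives a descendant by applying
configured counts of inversions, reciprocal and telomeric translocations,
centromere-loss arm translocations (both arms of one chromosome moved onto
telomeres of two others, the centromere discarded), tandem duplications,
per-gene losses, intergenic contraction and protein substitution — every
structural event is recorded with full parameters so that ``replay`` on
the ancestor reproduces the descendant genome exactly.

Default parameters emulate the *Eremothecium* study conditions at one
tenth of the real genome scale (8 chromosomes x 60 genes) so that the full
pipeline runs in seconds; see ``SimConfig``.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_model import Chromosome, GeneFeature, Genome, OrthologMap

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "EvolutionLog",
    "simulate_ancestor",
    "evolve",
    "replay",
    "expected_synteny_segments",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
TELOMERE_UNIT_ECYM = "CACACCGCTGAGAGACCCGTACAC"  # 24 bp tandem unit

_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "N": "ACGT",
}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Sizes follow the real genomes scaled by ~1/10: 8 chromosomes of 60
    genes (~4800 genes at full scale), ~1.45 kb genes with ~0.56 kb
    spacers (2.05 kb/gene density), 40.3% background GC with AT-rich
    centromeric troughs of 18 kb, a 24 bp telomere unit, ~3% gene loss,
    a 0.4 per-site protein substitution rate (60% mean identity), and an
    intergenic contraction to 70% emulating genome streamlining.
    """

    seed: int = 0
    n_chromosomes: int = 8
    genes_per_chromosome: int = 60
    mean_gene_bp: int = 1450
    mean_intergenic_bp: int = 560
    base_gc: float = 0.403
    centromere_gc: float = 0.25
    centromere_dip_bp: int = 18_000
    cdeII_bp: int = 160
    cdeII_at: float = 0.90
    cdeI_consensus: str = "RTCACRTG"
    cdeIII_consensus: str = "TGTTTNTGNTTTCCGAA"
    telomere_unit: str = TELOMERE_UNIT_ECYM
    telomere_copies: int = 16
    trna_per_chromosome: int = 2
    intron_fraction: float = 0.05
    n_ancestral_tandem_dups: int = 2
    ancestor_id: str = "ANC"
    descendant_id: str = "DES"
    # evolution
    n_inversions: int = 8
    n_reciprocal_translocations: int = 2
    n_telomeric_translocations: int = 1
    n_centromere_loss_events: int = 1
    gene_loss_rate: float = 0.03
    tandem_dup_count: int = 3
    protein_mutation_rate: float = 0.40
    intergenic_contraction: float = 0.70

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes, self.genes_per_chromosome, self.n_inversions,
            self.n_reciprocal_translocations, self.n_telomeric_translocations,
            self.n_centromere_loss_events, self.tandem_dup_count,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for r in (self.gene_loss_rate, self.protein_mutation_rate,
                  self.base_gc, self.centromere_gc, self.intergenic_contraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if self.n_centromere_loss_events >= self.n_chromosomes - 1:
            raise ValueError("centromere losses must leave at least two chromosomes")


@dataclass
class _Seg:
    kind: str  # tel | ig | gene | cen
    seq: str
    gene_id: Optional[str] = None
    strand: str = "+"
    feature_class: str = "protein_coding"
    introns: tuple[tuple[int, int], ...] = ()  # relative to segment start
    cde: Optional[dict] = None  # relative cdeI/cdeII/cdeIII spans + orientation

    def flipped(self) -> "_Seg":
        n = len(self.seq)
        introns = tuple(sorted((n - e, n - s) for s, e in self.introns))
        cde = None
        if self.cde is not None:
            cde = {
                k: (n - v[1], n - v[0])
                for k, v in self.cde.items()
                if k != "orientation"
            }
            cde["orientation"] = (
                "reverse" if self.cde["orientation"] == "forward" else "forward"
            )
        return _Seg(
            self.kind, _revcomp(self.seq), self.gene_id,
            "-" if self.strand == "+" else "+",
            self.feature_class, introns, cde,
        )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(np.array(list("ACGT"))[idx])


def _instantiate_iupac(rng: np.random.Generator, motif: str) -> str:
    return "".join(
        c[int(rng.integers(len(c)))] for c in (_IUPAC_CHOICES[b] for b in motif)
    )


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(AA_ALPHABET), size=n)
    return "".join(AA_ALPHABET[i] for i in idx)


@dataclass
class SimulatedGenome:
    genome: Genome
    proteins: dict[str, str]
    centromeres: dict[str, tuple[int, int]]  # AT-dip span per chromosome
    cde_spans: dict[str, dict]  # cdeI/cdeII/cdeIII absolute spans + orientation
    telomeres: dict[str, list[tuple[int, int]]]
    paralog_pairs: list[tuple[str, str, float]]
    segments: dict[str, list[_Seg]] = field(repr=False, default_factory=dict)
    gene_truth: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    # gene_id -> (chrom, ordinal among protein-coding genes, strand)


@dataclass
class EvolutionLog:
    """Ordered record of applied events; replaying it on the ancestor
    reproduces the descendant genome (sequences and features) exactly."""

    events: list[dict] = field(default_factory=list)
    lost_genes: list[str] = field(default_factory=list)
    duplicated_genes: list[tuple[str, str]] = field(default_factory=list)
    lost_centromeres: list[str] = field(default_factory=list)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# Ancestor construction


def _build_centromere_segment(rng: np.random.Generator, cfg: SimConfig) -> _Seg:
    cdeI = _instantiate_iupac(rng, cfg.cdeI_consensus)
    cdeII = _rand_seq(rng, cfg.cdeII_bp, 1.0 - cfg.cdeII_at)
    cdeIII = _instantiate_iupac(rng, cfg.cdeIII_consensus)
    cassette = cdeI + cdeII + cdeIII
    orientation = "forward" if rng.random() < 0.5 else "reverse"
    pad = cfg.centromere_dip_bp - len(cassette)
    left = pad // 2
    flank_l = _rand_seq(rng, left, cfg.centromere_gc)
    flank_r = _rand_seq(rng, pad - left, cfg.centromere_gc)
    if orientation == "forward":
        spans = {
            "cdeI": (left, left + len(cdeI)),
            "cdeII": (left + len(cdeI), left + len(cdeI) + len(cdeII)),
            "cdeIII": (left + len(cdeI) + len(cdeII), left + len(cassette)),
        }
        seq = flank_l + cassette + flank_r
    else:
        rc = _revcomp(cassette)
        # on the forward axis: CDEIII' CDEII' CDEI'
        spans = {
            "cdeIII": (left, left + len(cdeIII)),
            "cdeII": (left + len(cdeIII), left + len(cdeIII) + len(cdeII)),
            "cdeI": (left + len(rc) - len(cdeI), left + len(rc)),
        }
        seq = flank_l + rc + flank_r
    cde = dict(spans)
    cde["orientation"] = orientation
    return _Seg("cen", seq, cde=cde)


def _build_gene_segment(
    rng: np.random.Generator, cfg: SimConfig, gene_id: str
) -> tuple[_Seg, str]:
    n = max(303, int(rng.normal(cfg.mean_gene_bp, cfg.mean_gene_bp * 0.25)))
    n -= n % 3
    seq = _rand_seq(rng, n, cfg.base_gc)
    introns: tuple[tuple[int, int], ...] = ()
    if rng.random() < cfg.intron_fraction:
        intron = (
            "GT" + _rand_seq(rng, 20, cfg.base_gc)
            + "TACTAAC" + _rand_seq(rng, 10, cfg.base_gc) + "AG"
        )
        pos = n // 4
        seq = seq[:pos] + intron + seq[pos:]
        introns = ((pos, pos + len(intron)),)
    strand = "+" if rng.random() < 0.5 else "-"
    protein = _rand_protein(rng, n // 3)
    return _Seg("gene", seq, gene_id, strand, "protein_coding", introns), protein


def _render(
    segments: dict[str, list[_Seg]],
    genome_id: str,
    proteins: dict[str, str],
    paralog_pairs: list[tuple[str, str, float]],
) -> SimulatedGenome:
    chroms = []
    centromeres: dict[str, tuple[int, int]] = {}
    cde_spans: dict[str, dict] = {}
    telomeres: dict[str, list[tuple[int, int]]] = {}
    gene_truth: dict[str, tuple[str, int, str]] = {}
    for chrom_id, segs in segments.items():
        pos = 0
        feats = []
        tel_list = []
        ordinal = 0
        parts = []
        for seg in segs:
            n = len(seg.seq)
            if seg.kind == "gene":
                introns = tuple((pos + s, pos + e) for s, e in seg.introns)
                feats.append(
                    GeneFeature(seg.gene_id, pos, pos + n, seg.strand,
                                seg.feature_class, introns)
                )
                if seg.feature_class == "protein_coding":
                    gene_truth[seg.gene_id] = (chrom_id, ordinal, seg.strand)
                    ordinal += 1
            elif seg.kind == "cen":
                centromeres[chrom_id] = (pos, pos + n)
                cde = {
                    k: (pos + v[0], pos + v[1])
                    for k, v in seg.cde.items()
                    if k != "orientation"
                }
                cde["orientation"] = seg.cde["orientation"]
                cde_spans[chrom_id] = cde
            elif seg.kind == "tel":
                tel_list.append((pos, pos + n))
            parts.append(seg.seq)
            pos += n
        telomeres[chrom_id] = tel_list
        seq = "".join(parts)
        chroms.append(Chromosome(chrom_id, len(seq), seq, feats))
    genome = Genome(genome_id, chroms)
    return SimulatedGenome(
        genome=genome,
        proteins=dict(proteins),
        centromeres=centromeres,
        cde_spans=cde_spans,
        telomeres=telomeres,
        paralog_pairs=list(paralog_pairs),
        segments=segments,
        gene_truth=gene_truth,
    )


def simulate_ancestor(config: SimConfig) -> SimulatedGenome:
    """Build the ancestral genome for the configured study conditions."""
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])
    tel_seq = cfg.telomere_unit * cfg.telomere_copies
    segments: dict[str, list[_Seg]] = {}
    proteins: dict[str, str] = {}
    paralogs: list[tuple[str, str, float]] = []

    for c in range(1, cfg.n_chromosomes + 1):
        chrom_id = f"{cfg.ancestor_id}_chr{c}"
        segs: list[_Seg] = [_Seg("tel", tel_seq)]
        trna_slots = set(
            rng.choice(cfg.genes_per_chromosome, size=cfg.trna_per_chromosome,
                       replace=False)
        )
        half = cfg.genes_per_chromosome // 2
        serial = 0
        for g in range(cfg.genes_per_chromosome):
            ig_len = max(60, int(rng.normal(cfg.mean_intergenic_bp,
                                            cfg.mean_intergenic_bp * 0.3)))
            segs.append(_Seg("ig", _rand_seq(rng, ig_len, cfg.base_gc)))
            if g == half:
                segs.append(_build_centromere_segment(rng, cfg))
                segs.append(_Seg("ig", _rand_seq(rng, 200, cfg.base_gc)))
            serial += 1
            gene_id = f"{cfg.ancestor_id}_{c}{serial:03d}"
            seg, protein = _build_gene_segment(rng, cfg, gene_id)
            segs.append(seg)
            proteins[gene_id] = protein
            if g in trna_slots:
                segs.append(_Seg("ig", _rand_seq(rng, 120, cfg.base_gc)))
                serial += 1
                trna_id = f"{cfg.ancestor_id}_{c}{serial:03d}t"
                segs.append(
                    _Seg("gene", _rand_seq(rng, 72, cfg.base_gc), trna_id,
                         "+" if rng.random() < 0.5 else "-", "tRNA")
                )
        segs.append(_Seg("ig", _rand_seq(rng, 300, cfg.base_gc)))
        segs.append(_Seg("tel", tel_seq))
        segments[chrom_id] = segs

    # ancestral tandem-duplication loci (paralog pairs present before divergence)
    all_genes = [
        (chrom, i)
        for chrom, segs in segments.items()
        for i, s in enumerate(segs)
        if s.kind == "gene" and s.feature_class == "protein_coding"
    ]
    for k in range(cfg.n_ancestral_tandem_dups):
        chrom, i = all_genes[int(rng.integers(len(all_genes)))]
        seg = segments[chrom][i]
        copy_id = f"{seg.gene_id}p"
        if any(s.gene_id == copy_id for s in segments[chrom]):
            continue
        spacer = _Seg("ig", _rand_seq(rng, 80, cfg.base_gc))
        dup = _Seg("gene", seg.seq, copy_id, seg.strand, "protein_coding", seg.introns)
        segments[chrom][i + 1: i + 1] = [spacer, dup]
        # slightly diverged paralog protein
        parent = proteins[seg.gene_id]
        mask = rng.random(len(parent)) < 0.10
        copy_prot = _mutate_protein(rng, parent, mask)
        proteins[copy_id] = copy_prot
        identity = 100.0 * float(np.mean([a == b for a, b in zip(parent, copy_prot)]))
        paralogs.append((seg.gene_id, copy_id, identity))

    return _render(segments, cfg.ancestor_id, proteins, paralogs)


def _mutate_protein(rng: np.random.Generator, protein: str, mask: np.ndarray) -> str:
    out = list(protein)
    for i in np.nonzero(mask)[0]:
        choices = AA_ALPHABET.replace(out[i], "")
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Evolution


def _gene_indices(segs: list[_Seg]) -> list[int]:
    return [
        i for i, s in enumerate(segs)
        if s.kind == "gene" and s.feature_class == "protein_coding"
    ]


def _cen_index(segs: list[_Seg]) -> Optional[int]:
    for i, s in enumerate(segs):
        if s.kind == "cen":
            return i
    return None


def _apply_event(segments: dict[str, list[_Seg]], ev: dict) -> None:
    kind = ev["type"]
    if kind == "inversion":
        segs = segments[ev["chrom"]]
        i, j = ev["seg_start"], ev["seg_end"]
        segments[ev["chrom"]] = (
            segs[:i] + [s.flipped() for s in reversed(segs[i: j + 1])] + segs[j + 1:]
        )
    elif kind == "reciprocal_translocation":
        s1 = segments[ev["chrom1"]]
        s2 = segments[ev["chrom2"]]
        k1, k2 = ev["cut1"], ev["cut2"]
        segments[ev["chrom1"]] = s1[:k1] + s2[k2:]
        segments[ev["chrom2"]] = s2[:k2] + s1[k1:]
    elif kind == "telomeric_translocation":
        s1 = segments[ev["chrom1"]]
        k = ev["cut"]
        if ev["arm"] == "right":
            arm, rest = s1[k:], s1[:k]
        else:
            arm, rest = s1[:k], s1[k:]
        segments[ev["chrom1"]] = rest
        s2 = segments[ev["chrom2"]]
        arm_telomere_side = "right" if ev["arm"] == "right" else "left"
        if ev["attach_end"] == "right":
            if arm_telomere_side == "left":  # flip so the telomere faces out
                arm = [s.flipped() for s in reversed(arm)]
            segments[ev["chrom2"]] = s2 + arm
        else:
            if arm_telomere_side == "right":
                arm = [s.flipped() for s in reversed(arm)]
            segments[ev["chrom2"]] = arm + s2
    elif kind == "centromere_loss":
        segs = segments.pop(ev["chrom"])
        ci = ev["cen_index"]
        left_arm, right_arm = segs[:ci], segs[ci + 1:]
        for arm, arm_tel_side, target, end in (
            (left_arm, "left", ev["left_target"], ev["left_end"]),
            (right_arm, "right", ev["right_target"], ev["right_end"]),
        ):
            s2 = segments[target]
            if end == "right":
                if arm_tel_side == "left":
                    arm = [s.flipped() for s in reversed(arm)]
                segments[target] = s2 + arm
            else:
                if arm_tel_side == "right":
                    arm = [s.flipped() for s in reversed(arm)]
                segments[target] = arm + s2
    elif kind == "tandem_duplication":
        segs = segments[ev["chrom"]]
        i = ev["seg_index"]
        seg = segs[i]
        dup = _Seg("gene", seg.seq, ev["copy_id"], seg.strand,
                   "protein_coding", seg.introns)
        spacer = _Seg("ig", ev["spacer_seq"])
        segs[i + 1: i + 1] = [spacer, dup]
    elif kind == "gene_loss":
        for chrom, segs in segments.items():
            segments[chrom] = [
                s for s in segs if s.gene_id not in set(ev["gene_ids"])
            ]
    elif kind == "intergenic_contraction":
        factor = ev["factor"]
        for segs in segments.values():
            for s in segs:
                if s.kind == "ig":
                    keep = max(20, int(math.ceil(factor * len(s.seq))))
                    s.seq = s.seq[:keep]
    else:
        raise ValueError(f"unknown event type {kind}")


def _sample_inversion(
    rng: np.random.Generator,
    segments: dict[str, list[_Seg]],
    used: dict[str, list[tuple[int, int]]],
    retries: int = 100,
) -> Optional[dict]:
    chrom_ids = sorted(segments)
    for _ in range(retries):
        chrom = chrom_ids[int(rng.integers(len(chrom_ids)))]
        segs = segments[chrom]
        genes = _gene_indices(segs)
        ci = _cen_index(segs)
        arms = (
            [[g for g in genes if g < ci], [g for g in genes if g > ci]]
            if ci is not None else [genes]
        )
        arm = arms[int(rng.integers(len(arms)))]
        if len(arm) < 3:
            continue
        a = int(rng.integers(len(arm) - 1))
        b = int(rng.integers(a + 1, len(arm)))
        i, j = arm[a], arm[b]
        # keep simulated inversions non-overlapping and non-adjacent so each
        # event contributes two clean breakpoints
        clash = any(i <= e + 2 and s - 2 <= j for s, e in used.get(chrom, []))
        if clash:
            continue
        used.setdefault(chrom, []).append((i, j))
        return {"type": "inversion", "chrom": chrom, "seg_start": i, "seg_end": j}
    return None


def _interior_ig_cuts(segs: list[_Seg], lo: int, hi: int) -> list[int]:
    """Cut points (seg-list indices) at an ig that sits between two genes."""
    genes = _gene_indices(segs)
    cuts = []
    for i in range(lo, hi):
        if segs[i].kind != "ig":
            continue
        if any(g < i for g in genes) and any(g > i for g in genes):
            cuts.append(i)
    return cuts


def _sample_reciprocal(
    rng: np.random.Generator, segments: dict[str, list[_Seg]], retries: int = 100
) -> Optional[dict]:
    chrom_ids = sorted(c for c in segments if _cen_index(segments[c]) is not None)
    if len(chrom_ids) < 2:
        return None
    for _ in range(retries):
        c1, c2 = rng.choice(len(chrom_ids), size=2, replace=False)
        ch1, ch2 = chrom_ids[int(c1)], chrom_ids[int(c2)]
        cuts1 = _right_arm_cuts(segments[ch1])
        cuts2 = _right_arm_cuts(segments[ch2])
        if not cuts1 or not cuts2:
            continue
        k1 = cuts1[int(rng.integers(len(cuts1)))]
        k2 = cuts2[int(rng.integers(len(cuts2)))]
        return {
            "type": "reciprocal_translocation",
            "chrom1": ch1, "cut1": k1, "chrom2": ch2, "cut2": k2,
        }
    return None


def _right_arm_cuts(segs: list[_Seg]) -> list[int]:
    """Cuts right of the centromere, between genes (tails swap then keep
    one centromere per product)."""
    ci = _cen_index(segs)
    if ci is None:
        return []
    genes = [g for g in _gene_indices(segs) if g > ci]
    if len(genes) < 2:
        return []
    return [
        i for i in range(genes[0] + 1, genes[-1])
        if segs[i].kind == "ig"
        and any(g < i for g in genes) and any(g > i for g in genes)
    ]


def _sample_telomeric(
    rng: np.random.Generator, segments: dict[str, list[_Seg]], retries: int = 100
) -> Optional[dict]:
    chrom_ids = sorted(c for c in segments if _cen_index(segments[c]) is not None)
    if len(chrom_ids) < 2:
        return None
    for _ in range(retries):
        c1, c2 = rng.choice(len(chrom_ids), size=2, replace=False)
        ch1, ch2 = chrom_ids[int(c1)], chrom_ids[int(c2)]
        segs = segments[ch1]
        ci = _cen_index(segs)
        arm = "left" if rng.random() < 0.5 else "right"
        genes = _gene_indices(segs)
        if arm == "left":
            arm_genes = [g for g in genes if g < ci]
        else:
            arm_genes = [g for g in genes if g > ci]
        if len(arm_genes) < 2:
            continue
        lo, hi = arm_genes[0] + 1, arm_genes[-1]
        cuts = [i for i in range(lo, hi) if segs[i].kind == "ig"]
        if not cuts:
            continue
        k = cuts[int(rng.integers(len(cuts)))]
        return {
            "type": "telomeric_translocation",
            "chrom1": ch1, "cut": k, "arm": arm,
            "chrom2": ch2,
            "attach_end": "left" if rng.random() < 0.5 else "right",
        }
    return None


def _sample_centromere_loss(
    rng: np.random.Generator, segments: dict[str, list[_Seg]]
) -> Optional[dict]:
    chrom_ids = sorted(c for c in segments if _cen_index(segments[c]) is not None)
    if len(chrom_ids) < 3:
        return None
    victim = chrom_ids[int(rng.integers(len(chrom_ids)))]
    others = [c for c in chrom_ids if c != victim]
    x, y = rng.choice(len(others), size=2, replace=False)
    return {
        "type": "centromere_loss",
        "chrom": victim,
        "cen_index": _cen_index(segments[victim]),
        "left_target": others[int(x)],
        "left_end": "left" if rng.random() < 0.5 else "right",
        "right_target": others[int(y)],
        "right_end": "left" if rng.random() < 0.5 else "right",
    }


def _descendant_gene_id(anc_gene_id: str, cfg: SimConfig) -> str:
    prefix = cfg.ancestor_id + "_"
    suffix = anc_gene_id[len(prefix):] if anc_gene_id.startswith(prefix) else anc_gene_id
    return f"{cfg.descendant_id}_{suffix}"


def evolve(
    ancestor: SimulatedGenome, config: SimConfig
) -> tuple[SimulatedGenome, OrthologMap, EvolutionLog]:
    """Derive a descendant genome, its ortholog map, and the ground-truth log.

    Event order is fixed (rearrangements, duplications, losses, intergenic
    contraction, protein substitution) so the log is replayable.  The
    ortholog map links each surviving ancestral gene to its descendant copy
    with the realized protein identity; tandem-duplication copies are not
    ortholog-mapped (they are logged and reported as paralogs).
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    segments = {c: [copy.deepcopy(s) for s in segs]
                for c, segs in ancestor.segments.items()}
    log = EvolutionLog()

    used_inversions: dict[str, list[tuple[int, int]]] = {}
    for _ in range(cfg.n_inversions):
        ev = _sample_inversion(rng, segments, used_inversions)
        if ev is None:
            raise RuntimeError("could not place an inversion (retry cap reached)")
        log.events.append(ev)
        _apply_event(segments, ev)
    for _ in range(cfg.n_reciprocal_translocations):
        ev = _sample_reciprocal(rng, segments)
        if ev is None:
            raise RuntimeError("could not place a reciprocal translocation")
        log.events.append(ev)
        _apply_event(segments, ev)
    for _ in range(cfg.n_telomeric_translocations):
        ev = _sample_telomeric(rng, segments)
        if ev is None:
            raise RuntimeError("could not place a telomeric translocation")
        log.events.append(ev)
        _apply_event(segments, ev)
    for _ in range(cfg.n_centromere_loss_events):
        ev = _sample_centromere_loss(rng, segments)
        if ev is None:
            raise RuntimeError("could not place a centromere-loss event")
        log.events.append(ev)
        log.lost_centromeres.append(ev["chrom"])
        _apply_event(segments, ev)

    # tandem duplications (fresh copies are not eligible parents themselves)
    dup_parents: list[str] = []
    new_copies: set[str] = set()
    for k in range(cfg.tandem_dup_count):
        gene_sites = [
            (chrom, i)
            for chrom, segs in sorted(segments.items())
            for i in _gene_indices(segs)
            if not segs[i].gene_id.endswith("p")
            and segs[i].gene_id not in new_copies
        ]
        chrom, i = gene_sites[int(rng.integers(len(gene_sites)))]
        parent_id = segments[chrom][i].gene_id
        if parent_id in dup_parents:
            continue
        copy_id = f"{parent_id}x{k + 1}"
        ev = {
            "type": "tandem_duplication", "chrom": chrom, "seg_index": i,
            "copy_id": copy_id,
            "spacer_seq": _rand_seq(rng, 80, cfg.base_gc),
        }
        log.events.append(ev)
        log.duplicated_genes.append((parent_id, copy_id))
        dup_parents.append(parent_id)
        new_copies.add(copy_id)
        _apply_event(segments, ev)

    # per-gene losses
    gene_ids = sorted(
        s.gene_id
        for segs in segments.values()
        for s in segs
        if s.kind == "gene" and s.feature_class == "protein_coding"
    )
    loss_mask = rng.random(len(gene_ids)) < cfg.gene_loss_rate
    lost = [g for g, m in zip(gene_ids, loss_mask) if m]
    if lost:
        ev = {"type": "gene_loss", "gene_ids": lost}
        log.events.append(ev)
        log.lost_genes.extend(lost)
        _apply_event(segments, ev)

    if cfg.intergenic_contraction < 1.0:
        ev = {"type": "intergenic_contraction", "factor": cfg.intergenic_contraction}
        log.events.append(ev)
        _apply_event(segments, ev)

    # rename: descendant ids, chromosomes renumbered in ancestral order
    renamed: dict[str, list[_Seg]] = {}
    anc_chrom_order = [c.id for c in ancestor.genome.chromosomes]
    serial = 0
    copy_parent: dict[str, str] = {}
    for parent, cp in log.duplicated_genes:
        copy_parent[cp] = parent
    for anc_chrom in anc_chrom_order:
        if anc_chrom not in segments:
            continue
        serial += 1
        desc_chrom = f"{cfg.descendant_id}_chr{serial}"
        renamed[desc_chrom] = segments[anc_chrom]

    # proteins: surviving genes mutate at the configured per-site rate
    proteins: dict[str, str] = {}
    identities: dict[str, float] = {}
    surviving = sorted(
        s.gene_id
        for segs in renamed.values()
        for s in segs
        if s.kind == "gene" and s.feature_class == "protein_coding"
    )
    for gid in surviving:
        source_id = copy_parent.get(gid, gid)
        parent_protein = ancestor.proteins[source_id]
        mask = rng.random(len(parent_protein)) < cfg.protein_mutation_rate
        mutated = _mutate_protein(rng, parent_protein, mask)
        desc_id = _descendant_gene_id(gid, cfg)
        proteins[desc_id] = mutated
        identities[gid] = 100.0 * float(
            np.mean([a == b for a, b in zip(parent_protein, mutated)])
        )

    # apply descendant ids on the segments
    for segs in renamed.values():
        for s in segs:
            if s.kind == "gene":
                s.gene_id = _descendant_gene_id(s.gene_id, cfg)

    ortholog_pairs = [
        (gid, _descendant_gene_id(gid, cfg), identities[gid])
        for gid in surviving
        if gid not in copy_parent and gid in ancestor.proteins
    ]
    paralogs = _descendant_paralogs(ancestor, log, proteins, cfg)
    descendant = _render(renamed, cfg.descendant_id, proteins, paralogs)
    return descendant, OrthologMap(ortholog_pairs), log


def _descendant_paralogs(
    ancestor: SimulatedGenome,
    log: EvolutionLog,
    desc_proteins: dict[str, str],
    cfg: SimConfig,
) -> list[tuple[str, str, float]]:
    lost = set(log.lost_genes)
    pairs = []
    candidates = [(a, b) for a, b, _ in ancestor.paralog_pairs] + log.duplicated_genes
    for a, b in candidates:
        if a in lost or b in lost:
            continue
        da, db = _descendant_gene_id(a, cfg), _descendant_gene_id(b, cfg)
        if da not in desc_proteins or db not in desc_proteins:
            continue
        pa, pb = desc_proteins[da], desc_proteins[db]
        n = min(len(pa), len(pb))
        ident = 100.0 * float(np.mean([pa[i] == pb[i] for i in range(n)]))
        pairs.append((da, db, ident))
    return pairs


def replay(ancestor: SimulatedGenome, log: EvolutionLog, config: SimConfig) -> SimulatedGenome:
    """Re-apply a recorded event log to the ancestor.

    Reproduces the descendant genome (sequences, features, chromosome
    naming) exactly; protein divergence is not part of the structural log,
    so the replayed object carries the ancestral protein set.
    """
    cfg = config
    segments = {c: [copy.deepcopy(s) for s in segs]
                for c, segs in ancestor.segments.items()}
    for ev in log.events:
        _apply_event(segments, ev)
    renamed: dict[str, list[_Seg]] = {}
    serial = 0
    for anc_chrom in [c.id for c in ancestor.genome.chromosomes]:
        if anc_chrom not in segments:
            continue
        serial += 1
        renamed[f"{cfg.descendant_id}_chr{serial}"] = segments[anc_chrom]
    for segs in renamed.values():
        for s in segs:
            if s.kind == "gene":
                s.gene_id = _descendant_gene_id(s.gene_id, cfg)
    return _render(renamed, cfg.descendant_id, {}, [])


def expected_synteny_segments(
    ancestor: SimulatedGenome,
    descendant: SimulatedGenome,
    ortholog_map: OrthologMap,
) -> dict[str, int]:
    """Ground-truth colinear segment count per ancestor chromosome.

    Walks each ancestor chromosome's mapped genes in order and counts the
    maximal runs whose descendant copies stay on one chromosome, at
    consecutive ordinal positions, with a consistent relative orientation —
    the breakpoint segments induced by the recorded events, computed from
    the truth mapping rather than from the synteny chainer.
    """
    a2b = ortholog_map.a_to_b()
    desc_pos = descendant.gene_truth
    counts: dict[str, int] = {}
    for chrom in ancestor.genome.chromosomes:
        genes = [f for f in chrom.genes("protein_coding") if f.gene_id in a2b]
        n_segments = 0
        prev = None  # (desc chrom, desc ordinal, relative orientation)
        for f in genes:
            d_chrom, d_idx, d_strand = desc_pos[a2b[f.gene_id]]
            rel = "same" if d_strand == f.strand else "inverted"
            step = 1 if rel == "same" else -1
            if (
                prev is None
                or prev[0] != d_chrom
                or prev[2] != rel
                or d_idx - prev[1] != step
            ):
                n_segments += 1
            prev = (d_chrom, d_idx, rel)
        counts[chrom.id] = n_segments
    return counts
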