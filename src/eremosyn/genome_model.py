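"""Core data model for annotated genomes and cross-genome gene maps.

Coordinates are 0-based, half-open everywhere in this package.  GFF3 input
(1-based, closed) is converted on read.  A :class:`Genome` is a small,
plain container: chromosomes with optional nucleotide sequence and an
ordered list of gene features.  Readers/writers cover FASTA (via Biopython),
a 7-column annotation TSV, GFF3, ortholog tables and ancestral gene orders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_CLASSES = ("protein_coding", "tRNA", "rDNA", "transposon", "other")

__all__ = [
    "FEATURE_CLASSES",
    "GeneFeature",
    "Chromosome",
    "Genome",
    "OrthologMap",
    "AncestralOrder",
    "GenomeStatistics",
    "read_genome",
    "write_genome",
    "read_annotation_tsv",
    "read_annotation_gff3",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_ancestral_order",
    "write_ancestral_order",
    "genome_statistics",
    "gene_density_kb_per_gene",
    "coding_fraction_percent",
    "gc_percent",
]


@dataclass(frozen=True)
class GeneFeature:
    """A gene-level feature on a chromosome.

    ``span`` is 0-based half-open; ``introns`` are sub-intervals strictly
    inside the span, non-overlapping, in genomic order.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    feature_class: str = "protein_coding"
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.gene_id}: invalid span ({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene_id}: strand must be + or -")
        if self.feature_class not in FEATURE_CLASSES:
            object.__setattr__(self, "feature_class", "other")
        prev_end = self.start
        for (s, e) in self.introns:
            if not (self.start < s < e < self.end):
                raise ValueError(f"feature {self.gene_id}: intron outside span")
            if s < prev_end:
                raise ValueError(f"feature {self.gene_id}: overlapping introns")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Chromosome:
    id: str
    length: int
    sequence: Optional[str] = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"chromosome {self.id}: length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > self.length:
                raise ValueError(
                    f"feature {f.gene_id} extends past end of chromosome {self.id}"
                )

    def genes(self, feature_class: Optional[str] = "protein_coding") -> list[GeneFeature]:
        """Features of one class (default protein-coding), in genomic order."""
        if feature_class is None:
            return list(self.features)
        return [f for f in self.features if f.feature_class == feature_class]


@dataclass
class Genome:
    id: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError(f"genome {self.id}: needs at least one chromosome")
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.id}: duplicate chromosome ids")
        seen: set[str] = set()
        for c in self.chromosomes:
            for f in c.features:
                if f.gene_id in seen:
                    raise ValueError(f"genome {self.id}: duplicate gene id {f.gene_id}")
                seen.add(f.gene_id)

    def chromosome(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(f"no chromosome {chrom_id} in genome {self.id}")

    def gene_index(self) -> dict[str, tuple[str, GeneFeature]]:
        """gene_id -> (chromosome id, feature), over all feature classes."""
        out: dict[str, tuple[str, GeneFeature]] = {}
        for c in self.chromosomes:
            for f in c.features:
                out[f.gene_id] = (c.id, f)
        return out

    def all_gene_ids(self, feature_class: Optional[str] = "protein_coding") -> list[str]:
        return [
            f.gene_id
            for c in self.chromosomes
            for f in c.genes(feature_class)
        ]


@dataclass
class OrthologMap:
    """One-to-one cross-genome gene pairing with percent identity."""

    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b, ident in self.pairs:
            if a in seen_a or b in seen_b:
                raise ValueError(
                    f"ortholog map is not one-to-one at pair ({a}, {b}); "
                    "resolve many-to-many homologies before constructing the map"
                )
            if not (0.0 <= ident <= 100.0):
                raise ValueError(f"identity {ident} for ({a}, {b}) outside [0, 100]")
            seen_a.add(a)
            seen_b.add(b)

    def a_to_b(self) -> dict[str, str]:
        return {a: b for a, b, _ in self.pairs}

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AncestralOrder:
    """Ordered, signed gene labels per ancestral chromosome."""

    chromosomes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # chrom id -> [(gene_label, strand)], strand in {+, -}

    def __post_init__(self) -> None:
        labels = [g for genes in self.chromosomes.values() for g, _ in genes]
        if len(set(labels)) != len(labels):
            raise ValueError("ancestral gene labels must be unique across the ancestor")

    def gene_positions(self) -> dict[str, tuple[str, int, str]]:
        """label -> (chrom, ordinal index, strand)."""
        out = {}
        for chrom, genes in self.chromosomes.items():
            for i, (label, strand) in enumerate(genes):
                out[label] = (chrom, i, strand)
        return out


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_introns(token: str) -> tuple[tuple[int, int], ...]:
    if token in (".", ""):
        return ()
    out = []
    for part in token.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def _format_introns(introns: Sequence[tuple[int, int]]) -> str:
    if not introns:
        return "."
    return ";".join(f"{s}-{e}" for s, e in introns)


def read_annotation_tsv(path: str | Path) -> dict[str, list[GeneFeature]]:
    """Read a 6/7-column annotation TSV.

    Columns: chrom, start, end, strand, class, gene_id[, introns].  Coordinates
    are 0-based half-open; introns are ``start-end`` pairs joined with ``;`` or
    ``.`` for none.  Lines starting with ``#`` are ignored.
    """
    per_chrom: dict[str, list[GeneFeature]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"annotation row has {len(parts)} columns: {line!r}")
            chrom, start, end, strand, fclass, gene_id = parts[:6]
            introns = _parse_introns(parts[6]) if len(parts) > 6 else ()
            per_chrom.setdefault(chrom, []).append(
                GeneFeature(gene_id, int(start), int(end), strand, fclass, introns)
            )
    return per_chrom


_GFF3_CLASS_MAP = {
    "gene": "protein_coding",
    "mrna": "protein_coding",
    "cds": "protein_coding",
    "trna": "tRNA",
    "trna_gene": "tRNA",
    "rrna": "rDNA",
    "rdna": "rDNA",
    "transposable_element": "transposon",
    "transposon": "transposon",
}


def read_annotation_gff3(path: str | Path) -> dict[str, list[GeneFeature]]:
    """Read gene-level records from a GFF3 file.

    Only top-level gene-like records are used (types gene, tRNA, rRNA,
    transposable_element; anything else maps to ``other``).  1-based closed
    GFF coordinates become 0-based half-open.  The gene id is taken from the
    ``ID`` attribute.
    """
    per_chrom: dict[str, list[GeneFeature]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            ftype_l = ftype.lower()
            if ftype_l in ("mrna", "cds", "exon", "intron", "region"):
                continue  # sub-features of genes; genes carry the annotation here
            fclass = _GFF3_CLASS_MAP.get(ftype_l, "other")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("Name")
            if gene_id is None:
                raise ValueError(f"GFF3 record without ID attribute: {line!r}")
            per_chrom.setdefault(chrom, []).append(
                GeneFeature(gene_id, int(start) - 1, int(end), strand, fclass)
            )
    return per_chrom


def read_genome(
    fasta_path: str | Path | None,
    annotation_path: str | Path,
    genome_id: Optional[str] = None,
) -> Genome:
    """Assemble a :class:`Genome` from a FASTA file and an annotation table.

    ``annotation_path`` may be the package TSV format or GFF3 (detected by
    extension ``.gff``/``.gff3``).  FASTA record ids must match annotation
    chromosome ids; an annotation row naming an absent chromosome is a hard
    error.  ``fasta_path=None`` builds a sequence-less genome; chromosome
    lengths are then the maximum feature end per chromosome.
    """
    annotation_path = Path(annotation_path)
    if annotation_path.suffix.lower() in (".gff", ".gff3"):
        per_chrom = read_annotation_gff3(annotation_path)
    else:
        per_chrom = read_annotation_tsv(annotation_path)

    gid = genome_id or (Path(fasta_path).stem if fasta_path else annotation_path.stem)
    chromosomes: list[Chromosome] = []
    if fasta_path is not None:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        seq_ids = {r.id for r in records}
        for chrom in per_chrom:
            if chrom not in seq_ids:
                raise ValueError(
                    f"annotation references chromosome {chrom!r} absent from FASTA"
                )
        for rec in records:
            seq = str(rec.seq).upper()
            chromosomes.append(
                Chromosome(rec.id, len(seq), seq, per_chrom.get(rec.id, []))
            )
    else:
        for chrom, feats in per_chrom.items():
            length = max(f.end for f in feats)
            chromosomes.append(Chromosome(chrom, length, None, feats))
    return Genome(gid, chromosomes)


def write_genome(genome: Genome, fasta_path: str | Path, annotation_path: str | Path) -> None:
    """Write FASTA plus 7-column annotation TSV (lossless round trip)."""
    records = []
    for c in genome.chromosomes:
        if c.sequence is None:
            raise ValueError(f"chromosome {c.id} has no sequence to write")
        records.append(SeqRecord(Seq(c.sequence), id=c.id, description=""))
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(annotation_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tclass\tgene_id\tintrons\n")
        for c in genome.chromosomes:
            for f in c.features:
                fh.write(
                    f"{c.id}\t{f.start}\t{f.end}\t{f.strand}\t{f.feature_class}"
                    f"\t{f.gene_id}\t{_format_introns(f.introns)}\n"
                )


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """TSV columns: gene_id_A, gene_id_B, percent_identity."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, b, ident = line.split("\t")[:3]
            pairs.append((a, b, float(ident)))
    return OrthologMap(pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\tpercent_identity\n")
        for a, b, ident in omap.pairs:
            fh.write(f"{a}\t{b}\t{ident:.2f}\n")


def read_ancestral_order(path: str | Path) -> AncestralOrder:
    """TSV columns: chrom, gene_label, strand (rows in ancestral order)."""
    chroms: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, label, strand = line.split("\t")[:3]
            chroms.setdefault(chrom, []).append((label, strand))
    return AncestralOrder(chroms)


def write_ancestral_order(order: AncestralOrder, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tgene\tstrand\n")
        for chrom, genes in order.chromosomes.items():
            for label, strand in genes:
                fh.write(f"{chrom}\t{label}\t{strand}\n")


# ---------------------------------------------------------------------------
# Genome statistics


def gene_density_kb_per_gene(total_bp: float, gene_count: int) -> Optional[float]:
    """Gene density in kb per gene, rounded to 2 decimals; None for 0 genes."""
    if gene_count == 0:
        return None
    return round(total_bp / 1000.0 / gene_count, 2)


def coding_fraction_percent(coding_bp: float, total_bp: float) -> float:
    """Protein-coding fraction of the genome as a percentage (2 decimals)."""
    if total_bp <= 0:
        raise ValueError("total length must be positive")
    return round(100.0 * coding_bp / total_bp, 2)


def gc_percent(sequences: Iterable[str]) -> Optional[float]:
    """GC percentage over non-N bases of all sequences; None if no sequence."""
    gc = 0
    acgt = 0
    for seq in sequences:
        if seq is None:
            continue
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    return 100.0 * gc / acgt


@dataclass(frozen=True)
class GenomeStatistics:
    genome_id: str
    n_chromosomes: int
    total_bp: int  # excludes rDNA-class feature spans
    gene_count: int
    gene_density_kb: Optional[float]
    coding_bp: int
    coding_fraction: float
    intron_count: int
    trna_count: int
    gc_content: Optional[float]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def genome_statistics(genome: Genome) -> GenomeStatistics:
    """Summary statistics in the style of a genome-comparison table.

    Total length excludes rDNA-class feature spans ("genome size without
    rDNA"); gene count and coding bp cover protein-coding features only;
    gene density is kb of (rDNA-excluded) genome per protein-coding gene;
    GC content is computed over non-N bases of available sequences.
    """
    total = 0
    genes = 0
    coding = 0
    introns = 0
    trnas = 0
    seqs = []
    for c in genome.chromosomes:
        rdna_bp = sum(f.length for f in c.features if f.feature_class == "rDNA")
        total += c.length - rdna_bp
        for f in c.features:
            if f.feature_class == "protein_coding":
                genes += 1
                coding += f.length - sum(e - s for s, e in f.introns)
                introns += len(f.introns)
            elif f.feature_class == "tRNA":
                trnas += 1
        if c.sequence is not None:
            seqs.append(c.sequence)
    return GenomeStatistics(
        genome_id=genome.id,
        n_chromosomes=len(genome.chromosomes),
        total_bp=total,
        gene_count=genes,
        gene_density_kb=gene_density_kb_per_gene(total, genes),
        coding_bp=coding,
        coding_fraction=coding_fraction_percent(coding, total) if total else math.nan,
        intron_count=introns,
        trna_count=trnas,
        gc_content=gc_percent(seqs),
    )
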