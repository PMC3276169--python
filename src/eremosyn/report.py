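"""End-to-end comparison pipeline and report generation.

``run_comparison`` executes the full chain — genome statistics, synteny
blocks against the partner genome (and optionally an ancestral gene
order), GC troughs, telomere repeats, centromere calls, and gene
presence/absence — and writes a JSON report plus TSV/BED artifacts shaped
like the genome-comparison and block-count tables of a two-species study.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Any, Optional

from . import gc_landscape, gene_content, synteny, telomere_centromere
from .genome_model import (
    Genome,
    OrthologMap,
    genome_statistics,
    read_ancestral_order,
    read_genome,
    read_ortholog_map,
    write_genome,
    write_ortholog_map,
)
from .synthetic_genomes import SimConfig, evolve, simulate_ancestor

logger = logging.getLogger("eremosyn")

__all__ = ["ComparisonReport", "run_comparison"]


@dataclass
class ComparisonReport:
    statistics: dict[str, dict]
    block_tables: dict[str, dict]  # reference name -> block statistics
    troughs: dict[str, list[dict]]
    telomere_units: dict[str, list[dict]]
    centromere_calls: dict[str, list[dict]]
    presence_absence: Optional[dict]

    def as_dict(self) -> dict:
        return asdict(self)


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _load_inputs(config: dict):
    if "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        sim = SimConfig(**sim_kwargs)
        ancestor = simulate_ancestor(sim)
        descendant, omap, log = evolve(ancestor, sim)
        return ancestor.genome, descendant.genome, omap, None, {
            "ancestor_sim": ancestor, "descendant_sim": descendant, "log": log,
        }
    genomes = config["genomes"]
    genome_a = read_genome(genomes["a"].get("fasta"), genomes["a"]["annotation"],
                           genomes["a"].get("id"))
    genome_b = read_genome(genomes["b"].get("fasta"), genomes["b"]["annotation"],
                           genomes["b"].get("id"))
    omap = read_ortholog_map(config["orthologs"])
    ancestor_order = (
        read_ancestral_order(config["ancestor"]) if config.get("ancestor") else None
    )
    return genome_a, genome_b, omap, ancestor_order, {}


@_stage("synteny")
def _synteny_stage(genome_a, ref, omap, max_gap: int):
    anchors = synteny.build_anchors(genome_a, ref, omap)
    blocks, leftovers = synteny.chain_blocks(anchors, max_gap_genes=max_gap)
    stats = synteny.block_statistics(blocks, genome_a)
    return blocks, leftovers, stats


def run_comparison(config: dict, out_dir: str | Path) -> ComparisonReport:
    """Run all analysis stages and write the report to ``out_dir``.

    ``config`` either points at input files (``genomes``/``orthologs``/
    optional ``ancestor``) or carries a ``simulate`` section with
    :class:`SimConfig` fields; a stage failure aborts with the stage name.
    Outputs: report.json, table1.tsv, table2.tsv, blocks.bed, troughs.bed,
    telomeres.bed, centromeres.bed (plus the simulated inputs when
    simulating).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    max_gap = int(config.get("max_gap_genes", 3))

    genome_a, genome_b, omap, ancestor_order, sim_extra = _load_inputs(config)
    if sim_extra:
        write_genome(genome_a, out / "ancestor.fa", out / "ancestor.tsv")
        write_genome(genome_b, out / "descendant.fa", out / "descendant.tsv")
        write_ortholog_map(omap, out / "orthologs.tsv")
        sim_extra["log"].write_json(out / "truth_log.json")

    stats = {g.id: genome_statistics(g).as_dict() for g in (genome_a, genome_b)}

    block_tables = {}
    blocks_b, _, stats_b = _synteny_stage(genome_a, genome_b, omap, max_gap)
    block_tables[genome_b.id] = stats_b.as_dict()
    if ancestor_order is not None:
        blocks_anc, _, stats_anc = _synteny_stage(genome_a, ancestor_order, omap, max_gap)
        block_tables["ancestor"] = stats_anc.as_dict()
    synteny.write_blocks_tsv(blocks_b, out / "blocks.bed")

    troughs_by_genome = {}
    telomere_units = {}
    centromere_calls = {}
    for g in (genome_a, genome_b):
        if not any(c.sequence for c in g.chromosomes):
            continue
        profiles = gc_landscape.genome_gc_profiles(g)
        cens = {}
        calls = []
        for c in g.chromosomes:
            best, _secondary = telomere_centromere.find_centromeres(c)
            if best is not None:
                cens[c.id] = best.span
                calls.append(_jsonable(best))
        centromere_calls[g.id] = calls
        troughs = gc_landscape.detect_troughs(profiles, centromeres=cens)
        troughs_by_genome[g.id] = [_jsonable(t) for t in troughs]
        units = []
        for c in g.chromosomes:
            for end in ("left", "right"):
                u = telomere_centromere.infer_telomere_repeat(c, end, scan_bp=1000)
                if u is not None:
                    units.append(_jsonable(u))
        telomere_units[g.id] = units
        if g is genome_a:
            gc_landscape.write_troughs_bed(troughs, out / "troughs.bed")

    presence = None
    if omap is not None:
        report = gene_content.classify_presence_absence(genome_a, genome_b, omap, ())
        presence = report.counts()

    _write_table1(stats, out / "table1.tsv")
    _write_table2(block_tables, out / "table2.tsv")
    _write_bed(telomere_units, out / "telomeres.bed")
    _write_bed(centromere_calls, out / "centromeres.bed", span_key="span")

    result = ComparisonReport(
        statistics=stats,
        block_tables=block_tables,
        troughs=troughs_by_genome,
        telomere_units=telomere_units,
        centromere_calls=centromere_calls,
        presence_absence=presence,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(result.as_dict()), fh, indent=1)
    return result


def _write_table1(stats: dict[str, dict], path: Path) -> None:
    names = list(stats)
    rows = [
        ("Chromosomes", "n_chromosomes"),
        ("Genome size without rDNA (bp)", "total_bp"),
        ("Genes", "gene_count"),
        ("Gene density (kb/gene)", "gene_density_kb"),
        ("Gene coding DNA (bp)", "coding_bp"),
        ("Gene coding DNA (%)", "coding_fraction"),
        ("Introns", "intron_count"),
        ("tRNAs", "trna_count"),
        ("GC content (%)", "gc_content"),
    ]
    with open(path, "w") as fh:
        fh.write("metric\t" + "\t".join(names) + "\n")
        for label, key in rows:
            vals = []
            for n in names:
                v = stats[n][key]
                vals.append("" if v is None else (f"{v:.2f}" if isinstance(v, float) else str(v)))
            fh.write(label + "\t" + "\t".join(vals) + "\n")


def _write_table2(block_tables: dict[str, dict], path: Path) -> None:
    refs = list(block_tables)
    chroms = sorted({c for t in block_tables.values() for c in t["per_chromosome"]})
    with open(path, "w") as fh:
        fh.write("chromosome\t" + "\t".join(f"blocks_vs_{r}" for r in refs) + "\n")
        for c in chroms:
            fh.write(c + "\t" + "\t".join(
                str(block_tables[r]["per_chromosome"].get(c, 0)) for r in refs) + "\n")
        fh.write("total\t" + "\t".join(str(block_tables[r]["total"]) for r in refs) + "\n")
        fh.write("mean_length_kb\t" + "\t".join(
            str(block_tables[r]["mean_length_kb"]) for r in refs) + "\n")
        fh.write("half_genome_blocks\t" + "\t".join(
            str(block_tables[r]["half_genome_blocks"]) for r in refs) + "\n")


def _write_bed(per_genome: dict[str, list[dict]], path: Path, span_key: str = "array_span") -> None:
    with open(path, "w") as fh:
        for gid, items in per_genome.items():
            for item in items:
                span = item.get(span_key) or item.get("span")
                if span is None:
                    continue
                fh.write(f"{item['chrom']}\t{span[0]}\t{span[1]}\t{gid}\n")
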