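"""Windowed GC profiling and detection of low-GC troughs.

Point centromeres of pre-WGD budding yeasts sit in AT-rich chromatin: the
GC landscape dips well below the genome mean for 15 kb or more around each
centromere, and often at telomeres.  A sliding window (default 5 kb window,
1 kb step) turns each chromosome into a GC profile; troughs are maximal
runs of windows below ``mean - z * sd``, kept when they span at least
``min_trough_bp`` and labeled by overlap with known centromere/telomere
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome_model import Chromosome, Genome

__all__ = [
    "GCProfile",
    "Trough",
    "gc_profile",
    "genome_gc_profiles",
    "detect_troughs",
    "write_profiles_tsv",
    "write_troughs_bed",
]

DEFAULT_WINDOW_BP = 5_000
DEFAULT_STEP_BP = 1_000
DEFAULT_Z = 1.0
DEFAULT_MIN_TROUGH_BP = 15_000


@dataclass(frozen=True)
class GCProfile:
    chrom: str
    window_bp: int
    step_bp: int
    starts: np.ndarray  # window start positions
    values: np.ndarray  # GC fraction per window over non-N bases; NaN if all-N
    chrom_length: int

    def window_end(self, i: int) -> int:
        return min(int(self.starts[i]) + self.window_bp, self.chrom_length)


@dataclass(frozen=True)
class Trough:
    chrom: str
    span: tuple[int, int]
    mean_gc: float
    deficit: float  # genome mean GC minus trough mean
    annotation_overlap: str  # centromere | telomere | internal | none

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


def gc_profile(
    chromosome: Chromosome,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> GCProfile:
    """GC fraction in windows tiling the chromosome at a fixed step.

    Terminal windows shorter than ``window_bp`` are included with their true
    length.  N bases are excluded from the denominator; an all-N window gets
    NaN.
    """
    if chromosome.sequence is None:
        raise ValueError(f"chromosome {chromosome.id} has no sequence")
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    seq = np.frombuffer(chromosome.sequence.encode("ascii"), dtype=np.uint8)
    is_gc = (seq == ord("G")) | (seq == ord("C"))
    is_acgt = is_gc | (seq == ord("A")) | (seq == ord("T"))
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_acgt = np.concatenate([[0], np.cumsum(is_acgt)])

    n = len(seq)
    starts = np.arange(0, max(n, 1), step_bp)
    ends = np.minimum(starts + window_bp, n)
    gc = cum_gc[ends] - cum_gc[starts]
    acgt = cum_acgt[ends] - cum_acgt[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(acgt > 0, gc / np.maximum(acgt, 1), np.nan)
    return GCProfile(chromosome.id, window_bp, step_bp, starts, values, n)


def genome_gc_profiles(
    genome: Genome,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> list[GCProfile]:
    return [gc_profile(c, window_bp, step_bp) for c in genome.chromosomes if c.sequence]


def _label_overlap(
    chrom: str,
    span: tuple[int, int],
    centromeres: Optional[Mapping[str, tuple[int, int]]],
    telomeres: Optional[Mapping[str, Sequence[tuple[int, int]]]],
) -> str:
    def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    if centromeres is None and telomeres is None:
        return "none"
    if centromeres and chrom in centromeres and overlaps(span, centromeres[chrom]):
        return "centromere"
    if telomeres and chrom in telomeres:
        for t in telomeres[chrom]:
            if overlaps(span, t):
                return "telomere"
    return "internal"


def detect_troughs(
    profiles: Sequence[GCProfile],
    z_threshold: float = DEFAULT_Z,
    min_trough_bp: int = DEFAULT_MIN_TROUGH_BP,
    centromeres: Optional[Mapping[str, tuple[int, int]]] = None,
    telomeres: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
    genome_mean_gc: Optional[float] = None,
) -> list[Trough]:
    """Maximal low-GC runs of windows, kept when spanning >= min_trough_bp.

    The threshold is ``mean - z_threshold * sd`` over all (non-NaN) window
    values genome-wide; ``genome_mean_gc`` overrides the mean if the caller
    has an external estimate.  A uniform-GC genome (sd == 0) yields no
    troughs.  Troughs are labeled by overlap with the provided centromere /
    telomere intervals ("none" when no annotation is supplied at all).
    """
    all_vals = np.concatenate([p.values for p in profiles]) if profiles else np.array([])
    all_vals = all_vals[~np.isnan(all_vals)]
    if all_vals.size == 0:
        return []
    mean = float(np.mean(all_vals)) if genome_mean_gc is None else float(genome_mean_gc)
    sd = float(np.std(all_vals))
    if sd == 0.0:
        return []
    threshold = mean - z_threshold * sd

    troughs: list[Trough] = []
    for p in profiles:
        low = p.values < threshold  # NaN compares False: all-N windows break runs
        i = 0
        n = len(low)
        while i < n:
            if not low[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            span = (int(p.starts[i]), p.window_end(j))
            if span[1] - span[0] >= min_trough_bp:
                vals = p.values[i: j + 1]
                mean_gc = float(np.nanmean(vals))
                troughs.append(
                    Trough(
                        chrom=p.chrom,
                        span=span,
                        mean_gc=mean_gc,
                        deficit=mean - mean_gc,
                        annotation_overlap=_label_overlap(p.chrom, span, centromeres, telomeres),
                    )
                )
            i = j + 1
    return troughs


def write_profiles_tsv(profiles: Sequence[GCProfile], path: str | Path) -> None:
    """Wiggle-style TSV: chrom, start, end, gc_fraction."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgc\n")
        for p in profiles:
            for i, s in enumerate(p.starts):
                v = p.values[i]
                val = f"{v:.4f}" if not np.isnan(v) else "NA"
                fh.write(f"{p.chrom}\t{int(s)}\t{p.window_end(i)}\t{val}\n")


def write_troughs_bed(troughs: Sequence[Trough], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in troughs:
            fh.write(
                f"{t.chrom}\t{t.span[0]}\t{t.span[1]}\t"
                f"{t.annotation_overlap}\t{t.mean_gc:.4f}\n"
            )
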