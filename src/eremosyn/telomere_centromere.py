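"""Telomere tandem-repeat unit inference and point-centromere detection.

Telomeres of *Eremothecium*-like genomes are short tandem arrays (a 24 bp
unit in *E. cymbalariae*); the repeat register and strand are ambiguous, so
units are reported as the lexicographically smallest rotation on the forward
strand, alongside the canonical reverse complement.

Point centromeres follow the CDEI-CDEII-CDEIII architecture of the
*Saccharomyces* complex: a short conserved CDEI motif, an AT-rich CDEII
spacer (~160 bp in *Eremothecium*, about twice the *S. cerevisiae* length),
and a CDEIII element carrying the CCGAA core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re
from typing import Optional

from .genome_model import Chromosome

__all__ = [
    "RepeatUnit",
    "CdeConfig",
    "CentromereCall",
    "canonical_rotation",
    "revcomp",
    "infer_telomere_repeat",
    "repeat_distance",
    "find_centromeres",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation of a repeat unit."""
    doubled = unit + unit
    return min(doubled[i: i + len(unit)] for i in range(len(unit)))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class RepeatUnit:
    unit: str  # canonical rotation, forward strand
    unit_revcomp: str  # canonical rotation of the reverse complement
    period: int
    copy_number: float
    end: str  # "left" | "right"
    chrom: str
    array_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.period != len(self.unit):
            raise ValueError("period must equal unit length")
        if self.copy_number < 2:
            raise ValueError("a tandem array needs at least 2 copies")


def _terminal_array_bp(
    region: str, period: int, max_mismatch_frac: float
) -> tuple[int, int]:
    """(span bp, mismatch count) of the tandem array anchored at the *end*
    of ``region``.

    The unit is the terminal ``period`` bp; copies extend inward while each
    copy matches its outward neighbor at >= (1 - max_mismatch_frac) identity.
    Mismatches are tallied against the terminal unit (once per substituted
    base, regardless of the period tried).  A final partial copy extends the
    array as far as it matches exactly.
    """
    n = len(region)
    if period > n // 2:
        return 0, 0
    allowed = int(max_mismatch_frac * period)
    unit = region[n - period:]
    prev = unit
    pos = n - period
    total = period
    mismatches = 0
    while pos - period >= 0:
        cand = region[pos - period: pos]
        if _hamming(cand, prev) > allowed:
            break
        total += period
        mismatches += _hamming(cand, unit)
        pos -= period
        prev = cand
    # partial inward copy: exact suffix match against the adjacent copy
    k = 0
    while k < min(period, pos) and region[pos - 1 - k] == prev[period - 1 - k]:
        k += 1
    return total + k, mismatches


def infer_telomere_repeat(
    chromosome: Chromosome,
    end: str,
    scan_bp: int = 5_000,
    min_copies: int = 2,
    max_mismatch_frac: float = 0.10,
) -> Optional[RepeatUnit]:
    """Minimal-period unit of the longest terminal tandem array, or None.

    Scans the terminal ``scan_bp`` of the chromosome.  For every candidate
    period p <= scan_bp/2 the terminal p bp define the unit; the array grows
    inward while adjacent copies agree at >= 90% identity (default).  Arrays
    are ranked by matched bases minus mismatched bases (so a longer period
    cannot win by absorbing noise through its larger mismatch allowance);
    ties go to the smaller period, which also guarantees the reported
    period is minimal (a unit that is itself periodic loses to its
    divisor).  Returns None when no array of >= ``min_copies`` copies
    exists.
    """
    if chromosome.sequence is None:
        raise ValueError(f"chromosome {chromosome.id} has no sequence")
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    scan_bp = min(scan_bp, chromosome.length)
    if end == "right":
        region = chromosome.sequence[chromosome.length - scan_bp:]
    else:
        # read the left end inward: reverse the prefix so the array is a suffix
        region = chromosome.sequence[:scan_bp][::-1]

    best_score = 0
    best_bp = 0
    best_p = 0
    for p in range(1, scan_bp // 2 + 1):
        bp, mismatches = _terminal_array_bp(region, p, max_mismatch_frac)
        # matched minus mismatched bases: random flanking sequence absorbed
        # into a (large-period) copy scores negative on average
        score = bp - 3 * mismatches
        if bp >= p * min_copies and score > best_score:
            best_score, best_bp, best_p = score, bp, p
    if best_p == 0:
        return None

    unit_terminal = region[len(region) - best_p:]
    if end == "left":
        unit_fwd = unit_terminal[::-1]  # undo the reversal
        span = (0, best_bp)
    else:
        unit_fwd = unit_terminal
        span = (chromosome.length - best_bp, chromosome.length)
    return RepeatUnit(
        unit=canonical_rotation(unit_fwd),
        unit_revcomp=canonical_rotation(revcomp(unit_fwd)),
        period=best_p,
        copy_number=best_bp / best_p,
        end=end,
        chrom=chromosome.id,
        array_span=span,
    )


def repeat_distance(unit_a: str, unit_b: str) -> int:
    """Minimal substitution count between two repeat units.

    Minimizes Hamming distance over all rotations of ``unit_b`` and of its
    reverse complement — repeat units are register- and strand-ambiguous.
    Units must have equal periods.
    """
    if len(unit_a) != len(unit_b):
        raise ValueError(
            f"units have different periods ({len(unit_a)} vs {len(unit_b)})"
        )
    p = len(unit_a)
    best = p
    for candidate in (unit_b, revcomp(unit_b)):
        doubled = candidate + candidate
        for i in range(p):
            best = min(best, _hamming(unit_a, doubled[i: i + p]))
    return best


# ---------------------------------------------------------------------------
# Point centromeres


@dataclass(frozen=True)
class CdeConfig:
    """Consensus motifs and CDEII bounds for the point-centromere scan.

    Defaults follow the *S. cerevisiae* consensus for CDEI and the CCGAA
    core of CDEIII, with the CDEII spacer widened to the ~160 bp of
    *Eremothecium* (bounds 120-200 bp, AT fraction >= 0.8).
    """

    cdeI: str = "RTCACRTG"
    cdeIII: str = "TGTTTNTGNTTTCCGAA"
    cdeII_min: int = 120
    cdeII_max: int = 200
    min_at: float = 0.80


@dataclass(frozen=True)
class CentromereCall:
    chrom: str
    span: tuple[int, int]
    cdeI_span: tuple[int, int]
    cdeII_span: tuple[int, int]
    cdeIII_span: tuple[int, int]
    orientation: str  # "forward" | "reverse"
    cdeII_at_fraction: float

    @property
    def cdeII_length(self) -> int:
        return self.cdeII_span[1] - self.cdeII_span[0]


def _iupac_regex(motif: str) -> re.Pattern:
    return re.compile("".join(IUPAC[b] for b in motif))


def _at_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("A") + seq.count("T")) / acgt


def _scan_strand(seq: str, cfg: CdeConfig) -> list[tuple[float, int, int, int, int]]:
    """(score, cdeI start, cdeI end, cdeIII start, cdeIII end) candidates."""
    re1 = _iupac_regex(cfg.cdeI)
    re3 = _iupac_regex(cfg.cdeIII)
    hits3 = [(m.start(), m.end()) for m in re3.finditer(seq)]
    out = []
    for m1 in re1.finditer(seq):
        s1, e1 = m1.start(), m1.end()
        for s3, e3 in hits3:
            spacer_len = s3 - e1
            if spacer_len < cfg.cdeII_min:
                continue
            if spacer_len > cfg.cdeII_max:
                break
            at = _at_fraction(seq[e1:s3])
            if at >= cfg.min_at:
                out.append((at, s1, e1, s3, e3))
    return out


def find_centromeres(
    chromosome: Chromosome, cde_config: CdeConfig = CdeConfig()
) -> tuple[Optional[CentromereCall], list[CentromereCall]]:
    """Best CDEI-CDEII-CDEIII call on either strand, plus secondary calls.

    Both strands are scanned for the CDEI consensus followed, after an
    AT-rich spacer within the configured length bounds, by the CDEIII
    consensus.  Candidates are ranked by spacer AT fraction (ties go to the
    leftmost, forward-strand call).  Returns ``(best_or_None, secondary)``.
    """
    if chromosome.sequence is None:
        raise ValueError(f"chromosome {chromosome.id} has no sequence")
    seq = chromosome.sequence
    n = len(seq)
    calls: list[CentromereCall] = []
    for strand, s in (("forward", seq), ("reverse", revcomp(seq))):
        for at, s1, e1, s3, e3 in _scan_strand(s, cde_config):
            if strand == "reverse":
                # map reverse-strand coordinates back to the forward axis,
                # where the elements read CDEIII-CDEII-CDEI left to right
                cdeI_span = (n - e1, n - s1)
                cdeIII_span = (n - e3, n - s3)
                cdeII_span = (n - s3, n - e1)
            else:
                cdeI_span, cdeIII_span = (s1, e1), (s3, e3)
                cdeII_span = (e1, s3)
            span = (min(cdeI_span[0], cdeIII_span[0]), max(cdeI_span[1], cdeIII_span[1]))
            calls.append(
                CentromereCall(
                    chrom=chromosome.id,
                    span=span,
                    cdeI_span=cdeI_span,
                    cdeII_span=cdeII_span,
                    cdeIII_span=cdeIII_span,
                    orientation=strand,
                    cdeII_at_fraction=at,
                )
            )
    if not calls:
        return None, []
    calls.sort(key=lambda c: (-c.cdeII_at_fraction, c.span[0], c.orientation))
    return calls[0], calls[1:]
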