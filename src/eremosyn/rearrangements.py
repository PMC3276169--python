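"""Genome rearrangements over signed block permutations.

A multichromosomal genome is a set of chromosomes, each an ordered tuple of
signed block labels; the sign encodes block orientation.  Two genomes are
considered equal up to chromosome order; flipping a whole chromosome is a
real (observable) inversion event, not a change of reading direction.

The operation alphabet is the event vocabulary of small-scale yeast genome
evolution: inversions, reciprocal translocations, telomeric translocations
(an arm moved onto another chromosome's telomere), fusions and fissions.
``minimal_scenario`` finds a provably shortest scenario by breadth-first
search (bidirectional, with canonical-form deduplication); it is meant for
desk-scale instances and refuses more than ``max_elements`` blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from .synteny import SyntenyBlock
from .genome_model import Genome

__all__ = [
    "SignedGenomePermutation",
    "Scenario",
    "blocks_to_permutation",
    "breakpoint_count",
    "minimal_scenario",
    "apply_operations",
]

Chrom = tuple[int, ...]
State = tuple[Chrom, ...]
Op = tuple


@dataclass(frozen=True)
class SignedGenomePermutation:
    chromosomes: State

    def __post_init__(self) -> None:
        labels = [abs(x) for c in self.chromosomes for x in c]
        if 0 in labels:
            raise ValueError("block label 0 is not allowed (sign would be ambiguous)")
        if len(set(labels)) != len(labels):
            raise ValueError("each block label must appear exactly once")

    @property
    def elements(self) -> frozenset[int]:
        return frozenset(abs(x) for c in self.chromosomes for x in c)

    @property
    def n_elements(self) -> int:
        return sum(len(c) for c in self.chromosomes)


def _flip(chrom: Chrom) -> Chrom:
    return tuple(-x for x in reversed(chrom))


def _canonical(state: State) -> State:
    # genomes are equal up to chromosome order; a whole-chromosome flip is a
    # real inversion event, so orientation is NOT normalized away
    return tuple(sorted(c for c in state if c))


def _adjacencies(state: State) -> frozenset:
    """Flip- and order-invariant adjacency set, including telomere caps."""
    adj = set()
    for c in state:
        if not c:
            continue
        # telomere caps: the left cap of (a, ...) equals the right cap of the
        # flipped chromosome (..., -a)
        adj.add(("T", c[0]))
        adj.add(("T", -c[-1]))
        for x, y in zip(c, c[1:]):
            adj.add(min((x, y), (-y, -x)))
    return frozenset(adj)


def breakpoint_count(
    source: SignedGenomePermutation, target: SignedGenomePermutation
) -> int:
    """Adjacencies (telomere caps included) of source absent from target."""
    if source.elements != target.elements:
        raise ValueError("source and target must contain the same block labels")
    return len(_adjacencies(source.chromosomes) - _adjacencies(target.chromosomes))


# ---------------------------------------------------------------------------
# Operations


def _apply(state: State, op: Op) -> State:
    kind = op[0]
    chroms = [list(c) for c in state]
    if kind == "inversion":
        _, c, i, j = op
        seg = [-x for x in reversed(chroms[c][i: j + 1])]
        chroms[c][i: j + 1] = seg
    elif kind == "reciprocal_translocation":
        _, c1, i, c2, j, pairing = op
        a1, a2 = chroms[c1][:i], chroms[c1][i:]
        b1, b2 = chroms[c2][:j], chroms[c2][j:]
        if pairing == 0:
            chroms[c1], chroms[c2] = a1 + b2, b1 + a2
        else:
            chroms[c1] = a1 + list(_flip(tuple(b1)))
            chroms[c2] = list(_flip(tuple(b2))) + a2
    elif kind == "telomeric_translocation":
        _, c1, i, arm_side, c2, attach_end, flip = op
        left, right = chroms[c1][:i], chroms[c1][i:]
        arm, rest = (left, right) if arm_side == "L" else (right, left)
        if flip:
            arm = list(_flip(tuple(arm)))
        chroms[c1] = rest
        if attach_end == "L":
            chroms[c2] = arm + chroms[c2]
        else:
            chroms[c2] = chroms[c2] + arm
    elif kind == "fusion":
        _, c1, c2, o1, o2 = op
        a = list(_flip(tuple(chroms[c1]))) if o1 else chroms[c1]
        b = list(_flip(tuple(chroms[c2]))) if o2 else chroms[c2]
        chroms[c1] = a + b
        chroms[c2] = []
    elif kind == "fission":
        _, c, i = op
        left, right = chroms[c][:i], chroms[c][i:]
        chroms[c] = left
        chroms.append(right)
    else:
        raise ValueError(f"unknown operation {kind}")
    return tuple(tuple(c) for c in chroms if c)


def apply_operations(source: SignedGenomePermutation, operations: Sequence[Op]) -> SignedGenomePermutation:
    state = source.chromosomes
    for op in operations:
        state = _apply(state, op)
    return SignedGenomePermutation(state)


def _enumerate_ops(state: State) -> Iterator[Op]:
    """All operations applicable to a state, in a fixed (sorted) order.

    Reciprocal translocations cut both chromosomes internally; telomeric
    translocations move one arm onto a telomere of another chromosome.
    """
    ops: list[Op] = []
    n = len(state)
    for c, chrom in enumerate(state):
        ln = len(chrom)
        for i in range(ln):
            for j in range(i, ln):
                ops.append(("inversion", c, i, j))
        for i in range(1, ln):
            ops.append(("fission", c, i))
    for c1 in range(n):
        for c2 in range(n):
            if c1 == c2:
                continue
            l1, l2 = len(state[c1]), len(state[c2])
            if c1 < c2:
                for o1 in (0, 1):
                    for o2 in (0, 1):
                        ops.append(("fusion", c1, c2, o1, o2))
                for i in range(1, l1):
                    for j in range(1, l2):
                        for pairing in (0, 1):
                            ops.append(("reciprocal_translocation", c1, i, c2, j, pairing))
            for i in range(1, l1):
                for arm_side in ("L", "R"):
                    for attach_end in ("L", "R"):
                        for flip in (0, 1):
                            ops.append(
                                ("telomeric_translocation", c1, i, arm_side, c2, attach_end, flip)
                            )
    ops.sort()
    return iter(ops)


@dataclass(frozen=True)
class Scenario:
    operations: tuple[Op, ...]

    @property
    def length(self) -> int:
        return len(self.operations)

    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for op in self.operations:
            out[op[0]] = out.get(op[0], 0) + 1
        return out


def minimal_scenario(
    source: SignedGenomePermutation,
    target: SignedGenomePermutation,
    max_elements: int = 10,
    max_ops: int = 12,
) -> Scenario:
    """Provably minimal rearrangement scenario from source to target.

    Iterative-deepening A* over the operation alphabet, with the admissible
    breakpoint bound (one operation heals at most two breakpoints, telomere
    caps included).  Among equal-length scenarios the lexicographically
    first operation sequence (in the encoding order of the operation
    tuples) is returned, because operations are tried in sorted order at
    every depth.  Equality of genomes is up to chromosome order.  Instances
    above ``max_elements`` blocks are refused: the search is exhaustive by
    design — use :func:`breakpoint_count` for large inputs.
    """
    if source.elements != target.elements:
        raise ValueError("source and target must contain the same block labels")
    if source.n_elements > max_elements:
        raise ValueError(
            f"{source.n_elements} blocks exceed max_elements={max_elements}; "
            "use breakpoint_count for large instances"
        )
    canon_target = _canonical(target.chromosomes)
    target_adj = _adjacencies(target.chromosomes)

    def lower_bound(state: State) -> int:
        bp = len(_adjacencies(state) - target_adj)
        return (bp + 1) // 2

    path: list[Op] = []
    BIG = max_ops + 1

    def search(state: State, g: int, bound: int) -> int | bool:
        """True when a scenario of length <= bound is completed; else the
        smallest f-value that exceeded the bound (for the next iteration)."""
        if _canonical(state) == canon_target:
            return True
        f = g + max(1, lower_bound(state))
        if f > bound:
            return f
        minimum: int = BIG
        for op in _enumerate_ops(state):
            path.append(op)
            t = search(_apply(state, op), g + 1, bound)
            if t is True:
                return True
            path.pop()
            if t < minimum:
                minimum = t
        return minimum

    bound = lower_bound(source.chromosomes)
    while True:
        res = search(source.chromosomes, 0, bound)
        if res is True:
            break
        if res > max_ops:
            raise RuntimeError(f"no scenario of length <= {max_ops} found")
        bound = res

    result = Scenario(tuple(path))
    # every search result is checked: replaying the scenario must give target
    final = apply_operations(source, result.operations)
    assert _canonical(final.chromosomes) == canon_target
    return result


def blocks_to_permutation(
    blocks: Sequence[SyntenyBlock],
    genome_a: Genome,
    genome_b: Optional[Genome] = None,
) -> tuple[SignedGenomePermutation, SignedGenomePermutation]:
    """Turn synteny blocks into a (source, target) signed permutation pair.

    Blocks are numbered 1..n by (chrom_a, span_a).  The source reads the
    blocks along genome A (all positive, A is the reference orientation);
    the target orders them along B — by bp span when B coordinates exist,
    else by ordinal anchor position — with inverted blocks negated.
    """
    ordered = sorted(blocks, key=lambda b: (b.chrom_a, b.span_a))
    label = {id(b): k + 1 for k, b in enumerate(ordered)}

    chrom_order_a = [c.id for c in genome_a.chromosomes]
    source_chroms = []
    for chrom in chrom_order_a:
        row = [label[id(b)] for b in ordered if b.chrom_a == chrom]
        if row:
            source_chroms.append(tuple(row))

    by_chrom_b: dict[str, list[SyntenyBlock]] = {}
    for b in ordered:
        by_chrom_b.setdefault(b.chrom_b, []).append(b)
    if genome_b is not None:
        chrom_order_b = [c.id for c in genome_b.chromosomes if c.id in by_chrom_b]
    else:
        chrom_order_b = sorted(by_chrom_b)
    target_chroms = []
    for chrom in chrom_order_b:
        members = by_chrom_b[chrom]

        def b_pos(blk: SyntenyBlock):
            if blk.span_b is not None:
                return blk.span_b[0]
            return min(a.index_b for a in blk.anchors)

        members.sort(key=b_pos)
        target_chroms.append(
            tuple(
                label[id(b)] if b.orientation == "same" else -label[id(b)]
                for b in members
            )
        )
    return (
        SignedGenomePermutation(tuple(source_chroms)),
        SignedGenomePermutation(tuple(target_chroms)),
    )
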