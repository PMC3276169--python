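# Methods

## Scope and data model

The package analyses pairs (or trios, with an ancestral gene order) of
annotated genomes the way small pre-WGD yeast genomes are compared: gene
order is the primary signal, sequence is used for GC structure, telomere
repeats, centromere elements and protein identity.  Coordinates are 0-based
half-open throughout; GFF3 input (1-based closed) is converted on read.
The genome-size convention excludes rDNA-class feature spans ("genome size
without rDNA"), because the rDNA array length is an assembly artifact more
than a genome property; all other feature classes count toward length.
Gene density is reported in kb per protein-coding gene at two decimals, the
precision genome tables conventionally print.  N bases count toward length
but never toward a GC numerator or denominator.

## Synteny blocks

An anchor is a one-to-one ortholog pair placed at its ordinal gene position
(protein-coding genes only) on each genome; for an ancestral gene order the
ordinal position and strand sign come from the ancestor list and no bp
coordinates exist on that side.  A block is a maximal run of anchors,
consecutive in genome-A order, that stays on one chromosome pair, keeps one
relative orientation, and whose ordinal index gaps on both sides are at
most `max_gap_genes`.  The direction on B is implied by the orientation
(same → increasing, inverted → decreasing), so a run is colinear by
construction, the run predicate is purely pairwise, and greedy left-to-right
chaining provably yields the maximal-run partition — this is what the
brute-force enumerator cross-checks in the tests.  Defaults:
`max_gap_genes=3` (absorbs small species-specific insertions, tRNAs and
orphan genes that interrupt otherwise colinear runs), `min_anchors=2` (a
single anchor is not evidence of conserved order; such anchors are returned
separately as singletons).  When a gene could extend either of two adjacent
runs the left (lower genome-A span) run takes it, purely for determinism.

Block length statistics are computed on genome-A bp spans (outermost anchor
gene boundaries), also for ancestor comparisons, since the ancestor side
has no physical coordinates.  The mean block length is the mean of block
spans; it deliberately ignores inter-block gaps, so it is not genome length
divided by block count, and published averages computed under an unknown
convention may differ by a few percent.  The half-genome block number H is
computed by sorting blocks by length and accumulating until half the
genome-A length (rDNA excluded) is covered; a test checks this against an
exhaustive subset search.

## GC landscape

Profiles use a 5 kb window sliding at 1 kb; the window dominates the
binomial noise of per-window GC (sd ≈ 0.7 percentage points at 5 kb and
40% GC) while resolving 15 kb features.  The trough threshold is
`mean − z·sd` with z = 1 computed over all windows genome-wide; the
15 kb minimum span is the scale of centromeric AT troughs in these genomes
and is the default `min_trough_bp`.  A uniform-GC genome (sd = 0) yields no
troughs by definition.  Trough spans are unions of qualifying window spans,
so a detected trough extends up to one window beyond the underlying AT-rich
segment on each side; labels (centromere / telomere / internal) come from
overlap with caller-provided annotation and are "none" when no annotation
is given.  Cumulative-deviation segmentation (as in dedicated GC-profile
segmentation tools) was deliberately replaced by this windowed threshold
method: it is transparent, directly parameterized by the trough scale, and
sufficient for troughs that are ≥ 2 sd deep.

## Telomere repeats

Telomere arrays are found by exhaustive period search anchored at the
chromosome end: for each candidate period p ≤ scan/2 the terminal p bp are
the unit and the array grows inward while adjacent copies agree at ≥ 90%
identity (telomere arrays are degenerate; 90% tolerates drift while
rejecting chance matches).  Candidates are ranked by matched bases minus
three times the mismatched bases, counting mismatches against the terminal
unit: a long period cannot then win by absorbing random flanking sequence
into its larger per-copy mismatch allowance (random sequence is ~25%
identical, so absorbed junk scores negative), and a unit that is itself
periodic ties with its divisor and loses to the smaller period.  The
reported period is therefore minimal.  Repeat units are rotation- and
strand-ambiguous, so the canonical form is the lexicographically smallest
rotation on the forward strand, with the canonical reverse complement also
reported; the printed form of a published unit may be a rotation of the
canonical one.

## Point centromeres

The CDEI–CDEII–CDEIII scan is IUPAC-consensus matching on both strands:
CDEI `RTCACRTG` (the *S. cerevisiae* consensus), CDEIII
`TGTTTNTGNTTTCCGAA` (the TGT-rich element around the essential CCGAA
core), separated by an AT-rich spacer of 120–200 bp with AT fraction
≥ 0.8 — the *Eremothecium* CDEII is ~160 bp, roughly twice the
*S. cerevisiae* length, hence the widened bounds.  All consensus strings
and bounds are configurable (`CdeConfig`).  Candidates are ranked by
spacer AT fraction, ties broken toward the leftmost forward-strand call;
one best call per chromosome is returned with the rest listed as
secondary.  The scan is strand-symmetric and translation-invariant (tests
verify both).  Chromosome pairing across genomes then matches centromeres
that lie in (or within 25 kb of) a shared synteny block; a centromere with
no partner is an orphan — the signature of a centromere-loss arm
translocation reducing chromosome number.

## Gene content

Presence/absence partitions each genome's protein-coding set into shared
(ortholog-mapped), species-specific-with-outgroup-homolog, and orphans; the
five categories partition both gene sets exactly, which the implementation
asserts.  Tandem duplications are maximal runs of mutually paralogous genes
with at most one intervening unrelated gene (`max_intervening=1`) and
pairwise identity ≥ 30% — unspecified conventions chosen permissively
enough for loci of two to four members; a duplication in genome A counts as
conserved when at least two members have orthologs inside one duplication
locus of genome B.  Protein identity uses global alignment with fixed,
non-configurable scoring (match +1, mismatch 0, gap open −10, extend −1;
identity = matches / alignment columns × 100) so that identity values are
bit-reproducible; whether published identity distributions derive from
global or local alignments is rarely stated, and global alignment is the
choice here, documented rather than tuned.  The histogram uses 5%-wide bins
over [20, 100].  Introns validate against the 5′-GT…TACTAAC…AG-3′ rule
with the branch motif required to end at least 3 bp before the acceptor.

## Rearrangement scenarios

Blocks become signed elements, numbered along genome A; chromosomes are
unordered but orientation is observable — turning a chromosome end-for-end
is counted as one (whole-chromosome) inversion, so a target `(−1)` is one
operation away from `(+1)`.  The operation alphabet is exactly the event
vocabulary used when describing these genomes: inversions, reciprocal
translocations (both join pairings), telomeric translocations (a terminal
arm moved onto another chromosome's telomere, in any orientation), fusions
and fissions; transpositions are deliberately absent.  Breakpoints are
adjacencies (telomere caps included) present in the source but not the
target, normalized so a flipped adjacency compares equal.
`minimal_scenario` runs iterative-deepening A* with the admissible bound
⌈breakpoints/2⌉ (one operation changes at most two adjacencies);
operations are tried in sorted encoding order at every depth, so the first
scenario found is both provably minimal and lexicographically first among
minimal scenarios, and every result is re-applied to the source and checked
against the target.  The search is exhaustive by design and refuses more
than 10 elements (`max_elements`); breakpoint counts remain available at
any size.  No polynomial-time reversal-distance machinery is included —
the intended instances are the handful-of-blocks chromosome histories one
reconstructs by hand.

## Synthetic genomes

The simulator generates the study conditions at one tenth of the real
genome scale so the full pipeline runs in seconds: 8 chromosomes × 60
genes (≈ 4800 genes at full scale), mean gene 1.45 kb and spacer 0.56 kb
(≈ 2.05 kb/gene), background GC 40.3%, an 18 kb centromeric trough at 25%
GC (deeper than 2 sd of the window distribution, wider than the 15 kb
detection minimum) containing a planted CDEI + 160 bp 90%-AT CDEII +
CDEIII cassette in random orientation, 16-copy tandem arrays of the 24 bp
telomere unit at both ends, ~2 tRNAs per chromosome, and an intron in 5%
of genes.  Defaults for the evolutionary history mirror the species-pair
divergence at the same 1/10 scale: 8 inversions, 2 reciprocal and 1
telomeric translocation, 1 centromere-loss arm translocation (8 → 7
chromosomes with no gene loss), 3% per-gene loss (~150 of ~4700 genes at
full scale), 3 tandem duplications, intergenic contraction to 70%
(genome streamlining concentrated in spacers), and a 0.4 per-site protein
substitution rate giving ~60% mean ortholog identity.

Sequences are i.i.d. bases at the target GC and proteins are random
strings diverged by substitution only — sufficient to exercise GC and
identity statistics, but carrying none of the codon structure, indels,
repeat families or rate heterogeneity of real genomes; passing recovery
tests therefore demonstrates correctness of the inference chain on its
own assumptions, not performance on real data.  Structural events operate
on a typed segment list (telomere / intergenic / gene / centromere) with
cuts at segment boundaries inside intergenic spacers, so genes are never
truncated; inversions stay within one chromosome arm and are kept mutually
non-adjacent so each contributes two clean breakpoints; translocation cuts
keep exactly one centromere per product; arms moved onto telomeres keep
their telomere facing outward (the recipient's old telomere becomes
interstitial repeat sequence, and a donor's broken end is left without a
telomere, as unhealed ends are in real assemblies).  The fixed event order
— rearrangements, duplications, losses, intergenic contraction — plus
full event coordinates in the log make the log replayable: `replay`
re-applies the recorded events and reproduces the descendant genome
byte-exactly (a test asserts this).  Protein divergence is applied after
the structural phase and is recorded as realized per-pair identity in the
ortholog map rather than as per-site mutations in the log, keeping the
log compact; replayed objects therefore carry ancestral proteins.
`expected_synteny_segments` computes ground-truth colinear segment counts
directly from the gene-position truth tables, independently of the anchor
chainer, which is what the recovery tests compare against (with
`max_gap_genes=0`, single-gene truth segments correspond one-to-one to
singleton anchors).

## Numerical and degenerate-input choices

Zero genes → gene density is reported absent rather than dividing by zero.
All-N windows get NaN and break trough runs.  Empty protein sequences skip
their ortholog pair with a record of the skip.  Identity values, GC
fractions and densities are plain floats; the only rounding applied is the
printed-precision rounding of density (2 decimals) and mean block length
(1 decimal).  All simulator randomness flows through one seeded generator
per phase (`default_rng([seed, 0])` for the ancestor, `[seed, 1]` for the
evolution), so a configuration and seed fully determine every output byte.

## Known limitations

Ancestor-side block statistics have no bp scale, so "mean block length" is
always a genome-A quantity.  The neighborhood comparison anchors the
homologous locus by majority chromosome vote and an ordinal window; a
locus split across two B chromosomes is reported as rearranged rather than
resolved.  The tandem-duplication scanner closes a run when it meets a
gene that has paralogs elsewhere but not in the run, which can split
interleaved families.  The telomeric-translocation model appends arms
beyond existing telomere arrays rather than resecting them.  The scenario
search is exponential by design; ten blocks is a hard default ceiling.
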