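# eremosyn

Comparative genomics of small pre–whole-genome-duplication (pre-WGD) budding
yeast genomes, built around the *Eremothecium* species pair
(*E. cymbalariae*, eight chromosomes, ~9.7 Mb, 40% GC; *A. gossypii*, seven
chromosomes, ~8.8 Mb, 52% GC) and the reconstructed yeast ancestor.  The
package is aimed at people who have two (or more) annotated genomes plus an
ortholog table and want the standard desk analyses of such a comparison:

- **Genome statistics** — chromosome count, genome size without rDNA, gene
  count, gene density (kb/gene), coding fraction, intron and tRNA counts, GC
  content.
- **Synteny blocks** — one-to-one ortholog pairs become *anchors* at their
  ordinal gene positions; a *block* is a maximal run of anchors, consecutive
  on genome A, on one chromosome pair, with consistent orientation and
  ordinal gaps ≤ `max_gap_genes` on both genomes.  Block tables report
  per-chromosome counts, mean block length, and the half-genome block number
  *H* = the smallest *k* such that the *k* largest blocks cover ≥ 50% of the
  genome.
- **GC landscape** — sliding-window GC profiles (5 kb window, 1 kb step) and
  troughs: maximal runs of windows below `mean − z·sd` spanning ≥ 15 kb,
  labeled centromeric / telomeric / internal.  Point centromeres of these
  yeasts sit in AT-rich troughs of at least 15 kb.
- **Telomeres and centromeres** — minimal-period tandem-repeat inference at
  chromosome ends (the *E. cymbalariae* unit is the 24 bp
  `CACACCGCTGAGAGACCCGTACAC`, reported as its canonical rotation), and
  point-centromere detection with the CDEI–CDEII–CDEIII model (AT-rich CDEII
  spacer of ~160 bp, twice the *S. cerevisiae* length).
- **Gene content** — presence/absence classification against an outgroup,
  tandem-duplication detection and cross-species conservation, global-
  alignment protein identity distributions, and the
  5′-GT…TACTAAC…AG-3′ intron splice rule.
- **Rearrangement scenarios** — block orders as signed permutations,
  breakpoint counts, and provably minimal event scenarios (inversions,
  reciprocal and telomeric translocations, fusions, fissions) by exhaustive
  IDA* search on desk-scale instances (≤ 10 blocks).
- **Simulator** — `synthetic_genomes` builds ancestor/descendant genome
  pairs with planted centromeres, telomere arrays, AT-rich troughs, and a
  replayable ground-truth log of inversions, translocations,
  centromere-loss arm translocations, gene losses and tandem duplications,
  so every analysis above can be validated against known truth.

## Worked example

Simulate a genome pair under the default study conditions (8 chromosomes ×
60 genes, one centromere-loss event, 3% gene loss, 40% mean protein
divergence) and chain synteny blocks:

```python
from eremosyn.synthetic_genomes import SimConfig, simulate_ancestor, evolve
from eremosyn import synteny

cfg = SimConfig(seed=1)
ancestor = simulate_ancestor(cfg)
descendant, orthologs, log = evolve(ancestor, cfg)

anchors = synteny.build_anchors(ancestor.genome, descendant.genome, orthologs)
blocks, singletons = synteny.chain_blocks(anchors, max_gap_genes=0)
stats = synteny.block_statistics(blocks, ancestor.genome)
print(len(descendant.genome.chromosomes), stats.total, stats.mean_length_kb,
      stats.half_genome_blocks)
```

prints

```
7 48 19.5 14
```

— the descendant has 7 chromosomes (one centromere was lost, its arms
translocated onto two other chromosomes without losing a gene), the
ancestor maps onto it in 48 synteny blocks of mean length 19.5 kb, and the
14 largest blocks cover half the ancestral genome.  Telomere inference on
any chromosome end recovers the 24 bp unit:

```python
from eremosyn.telomere_centromere import infer_telomere_repeat
unit = infer_telomere_repeat(ancestor.genome.chromosomes[0], "right", scan_bp=600)
print(unit.period, round(unit.copy_number, 1), unit.unit)
```

```
24 16.1 ACACCACACCGCTGAGAGACCCGT
```

The same steps run from the shell: `eremosyn simulate --seed 1 --out sim/`,
`eremosyn stats --genome sim/ancestor.fa --ann sim/ancestor.tsv`,
`eremosyn synteny --a sim/ancestor.fa sim/ancestor.tsv --b sim/descendant.fa
sim/descendant.tsv --orthologs sim/orthologs.tsv`, or everything at once via
`eremosyn all --config cmp.yaml --out report/`.

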