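# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open; BED is consumed as-is,
GFF3 is converted on parse (start−1, end) and never afterwards. Ortholog
tables are BUSCO-like TSVs with an explicit strand column: orientation
is an input requirement because anchors and blocks are signed, and
deriving strand would require an aligner. SAM is read as text through
pysam; unmapped, secondary and supplementary records never contribute to
CQ counts. Contig N50 splits scaffolds at runs of ≥10 consecutive Ns;
the gap convention is not standardized across assemblies, so the
threshold is a parameter. N50 is the length of the shortest sequence in
the smallest set of longest sequences jointly covering at least half the
total.

## Anchors and synteny blocks

Single-copy filtering keeps an ortholog only when it has exactly one
single-copy placement in every species. Orthologs whose intervals
overlap (or are bookended, gap 0) anywhere are grouped by transitive
overlap; a group merges into one anchor only when, in **every** species,
its members lie on one chromosome, form a gap-free chain, and keep one
relative order and orientation (collinear, or jointly reversed with all
strands flipped). Conflicting groups are discarded entirely and logged:
partial overlaps cannot be polarized without sequence alignment, so
trimming would manufacture coordinates. De-duplication (gap 0) and
chaining (gap budget) are deliberately separate stages.

Chaining walks anchors along a designated reference species and joins
neighbours that are (a) co-chromosomal in every species, (b) within the
gap budget — 750 kb against the **sum** of per-species gaps by default;
a per-species maximum is available because the multi-genome reading of a
total-gap parameter is ambiguous — and (c) order/orientation-consistent
in every species. Maximal runs of at least 2 anchors become blocks.
Consequence: a boundary between ancestral blocks that no species
disrupts is invisible, and the two blocks legitimately merge; pairwise
reversal distances are unchanged because the collapsed adjacency is
shared by all genomes.

Arms are assigned to chromosomal elements by majority (>0.5) of block
span mapped back to labeled reference chromosomes; a secondary element
above 0.10 flags a mosaic arm (the threshold is this package's choice —
mosaicism in the literature is qualitative). Two-armed chromosomes then
yield unordered element pairings, and pairings that differ between
species are reported as whole-arm translocation events.

## Reversal distance

Signed permutations are framed with 0 and n+1 and doubled (+x →
(2x−1, 2x), −x → (2|x|, 2|x|−1)). Cycles are traversed directly; gray
edges are classified oriented when their position sum is even;
components come from the pairwise edge-interleaving relation (O(n²),
negligible at the block counts involved). For hurdles the frame is
closed into a circle and a component is a hurdle iff its positions form
one contiguous arc among unoriented-component positions; a hurdle is a
super-hurdle iff deleting it turns a non-hurdle into a hurdle; a
fortress needs an odd number of hurdles, all super. The full formula
n+1−c+h+f (not the cycle-only lower bound) is used, and its correctness
is arbitrated by an independent exhaustive oracle: one breadth-first
sweep over the entire group of signed permutations (memoized per n,
n ≤ 8; the n=8 group has 10,321,920 states, swept vectorized in numpy
with states packed into int64). Agreement is exhaustive for n ≤ 6 and
spot-checked at n = 8.

Sorting scenarios take, at each step, a distance-reducing reversal —
shortest span first, leftmost on ties — mirroring searches that detect
the smallest inversions first; the alternative `any` policy takes the
first reducing reversal in scan order. Tie-breaks are fixed so scenarios
are reproducible.

## Ancestral reconstruction

The tree is fixed: ((An_albimanus, An_coluzzii), (Cx_quinquefasciatus,
Ae_aegypti)), one signed permutation per chromosomal element
(paracentric-only model; arm exchanges are handled by the association
detector, not by reversal distance). Reconstruction is greedy and
tree-aware: within each cherry, reversals that reduce the sister-sister
distance are applied, preferring the one that maximally reduces the
summed distance to all other genomes (ties: smallest span, leftmost,
species order); this peels leaf-branch events and terminates exactly at
the cherry node, because shared deeper events do not reduce the
sister-sister distance. The two cherry ancestors are then walked toward
each other along a minimum scenario and the meeting point is the
inferred root, splitting the steps as evenly as possible (the odd step
going to the first cherry). Branch counts are attributed as events are
undone and always sum to the total scenario length.

Known limitation, by design: four leaves cannot polarize the internal
path — undoing a cherry1-side internal event and applying a cherry2-side
one change all leaf distances identically — so the root's position on
that path is unidentifiable and the balanced split bounds the placement
error by half the internal path length. With up to two events per
internal branch the estimate is within one inversion of the true root in
roughly 80–88% of simulations; no estimator can do substantially better
without an outgroup. An exact exhaustive median (n ≤ 6) is provided as a
test oracle only.

## Rates

Rate = inversions / (repeat-masked arm Mb × MY). Two normalizations are
always emitted — per-Mb-per-MY and additionally per synteny block —
because both denominators are in circulation; consumers pick one and
must not mix them. Arm sizes are config inputs (a helper subtracts
masked bp); divergence times default to 134.6 MY (root) and 62.3 MY
(*Culex*/*Aedes*), both settable since round-number variants (136, ~69)
also circulate. Sex-to-autosome ratios divide the sex-linked element's
rate by the unweighted mean of autosomal rates per lineage; for
Culicines the two arms of chromosome 1 are reported separately.

## Chromosome quotient

Defaults follow the published filter chain: 1-kb fragments over the
(already masked) assembly, windows ≥90% masked dropped, fragments with
<10 male alignments excluded (small-denominator bias; their CQ is
reported as missing, never 0 or ∞), CQ < 0.05 flags male-specific.
Region calling is this package's addition — the published region was
read off a dot plot — and merges flagged fragments within 100 kb,
keeping regions of ≥5 fragments; defaults resolve a multi-Mb region at
1-kb granularity. At 20× depth the Poisson tails make a false positive
essentially impossible (CQ < 0.05 with ≥10 male alignments needs a
near-zero female count against a mean of ~130), which the Monte-Carlo
tests confirm.

## Landscapes

Each arm is split into 50 equal-width bins (the published phrasing
"50 bins of different lengths" is read as equal within an arm, differing
between arms; no alternative is stated), the last bin absorbing the
remainder, oriented centromere→telomere via a declared centromere end.
Masking precedence is satellite > low-complexity > TE classes > gene,
matching the masking order in which annotations are produced; within a
class intervals are unioned. Genes are profiled untrimmed — gene and
repeat tracks are independent — while composition partitions the genome
into disjoint repeat fractions plus the single-copy remainder, which
sums to 1 by construction.

## Synthetic data

The generator produces what the analysis consumes, with known truth:

* **Karyotypes** — ancestral identity orders per arm evolved down the
  tree; reversal breakpoints uniform (no empirical inversion length
  spectrum exists to emulate, so the simplest null is used); optional
  whole-arm exchanges on a 3-chromosome, 6-arm karyotype. Blocks emit ≥2
  ortholog hits each (2-kb genes, 1-kb intra-block gaps, 20-kb
  inter-block gaps — comfortably inside the 750-kb budget) with strands
  consistent with block orientation.
* **Sex coverage** — Poisson counts at mean depth × fragment/read-length
  (defaults 20×, 1 kb, 150 bp → mean ≈ 133); inside the hemizygous
  region the male mean halves and the female mean drops to a
  configurable mismapping leak (0 by default). A negative-binomial
  switch provides overdispersion.
* **Annotations** — per-bin target coverage placed exactly (randomness
  shuffles positions, not amounts), repeat classes in masking order into
  space left by higher classes, genes independently.

What this does *not* emulate: sequence-level noise, missing or
fragmented orthologs, assembly errors, inversion length bias,
GC/mappability structure in coverage, or TE family structure. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the stated generative model, not robustness to real
annotation noise.

## Problem sizes

The shipped tests and the acceptance script use: exhaustive oracle
comparison at n = 6 (46,080 permutations) plus 200 seeded n = 8 draws;
planted-distance recovery at n = 50 blocks, k = 1..10, 100 replicates
per k; ancestor recovery at n = 30, 50 replicates; CQ scans over 15–70
Mb of 1-kb fragments at 20×, 10 seeds; landscapes over 10-Mb arms. These
sizes were chosen so the whole battery completes in minutes while every
regime of the theory (hurdles, fortresses, merged blocks, region edges)
is exercised.
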