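# Methods

## Coordinate conventions

All in-memory intervals are 0-based half-open. GFF3 input (1-based
inclusive) is converted on load and converted back when fixture files are
written; BED is consumed as-is. One internal convention keeps interval
arithmetic consistent across modules.

The representative transcript of a gene is the mRNA with the longest
summed CDS, ties broken by lexicographically smallest transcript id, and
its protein length is the CDS length in codons. Annotation dialects vary;
unknown feature types are tolerated and tallied rather than rejected.

## Ortholog-link classification

The classifier is deliberately simple and auditable, in three ordered
steps:

1. **Noise filter** — keep a hit iff identity ≥ `min_identity` (default
   90.0%) and aligned length ≥ `min_align_len` (default 150 aa). The
   defaults express "remove < 90% or < 150 aa", so equality at either
   boundary is kept. Filtering precedes uniqueness counting: a gene with
   one strong hit plus several noisy ones still qualifies as single-copy.
2. **HSP collapsing** — multiple local alignments between the same two
   genes are one similarity relationship, represented by the
   highest-bitscore HSP (ties: higher identity, then smaller subject id).
   Self-hits and within-genome hits are ignored.
3. **Single-copy test** — a gene qualifies when it hits exactly one gene
   in the other genome. The default `reciprocal` mode also requires the
   partner's only hit to point back, which makes the output symmetric
   under swapping the genomes and guarantees no gene appears twice. The
   literal one-directional variant is kept as `one_way`; there a genome-B
   gene can be the unique target of two different genome-A genes.

Qualifying pairs become links carrying both genes' coordinates and an
orientation (+1 same strand, −1 opposite).

## Synteny chaining and rearrangement calling

Links are grouped by chromosome pair and chained greedily in genome-A
order. A link extends the open chain iff the genome-A rank gap and the
absolute genome-B rank step are both in (0, `max_gap_genes`] (default 10)
and the genome-B step keeps the chain's direction. Grouping by chromosome
pair first means an interposed translocated segment does not interrupt
the chain of its host chromosome — this is also what makes chaining
invariant under relabeling the two genomes. A one-link lookahead resolves
boundary links: a candidate that could extend the chain only via a large
genome-B jump, while pairing tightly with the next link in the opposite
direction, starts the new (inverted) chain instead of being absorbed.
Chains shorter than `min_block_links` (default 5) are reported as
unchained leftovers.

**Inversions**: per chromosome pair, the dominant orientation is the one
carrying the majority of links — block links vote with their chain
direction, leftover links with their strand-product orientation (ties go
to +1, with a warning). Each minority-orientation block with ≥
`min_event_links` (default 5) links is one call. A chromosome pair that
is entirely inverted is its own dominant context and yields no calls.

**Translocations**: each genome-A chromosome's dominant partner is the
genome-B chromosome carrying most of its links (and symmetrically for
genome B; ties to the lexicographically smallest name). Blocks off the
dominant partner on either side, with ≥ `min_event_links` links, are
called; candidate blocks on the same chromosome pair with overlapping
genome-A spans merge into one call per contiguous region.

## Cross-genome projection and centromere origin

An interval is projected through its nearest flanking links: the closest
link entirely to its left and entirely to its right on its own genome.
If both exist and their partner genes share a chromosome, the projection
spans the gap between the partner genes' inner (gene-proximal) edges —
conservative bounds that work for collinear and inverted flank order
alike. Missing flanks (chromosome ends), partner-chromosome disagreement,
or overlapping partner genes yield no projection.

A genome-B centromere unit is classified:

- `corresponding` — its projection overlaps a genome-A unit with overlap
  ≥ `min_overlap_frac` (default 0.1) of the smaller interval. The
  threshold is a knob: the underlying biological claim is qualitative.
- `de_novo_insertion` — the projection exists, overlaps no genome-A unit,
  and both flanking links belong to one block (or two blocks that are
  adjacent continuations on the same chromosome pair): the unit splits an
  otherwise contiguous syntenic block, so it must have been inserted
  after divergence.
- `unresolved` — anything else.

## Satellite analysis

**Dyad symmetries.** All maximal inverted repeats with arm length ≥
`min_arm` (default 4), loop ≤ `max_loop` (default 12) and mismatches ≤
`max_mismatch` (default 0). Only Watson–Crick pairs count; N never pairs.
Every pair of a dyad lies on one anti-diagonal (the paired positions sum
to a constant), so maximality — no dyad whose pair set strictly contains
another reported one — is enforced per diagonal. The defaults are
conservative enough to verify against exhaustive enumeration, and the
test-bed does exactly that for every sequence length up to 80.

**Hairpin score.** A transparent stem-loop score, not a thermodynamic
folder: 3 per G:C pair, 2 per A:T pair, minus 0.5 per loop base beyond
`min_loop` (default 3), maximized over all perfectly paired folds with
loop ≥ `min_loop` (ties: longest stem, then leftmost). It is a proxy for
hairpin-forming potential and is documented as such; no equivalence to
any folding program is claimed.

**Shared motifs.** All longest common substrings between two monomers via
binary search on the common-substring length. `circular` searches each
monomer doubled, so junction-spanning motifs are found, with match length
capped at the shorter monomer; `include_revcomp` also searches the
reverse complement of the second monomer and reports motifs in the first
monomer's frame.

**Array decomposition.** Greedy tiling: at each position the consensus
and its reverse complement are aligned to a prefix of the remaining
sequence by banded edit distance (edlib, band = 20% of the monomer
length); the better orientation is accepted when identity =
100·(1 − distance/monomer length) reaches `min_identity` (default 80%),
otherwise the scan advances one base. Greedy tiling is linear-ish in
array length and deterministic; it is not an optimal segmentation, which
matters only near heavily decayed copies.

**HOR detection.** Mean pairwise identity between (forward-oriented)
monomers at lag L for L = 1..min(20, n/2). The HOR period is the smallest
L ≥ 2 whose mean exceeds the lag-1 mean by ≥ `margin` (default 5
percentage points) and reaches `hor_min_identity` (default 85%); a
homogeneous tandem (lag-1 identity already at the floor, no higher-order
signal) reports period 1; otherwise none. With planted variants at ~85%
between-variant identity and ≤ 5% per-copy mutation, the within-variant
lag sits near 90% and the between-variant lag near 77%, so the defaults
separate the two regimes with margin to spare; at least 8 monomers are
required for the lag means to be meaningful.

## ChIP enrichment

Cluster enrichment is the ratio of library-size-normalized proportions
with a pseudocount (default 1 read) added per cluster/window before
normalization — zero-count input bins stay defined, and the statistic is
invariant to rescaling both library sizes. The window track is
log2 of the same normalized ratio per fixed-width window (default 1 kb).
The segment caller takes maximal runs of windows ≥ threshold, merges runs
separated by ≤ `merge_gap` sub-threshold windows, and drops merged runs
spanning < `min_len` windows; it stands in for model-based peak calling
at the resolution the track provides. Spike-in normalization and
read-level processing (mapping, duplicate handling, MAPQ filtering) are
upstream of this module; counts are taken as given.

## The synthetic-data generator

The generator emulates the comparative design end to end and is the
package's source of ground truth:

- **Genomes.** Genes on a uniform grid (1.2 kb genes, 10 kb spacing) —
  rank-based synteny logic is coordinate-scale-free, so the grid is
  arbitrary but fixed. Defaults: 4 chromosomes × 60 genes, 3 inversions
  and 4 translocations of 5–10 genes, proteins at 95% identity, 7
  centromere insertions (50 kb, gene-free) in genome B, 1 centromere
  interval elsewhere in genome A. Planted events are non-overlapping in
  gene ranks; translocation insertion sites keep > `max_gap_genes`
  clearance from earlier inserted runs so planted events remain
  distinguishable as separate blocks, and centromere insertions sit
  inside runs of consecutive event-free genes so each unit genuinely
  splits one block. Protein mutation substitutes exactly
  round(length × (1 − identity)) positions, so realized identity is
  exact.
- **Hits.** Alignment tables are emitted directly from the truth (one hit
  per pair and direction at the realized identity, plus sub-threshold
  noise hits), keeping the pipeline aligner-agnostic. An aligner's
  scoring quirks, partial-length HSPs, and compositional biases are
  therefore not modeled — the tests validate the classification logic,
  not alignment behavior.
- **Satellite arrays.** `hor_period` divergent variants of the monomer
  (default per-base divergence 0.08, chosen because two sequences each
  mutated at rate d from a common ancestor have expected identity
  1 − 2d(1−d) − (2/3)d², ≈ 85% at d = 0.08) cycle along the array; each
  copy then receives independent per-base substitutions. Orientation
  flips reverse-complement individual copies in place; indels and
  monomer-length variation are not modeled.
- **ChIP counts.** Input ~ Poisson(depth) per window; ChIP ~
  Poisson(depth × enrichment) inside planted blocks. No overdispersion,
  GC bias or mappability structure — the tests show estimator
  calibration under the model, not robustness to real-library artifacts.

All generators are pure functions of (config, seed); reruns are
byte-identical. Passing tests therefore demonstrate correctness of the
algorithms on data matching the generative model, not performance on real
assemblies, where alignment noise, tandem duplications, and fragmented
scaffolds add failure modes the model omits.

## Numerical and design choices

- Mean chromosome size summaries round half-up to one decimal
  (e.g. 887/12 → 73.9, 789/10 → 78.9 Mb).
- Tabular numeric columns are parsed with a correctly rounded
  string-to-double conversion so write/read round-trips are exact.
- The links TSV carries nine positional columns for plotting tools plus
  gene/protein/score columns that make it a lossless serialization of the
  in-memory links.
- All tie-breaks (dominant orientation, dominant partner, HSP choice,
  hairpin folds) are deterministic and documented at the function level;
  ties in dominance warn.
- Problem sizes in the test-bed (240-gene genomes, 100-monomer arrays,
  10⁴–3×10⁴-window tracks, brute-force oracles at n ≤ 80–100) were chosen
  so exhaustive oracles remain feasible while leaving all planted-truth
  conditions at their stated values.

## Known limitations

- The rearrangement caller reports block-level events only: breakpoints
  are gene-rank-resolved, fission/fusion typing and nested events are out
  of scope.
- Greedy chaining can mis-assign a boundary link in adversarial
  configurations the one-link lookahead does not cover.
- The centromere-origin classifier depends on flanking links; units in
  link deserts (chromosome ends, repeat-rich regions) come back
  `unresolved` rather than being guessed.
- The hairpin score ranks folds plausibly but has no thermodynamic
  calibration.
- Array decomposition assumes a known consensus; it does not discover
  monomers de novo.
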