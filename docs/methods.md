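# Methods

This note documents the algorithms, parameter choices and numerical
conventions behind `minscaff`, and what the simulated studies do and do
not establish.

Conventions used throughout: coordinates are 0-based and half-open,
strands are `'+'`/`'-'`, and all randomness flows through explicit integer
seeds (`numpy.random.default_rng`). Identical inputs and configuration
produce byte-identical outputs; no algorithmic decision depends on
wall-clock time or hash iteration order.

## Minimizer sketching

A sketch is the ordered list of window minimizers of a sequence: for every
window of `w` consecutive k-mer start positions (slid one position at a
time) the k-mer with the smallest hash is selected, and duplicate
selections from overlapping windows are collapsed.

*Hashing.* Each base contributes a fixed 64-bit constant barrel-rotated by
its offset within the k-mer, XOR-combined — a classic rolling nucleotide
hash, computed here for all positions at once with a prefix-XOR trick
(rotate each position's constant by its absolute offset, prefix-XOR,
window-difference, counter-rotate). The canonical hash is
`min(hash(kmer), hash(revcomp(kmer)))`, so a k-mer and its reverse
complement always collide by construction; the recorded strand is `'+'`
when the forward k-mer is the canonical representative (ties report
`'+'`). Any deterministic canonical hash family would do — mapping
depends only on exact matching — and the constants are arbitrary. A
scalar, non-rolling reference implementation (`canonical_hash`) exists
solely so tests can cross-check the vectorised path.

*Numerical details.* Ties within a window select the leftmost occurrence
(deterministic, order-preserving). K-mers containing N are excluded; a
window with no valid k-mer emits nothing. Sequences with at least one but
fewer than `w` k-mers form a single degenerate window, so short sequences
remain sketchable. Sequences shorter than `k` give an empty sketch.

*Index.* Only minimizers whose hash occurs exactly once across all contig
sketches are indexed; repeated minimizers would map ambiguously into
repeats and are discarded.

Defaults are `k = 32`, `w = 100`; the `sweep` subcommand searches
k ∈ {24, 32, 40} × w ∈ {100, 250, 500} by NG50, a grid that works well
across assembly types. The simulated studies in the tests use `k = 24`
(with 5%-error reads, the probability that a 24-mer is error-free,
0.95²⁴ ≈ 0.29, leaves roughly 80–90 matching minimizers per 15-kb read —
comfortably above the couple of anchoring matches a join needs).

## Read mapping and pair inference

Each read minimizer found in the index yields a match; adjacent matches to
the same contig are collapsed into runs, giving the read's ordered contig
footprint. Runs are filtered by minimum contig size `z` (default 1000 bp;
small contigs are disproportionately repetitive and only add graph noise)
and by *subsumption*: a run whose read-coordinate interval lies inside
another run's interval orders nothing and is dropped. Subsumption is
judged on read coordinates (the natural frame: it asks whether the contig
contributes ordering information along the read). Filtering and re-merging
are iterated to a fixed point, making the filter idempotent by
construction.

A run's orientation is the majority vote of per-match strand agreement
between read and contig. Runs with tied votes, or with any internal
strand disagreement (an apparent inversion within the run), are excluded
from pairing — their orientation evidence is untrustworthy, and with
exact 64-bit matching such disagreements essentially only arise from
genuine structural conflict.

For a filtered run list of length m ≤ `f` (default 10), every ordered pair
(i, j), i < j, is emitted — adjacent and transitive. For m > `f`,
adjacent pairs are always emitted and a transitive pair only when every
intervening run is weakly supported (a single minimizer hit), bounding the
combinatorics on repeat-dense reads.

*Orientation and gap.* For a pair (cA, cB) the terminal minimizers are
mA, the last match of cA's run, and mB, the first match of cB's run. cA
is `'+'` iff mA has the same strand on the contig and the read (likewise
cB with mB). With read positions rA ≤ rB and oriented contig positions
pA′ = pA (or LA − k − pA when flipped), pB′ likewise:

    gap = (rB − rA) − (LA − pA′) − pB′

i.e. the read-space distance between the terminal k-mer starts minus the
stretch of each contig between its minimizer and the joined end. The
algebra cancels exactly on error-free reads (verified by the planted-gap
simulations); on noisy reads the error is the read's local indel drift
over the spanned distance (≈ √(0.06 · d) bp standard deviation at 5%
error with balanced indels — tens of bp at typical spans). Transitive
pairs use the same formula; the read-coordinate difference already spans
the intervening contigs, so their lengths are not subtracted. Pairs are
recorded in read-coordinate order; the reverse twin is materialised by
the graph.

## The scaffold graph

Nodes are oriented contigs (every contig twice). Each tallied pair exists
together with its twin (B^¬oB → A^¬oA); edges are stored once under a
canonical key with the twin view generated on access, so the two
directions cannot drift apart — twin symmetry is asserted as a graph-wide
invariant after every mutation in the tests.

Edge weights: `read_support` counts **distinct** supporting reads (a read
producing the same pair twice through different run splits counts once);
`anchor_support` counts distinct anchoring reads (≥ 2 minimizers on both
contigs); the gap is the lower median (sorted index ⌊(n−1)/2⌋) of all
per-read estimates — integer-valued and deterministic. Edges with
`anchor_support` below `a` (default 1) are noise and removed.

## Layout

For a support threshold n: edges below n are dropped; then edges whose
gap estimate is consistent with a two-hop path are removed — an edge
u → x is transitively explained when some v satisfies u → v → x with
`gap(u,x) ≈ gap(u,v) + len(v) + gap(v,x)` within 500 bp. This resolution
step is a deliberate design choice: the pairing stage *intentionally*
emits transitive pairs, so any layout of this graph must recognise them,
and the gap algebra makes the recognition exact rather than topological.
The 500-bp slack is far below the minimum intervening contig length
(≥ z = 1000 bp), so a true adjacent edge cannot be explained away; noisy
estimates drift tens of bp, far below the slack. Judged against the
pre-removal edge set, so the outcome is order-independent; symmetric for
twins because gaps and lengths are.

Remaining ambiguous nodes (out-degree > 1 or in-degree > 1) have all
edges on the ambiguous side removed — correctness over contiguity; a
wrong join is worse than a missed one. The surviving graph is a disjoint
union of simple oriented chains; each chain coexists with its
reverse-complement twin and is reported once (the lexicographically
smaller of the two), unplaced contigs become `'+'` singletons, and rare
cycles are broken deterministically at their smallest node. No contig is
duplicated or dropped.

The threshold n is swept (default 1..50, stopping early once no edge
survives) and each layout scored by NG50 of its scaffold lengths (contig
lengths plus clamped gaps) against the supplied genome size G; ties
prefer the smallest n. Gap runs shorter than `min_gap` = 20 (including
negative estimates, i.e. overlaps) are printed as 20 Ns — downstream
tools require at least one N — while the raw estimate is preserved in the
AGP/DOT metadata.

## Correction

Long reads are tiled from position 0 into non-overlapping
`fragment_size` = 500 bp fragments (trailing remainder discarded); each
fragment yields an FR-oriented pair of 250-bp mates and all pairs from a
read share its barcode. Mates are placed with the internal minimizer
mapper at `k = 24, w = 10` (dense windows suit 250-bp reads; an external
aligner would add nothing at this granularity) on the contig collecting
most of their minimizer hits, requiring ≥ 2 hits for a confident
placement.

Same-barcode placements on a contig merge into a molecule extent when
consecutive placements start within `dist` of the previous end; extents
with fewer than 2 supporting placements are discarded as noise. With
`dist` = median read length, all of one read's tiles virtually always
merge into one extent per contig — the intended proxy for the read's span.

A position p is *bridged* by an extent when `start < p − clearance` and
`end > p + clearance`, with `clearance` = fragment_size/2 = 250 bp
absorbing the tiling and sketch-phase jitter at extent ends. Positions
bridged by fewer than `span` extents are unsupported; maximal unsupported
stretches in the contig interior are cut at their midpoint (unbiased in
the absence of base-level evidence). The first and last
`terminal_exempt` = `dist` bp are exempt — no molecule can bridge past a
contig end. `span` = 0.25 × coverage, auto-computed from total read bp
and G (round half up, minimum 1). Fragments shorter than 100 bp after
cutting are dropped and logged. These defaults make clean, error-free
simulations cut-free while placing cuts within a few hundred bp of
planted chimeric junctions.

At a chimeric junction the draft joins sequence from two distant genomic
regions; molecules sampled from the true genome end on one side or the
other, so no extent bridges the junction and the unsupported stretch is
centred on it — the detection signal is geometric, not statistical, which
is why detection is near-exact once a junction lies outside the
terminal-exempt zone.

## What the simulations do and do not show

The synthetic genomes are i.i.d.-base sequences: effectively repeat-free
at the scale of a 24-mer, with every minimizer unique. The read model is
uniform sampling, lognormal lengths and i.i.d. errors (40/30/30
sub/ins/del) — no homopolymer bias, chimeric reads, or coverage dips.
Passing the recovery criteria therefore demonstrates the correctness of
the machinery (hashing, mapping geometry, orientation/gap algebra, graph
and layout logic, span/dist bookkeeping), not performance on repetitive
real genomes, where unique-minimizer density inside repeats, not
algorithmic bookkeeping, becomes the limiting factor — the motivation for
the k/w sweep.

Problem sizes in the test suite and acceptance script (1-Mbp genome,
25 contigs, 20× coverage, 10 planted junctions) were chosen as the
smallest study at which every stage operates in its intended regime:
contigs much longer than reads (so transitive pairs are rare but
present), reads much longer than fragments, and junctions outside the
terminal-exempt zone.

## Known limitations

- Ambiguity resolution deletes all competing edges; a dominant-edge
  heuristic (keep an edge with ≥ 2× the runner-up's support) is a
  possible opt-in but is deliberately not the default.
- Negative gap estimates (overlapping contigs) are reported but the
  overlap is not merged at sequence level; the scaffold prints `min_gap`
  Ns instead.
- The pseudo-linked read output is consumable by downstream linked-read
  scaffolders (for which small k ≈ 20 and a Jaccard threshold ≈ 0.05 are
  appropriate), but no such second scaffolding pass is implemented here.
- FASTQ qualities are parsed and ignored: every algorithm is
  quality-agnostic.
- The whole draft index and read set are held in memory; the design is
  desk-scale (up to tens of Mbp comfortably), not multi-gigabase.
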