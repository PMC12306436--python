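# Methods

## Coordinate model

All intervals are BED-convention 0-based half-open spans `[start, end)` on a
named chromosome. Overlap requires at least one shared base:
`a.start < b.end and b.start < a.end` on the same chromosome. Book-ended
intervals therefore do not overlap; this is the semantics under which every
gap-derived query provably returns nothing. Strand is ignored. Chromosome
names sort lexicographically (`chr10` < `chr2`); no karyotype order is
imposed, and none of the algorithms depends on the choice. Coordinates are
capped at two billion bases, the simulator's chromosome capacity.

## Simulator

### Reference placement

A dataset is parameterised by the interval count `intvlnums`, interval
length range (default 100–10000 bp), gap length range (default 100–5000
bp), and a seed. Intervals are spread as evenly as possible over
`min(24, max(1, intvlnums // 10))` chromosomes `chr1..chrN` — so every used
chromosome carries at least ten intervals (all of them, for datasets under
ten) and the default large datasets occupy exactly 24 chromosomes. Per
chromosome a cursor starts at zero and alternates a gap draw and an
interval draw, appending gap then interval; lengths are uniform-integer on
their inclusive ranges, the minimal assumption given only a min–max
specification. After the last interval a *tail* free space is drawn like a
gap, so queries extending past the final interval are always
constructible. If a chromosome would exceed capacity (minus one maximal
gap, reserved for the tail), the remaining intervals spill to scaffolds
`scf1, scf2, ...`; at the default sizes this never triggers (the largest
default chromosome ends around 3×10⁷ of the 2×10⁹ capacity).

Randomness: one top-level seed; each purpose (placement, overlap queries,
gap queries, complex queries, subsampling) uses a child generator seeded
`seed + fixed offset`, so adding or regenerating one query class never
perturbs another. Within placement the draw order is: per chromosome, the
gap-length vector, the interval-length vector, then the tail length.

### Query classes and their truth

Each reference interval `r` owns its preceding gap `g = [p, q)` (with
`q == r.start`) and sees the free space after it, which ends at the next
interval's start or at the tail end (`e`). Endpoints are drawn uniformly
from ranges chosen so that single-target truth holds *by construction*, not
by post-hoc filtering:

| class | span | truth |
|---|---|---|
| perfect | `[r.start, r.end)` | `{r}` |
| partial5p | `[U[p, r.start-1], U[r.start+1, r.end-1])` | `{r}` |
| partial3p | `[U[r.start+1, r.end-1], U[r.end+1, e])` | `{r}` |
| enclosing | `[U[p, r.start-1], U[r.end+1, e])` | `{r}` |
| contained | strictly inside `r` | `{r}` |
| gap_perfect | `[p, q)` | ∅ |
| gap_adj_start | `[U[p+1, q-1], q)` | ∅ |
| gap_adj_end | `[r.end, U[r.end+1, e-1])` | ∅ |
| gap_contained_left/right | disjoint sub-spans strictly inside the left/right half of `g` | ∅ |

A query ending exactly at the next interval's start misses it under
half-open semantics, which is why `e` itself is admissible for the overlap
classes but gap_adj_end stops at `e - 1`. The contained class needs
interval length ≥ 3 and the sub-gap classes need gap length ≥ 4; query
generation rejects configurations below these minima (the defaults are far
above them). Both contained sub-gaps anchor on the one preceding gap,
split at its midpoint, keeping all five gap classes attached to a single
gap. Query ids encode provenance as `<class>:<target id or k>:<serial>`,
and the truth is additionally written to a `truth.tsv` sidecar so external
tools' outputs can be scored without parsing ids.

Complex queries: per chromosome with `n ≥ 2` intervals, one query per span
length `k = 2..n`, running from the start of a uniformly chosen anchor
interval to the end of the (k−1)-th following one; its true overlap count
is exactly k. The anchor is random because only the span length, not its
position, defines the class; one query per k keeps the set size linear in
n. `decile_bin = ceil(10k/n)` clamped to 1..10.

Subsampling draws one seeded permutation and takes prefixes of size
`round(f·N)` (half-up, so `round(0.7) = 1` and sizes are monotone in f),
re-emitted in input order. The family is nested by construction and the
100% member equals the input, so runtime curves across fractions measure
query volume, not set composition. Only the basic and gap sets are
subsampled; complex queries are already stratified by k.

## Engines

All engines implement one contract — build from an interval collection,
return the overlapping reference intervals for a probe in
(chrom, start, end, id) order, empty (not an error) for unknown
chromosomes, multiset semantics for duplicate coordinates with distinct
ids — and all are single-threaded.

* **naive** — per-chromosome linear scan of the overlap predicate
  (vectorised over numpy start/end arrays, but still an exhaustive scan).
  It is the ground-truth oracle for the others.
* **iit** — implicit interval tree: the start-sorted array is treated as a
  balanced BST in which the node of an index range is its midpoint and the
  children are the midpoints of the half ranges — parent/child relations
  exist only as index arithmetic, no pointers. Each node stores its
  subtree's maximum end. A query skips any subtree whose maximum end is at
  or below the probe start and stops descending right once a node start
  reaches the probe end. The cache-oblivious (van Emde Boas) node layout
  used by some implementations is deliberately not implemented.
* **ailist** — augmented interval list: an interval that covers more than
  `coverage_threshold` of the up-to-`2×coverage_threshold` intervals
  following it in start order is promoted to the next component;
  decomposition stops when the remainder is no longer than `min_component`
  intervals or `max_components` is reached. Defaults
  (threshold 10, min component 64, at most 10 components) follow the
  published construction's spirit and are overridable; simulator output is
  non-nested, so it always forms a single component, and the nested cases
  are exercised by randomized tests. Each component keeps a running
  maximum-end array; a query binary-searches the rightmost start before the
  probe end and walks left while the running maximum end exceeds the probe
  start.

Correctness is established two ways: equivalence with the naive oracle on
every simulated query class and on uniform random probes, and agreement
with the third-party `intervaltree` package on dense randomized instances
(which, unlike simulator output, contain overlapping and nested intervals).
The cross-check library is never used in the implementation path.

## Benchmark harness

Each (tool, dataset) run produces one record per (phase, query class,
subsample fraction, replicate); the default is three replicates, kept
individually with their mean reported downstream. Preprocessing is charged
to the phase that needs it: tools with a persistent index pay for sorting
and index construction in the *index* phase; non-indexing tools (including
the built-in engines, which build their structure in memory at query time)
pay in the *query* phase. External tools run through shell command
templates (`{ref}`, `{query}`, `{out}`, `{index}`) defined in a YAML
adapter config; a `paired_bed` parser spec extracts (query id, target id)
pairs from their output for scoring. Batch invocation (one process per
query file) is the default; per-query invocation is available as an adapter
flag. A failing or unparsable tool yields a `failed` record carrying the
captured stderr — it never aborts a multi-tool run.

Peak memory is reported as a monotone upper estimate of peak RSS. External
processes are sampled at roughly 50 Hz by walking the child process tree
under `/proc` and summing `VmRSS`, combined with the kernel's exit-time
children high-water mark; in-process engines report the interpreter's own
high-water RSS. The estimate is conservative for short-lived processes
(the high-water mark is monotone across a harness run) — adequate for
ranking tools, not for byte-accurate accounting.

Precision: basic/gap queries are correct iff the returned target-id set
*equals* the expected set (empty for gap classes; missing queries count as
empty returns); the pooled fraction is reported with a per-class breakdown.
Complex queries are scored by the absolute distance between returned and
expected overlap counts (mean, and fraction at distance zero). Correct
engines achieve precision 1.0 and distance 0 on every simulated dataset —
the tests assert this through the full pipeline.

## Problem sizes and what the tests show

The test and acceptance suites run the simulator at 10–100,000 intervals
(the default sweep), check truth soundness exhaustively at 10/100/1000
intervals × 3 seeds, and verify engine equivalence on >10,000 random probes
— sizes chosen so the full battery completes in well under a minute while
still crossing the allocation rule's regime boundaries (1, 9, 10, 24
chromosomes). The simulator emulates the *structure* of annotation data
(disjoint, non-adjacent intervals with bounded lengths and gaps); it does
not emulate overlapping or nested features, real chromosome lengths,
clustered placement, or strand. Passing tests therefore demonstrate engine
exactness and harness correctness on disjoint references — the randomized
cross-library tests cover nested inputs for the engines — but say nothing
about runtime rankings on real data, which are hardware- and
implementation-dependent by nature.

## Numerical and degenerate-input choices

* Uniform-integer draws are inclusive on both bounds.
* `round(f·N)` is half-up, not banker's.
* Ties in sorting and in engine output order break by (chrom, start, end,
  id) — a total, stable order, so all outputs are deterministic.
* Empty query collections subsample to empty families; empty indexes
  answer every probe with the empty set; a chromosome with fewer than two
  intervals contributes no complex queries.
* The CLI log format carries no timestamps, so identical seeds produce
  byte-identical output directories.
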