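# ivbench

Simulation and benchmarking of genomic interval query engines.

Asking "which features overlap this region?" is one of the most common
primitives in genome informatics — variant annotation, peak assignment,
homology screens all reduce to interval overlap queries against large BED
files. Many data structures answer it (linear scans, interval trees, binned
indexes, ...), and comparing them fairly requires two things this package
provides:

1. **A simulator with machine-checkable truth.** Reference intervals are
   placed sequentially on chromosomes (alternating random gaps and random
   intervals, both uniform-integer within configurable ranges). For every
   reference interval the simulator derives **ten** queries whose correct
   answer is known by construction: five single-target overlap classes
   (perfect, 5′-partial, 3′-partial, enclosing, contained) and five
   zero-target gap classes (the preceding gap itself, gaps flush against the
   interval start or end, and two sub-gaps strictly inside the gap).
   Additional *complex* queries span k = 2..n consecutive intervals per
   chromosome, so their true overlap count is exactly k; they are binned by
   decile of k/n. Query sets are also emitted as nested 10%..100%
   subsamples, so runtime-vs-volume curves measure volume rather than set
   composition.

2. **A harness that measures and scores backends.** Three built-in engines
   share one contract — a naive linear scan (the oracle), an **implicit
   interval tree** (a balanced BST laid out over the start-sorted array by
   index arithmetic, augmented with subtree maximum ends for pruning), and
   an **augmented interval list** (AIList: a start-sorted array decomposed
   into a few components, each with a running maximum-end array, queried by
   binary search plus a bounded backward scan). External command-line tools
   plug in through adapter templates. The harness records wall time and peak
   RSS per phase (index vs query, with preprocessing charged to the phase
   that needs it) and scores precision: exact-set match for basic/gap
   queries, |returned − expected| count distance for complex queries.

Coordinates are BED-style 0-based half-open throughout; two intervals
overlap iff `max(starts) < min(ends)` on the same chromosome, so book-ended
intervals do not overlap — which is exactly why the gap-derived queries must
return nothing.

## Worked example

```sh
ivbench sim --intvlnums 1000 --seed 3 --outdir example_out
ivbench bench --tool naive --tool iit --tool ailist \
    --dataset example_out/n1000 --replicates 1
ivbench report --indir example_out/n1000
```

or, from Python (`examples/03_benchmark.py`):

```text
 naive: query time 0.118s, basic precision 1.0, complex mean distance 0.0
   iit: query time 0.051s, basic precision 1.0, complex mean distance 0.0
ailist: query time 0.056s, basic precision 1.0, complex mean distance 0.0
```

Every engine answers every query exactly (`basic precision 1.0` means each
of the 10,000 basic/gap queries returned precisely its expected target set;
`complex mean distance 0.0` means every multi-interval query returned
exactly its k overlaps) — correct backends differ only in runtime and
memory. Absolute timings are hardware-dependent and will differ on your
machine; the protocol, not the numbers, is the reproducible object.

The same machinery annotates arbitrary BED pairs
(`examples/04_annotate.py`):

```text
var1 at chr1:1500 lies in enhancer1
var3 at chr2:500 lies in enhancer2
2 of 3 variants hit a regulatory element
```

External tools are driven via adapter templates; `examples/adapters.yaml`
ships worked configs for bedtools and tabix:

```sh
ivbench bench --tool bedtools --adapters examples/adapters.yaml \
    --dataset example_out/n1000
```

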