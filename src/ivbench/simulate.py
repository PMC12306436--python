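"""Simulation of reference intervals and labelled query sets.

The simulator lays non-overlapping intervals sequentially on chromosomes
(alternating gap, interval, gap, interval, ...) and then derives, for every
reference interval, ten single-target queries — five overlap classes
(perfect, 5' partial, 3' partial, enclosing, contained) and five zero-target
gap classes (perfect gap, gap flush against the interval start or end, and
two sub-gaps strictly inside the preceding gap) — plus multi-interval
"complex" queries spanning k = 2..n consecutive intervals per chromosome.
Every query carries machine-checkable truth: the id(s) of the reference
interval(s) it must return, or the exact overlap count for complex queries.

Randomness is driven by one top-level seed; each purpose (reference
placement, basic queries, gap queries, complex queries, subsampling) uses a
child generator seeded ``seed + offset`` so adding one query class never
perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core import MAX_COORD, GenomicInterval, write_bed

# Child-seed offsets, one per purpose (fixed; see module docstring).
SEED_REF = 0
SEED_BASIC = 1
SEED_GAP = 2
SEED_COMPLEX = 3
SEED_SUBSAMPLE = 4

#: The five single-target overlap classes.
OVERLAP_CATEGORIES = ("perfect", "partial5p", "partial3p", "enclosing", "contained")
#: The five zero-target gap classes.
GAP_CATEGORIES = (
    "gap_perfect",
    "gap_adj_start",
    "gap_adj_end",
    "gap_contained_left",
    "gap_contained_right",
)
CATEGORIES = OVERLAP_CATEGORIES + GAP_CATEGORIES + ("complex",)

DEFAULT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    ``intvlsize_*`` and ``gapsize_*`` are inclusive bounds (bp) for the
    uniform-integer length draws; defaults are 100-10000 and 100-5000.
    ``chrom_capacity`` is the fixed two-billion-bp chromosome ceiling.
    """

    intvlnums: int
    intvlsize_min: int = 100
    intvlsize_max: int = 10_000
    gapsize_min: int = 100
    gapsize_max: int = 5_000
    chrom_count: int = 24
    chrom_capacity: int = MAX_COORD
    min_per_chrom: int = 10
    seed: int = 42
    subsample_fractions: tuple = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        if self.intvlnums < 1:
            raise ValueError("intvlnums must be >= 1")
        if not (0 < self.intvlsize_min <= self.intvlsize_max):
            raise ValueError("require 0 < intvlsize_min <= intvlsize_max")
        if not (0 < self.gapsize_min <= self.gapsize_max):
            raise ValueError("require 0 < gapsize_min <= gapsize_max")
        if self.chrom_count < 1:
            raise ValueError("chrom_count must be >= 1")
        if self.chrom_capacity != MAX_COORD:
            raise ValueError(f"chrom_capacity is fixed at {MAX_COORD}")
        if self.min_per_chrom < 1:
            raise ValueError("min_per_chrom must be >= 1")
        fr = self.subsample_fractions
        if not fr or any(b <= a for a, b in zip(fr, fr[1:])) or fr[-1] != 1.0:
            raise ValueError("subsample_fractions must be strictly increasing, ending at 1.0")

    def used_chromosomes(self) -> int:
        """Number of chromosomes the allocation rule spreads intervals over."""
        return min(self.chrom_count, max(1, self.intvlnums // self.min_per_chrom))


@dataclass
class ReferenceSet:
    """Simulated ground truth: per-chromosome sorted, non-overlapping intervals.

    ``gaps[c][i]`` is the free space immediately preceding ``intervals[c][i]``
    (it ends exactly at the interval's start); ``tails[c]`` is the synthetic
    free space following the last interval, drawn like a gap so that queries
    extending past the final interval are always constructible.
    ``chrom_order`` preserves placement order (chr1..chrN, then scf1, ...).
    """

    intervals: dict[str, list[GenomicInterval]]
    gaps: dict[str, list[GenomicInterval]]
    tails: dict[str, GenomicInterval]
    chrom_order: list[str]
    config: SimConfig
    seed: int

    def all_intervals(self) -> list[GenomicInterval]:
        return [iv for c in self.chrom_order for iv in self.intervals[c]]

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def following_space_end(self, chrom: str, i: int) -> int:
        """End of the free space after interval *i*: the next interval's start,
        or the tail end for the chromosome-last interval."""
        ivs = self.intervals[chrom]
        if i + 1 < len(ivs):
            return ivs[i + 1].start
        return self.tails[chrom].end


@dataclass(frozen=True)
class QueryRecord:
    """One query interval with its generation class and expected answer."""

    query: GenomicInterval
    category: str
    expected_ids: tuple = ()
    expected_count: int = 0
    decile_bin: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in GAP_CATEGORIES and self.expected_count != 0:
            raise ValueError("gap queries expect zero overlaps")
        if self.category in OVERLAP_CATEGORIES and self.expected_count != 1:
            raise ValueError("basic overlap queries expect exactly one target")


def _allocate(cfg: SimConfig) -> list[int]:
    """Even split of intvlnums over the used chromosomes (first chroms get
    the remainder)."""
    m = cfg.used_chromosomes()
    base, extra = divmod(cfg.intvlnums, m)
    return [base + (1 if i < extra else 0) for i in range(m)]


def simulate_reference(cfg: SimConfig) -> ReferenceSet:
    """Generate the reference intervals for *cfg*.

    Intervals are spread as evenly as possible over
    ``min(chrom_count, max(1, intvlnums // min_per_chrom))`` chromosomes named
    ``chr1..chrN``, so every used chromosome carries at least ``min_per_chrom``
    intervals (or all of them for tiny datasets).  Per chromosome a cursor
    starts at 0 and alternately draws a gap length then an interval length,
    both uniform-integer on their inclusive ranges.  Should a chromosome hit
    the two-billion-bp capacity, the remaining intervals spill onto scaffolds
    ``scf1, scf2, ...``.  Identical configs (including seed) give identical
    output.
    """
    rng = np.random.default_rng(cfg.seed + SEED_REF)
    counts = _allocate(cfg)
    names = [f"chr{i + 1}" for i in range(len(counts))]

    intervals: dict[str, list[GenomicInterval]] = {}
    gaps: dict[str, list[GenomicInterval]] = {}
    tails: dict[str, GenomicInterval] = {}
    order: list[str] = []
    serial = 0  # global interval counter, drives iv/gp ids
    spill = 0

    # guard so the tail free space always fits under the capacity ceiling
    guard = cfg.chrom_capacity - cfg.gapsize_max
    if cfg.gapsize_max + cfg.intvlsize_max > guard:
        raise ValueError("interval/gap sizes incompatible with chromosome capacity")

    def place(chrom: str, want: int) -> int:
        """Place up to *want* intervals on *chrom*; return how many fit."""
        nonlocal serial
        g = rng.integers(cfg.gapsize_min, cfg.gapsize_max, size=want, endpoint=True)
        ln = rng.integers(cfg.intvlsize_min, cfg.intvlsize_max, size=want, endpoint=True)
        ends = np.cumsum(g + ln)
        fit = int(np.searchsorted(ends, guard, side="right"))
        if fit == 0:
            return 0
        starts = ends - ln
        ivs, gps = [], []
        for i in range(fit):
            serial += 1
            s, e = int(starts[i]), int(ends[i])
            gps.append(GenomicInterval(chrom, s - int(g[i]), s, f"gp{serial}"))
            ivs.append(GenomicInterval(chrom, s, e, f"iv{serial}"))
        tail_len = int(rng.integers(cfg.gapsize_min, cfg.gapsize_max, endpoint=True))
        last_end = int(ends[fit - 1])
        intervals[chrom] = ivs
        gaps[chrom] = gps
        tails[chrom] = GenomicInterval(chrom, last_end, last_end + tail_len, f"tail_{chrom}")
        order.append(chrom)
        return fit

    leftover = 0
    for chrom, want in zip(names, counts):
        placed = place(chrom, want)
        leftover += want - placed
    while leftover > 0:
        spill += 1
        if spill > 1_000_000:  # practically unreachable at desk scale
            raise RuntimeError("cannot place all intervals even on scaffolds")
        placed = place(f"scf{spill}", leftover)
        if placed == 0:
            raise RuntimeError("interval does not fit on an empty scaffold")
        leftover -= placed

    return ReferenceSet(intervals, gaps, tails, order, cfg, cfg.seed)


def _require_query_feasible(cfg: SimConfig) -> None:
    if cfg.intvlsize_min < 3:
        raise ValueError("query generation requires intvlsize_min >= 3 (contained class)")
    if cfg.gapsize_min < 4:
        raise ValueError("query generation requires gapsize_min >= 4 (sub-gap classes)")


def _chrom_arrays(ref: ReferenceSet, chrom: str):
    ivs = ref.intervals[chrom]
    gps = ref.gaps[chrom]
    s = np.array([iv.start for iv in ivs], dtype=np.int64)
    e = np.array([iv.end for iv in ivs], dtype=np.int64)
    p = np.array([g.start for g in gps], dtype=np.int64)
    # free space after interval i ends at the next interval's start,
    # or at the tail end for the last interval
    nxt = np.empty_like(s)
    nxt[:-1] = s[1:]
    nxt[-1] = ref.tails[chrom].end
    return ivs, s, e, p, nxt


def make_interval_queries(ref: ReferenceSet, seed: int | None = None) -> list[QueryRecord]:
    """Emit the five single-target overlap queries per reference interval.

    With preceding gap ``[p, start)`` and following free space ending at
    ``e_next``:

    * perfect — the interval itself;
    * partial5p — starts in the preceding gap, ends strictly inside;
    * partial3p — starts strictly inside, ends in the following space
      (up to and including ``e_next``: a query ending exactly at the next
      interval's start still misses it under half-open semantics);
    * enclosing — starts in the preceding gap, ends in the following space;
    * contained — strictly inside the interval.

    Each emitted query overlaps exactly its one target by construction.
    """
    cfg = ref.config
    _require_query_feasible(cfg)
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + SEED_BASIC)
    out: list[QueryRecord] = []
    serial = 0
    for chrom in ref.chrom_order:
        ivs, s, e, p, nxt = _chrom_arrays(ref, chrom)
        n = len(ivs)
        # vectorised endpoint draws, one array per class, fixed order
        u5 = rng.integers(p, s - 1, endpoint=True)
        v5 = rng.integers(s + 1, e - 1, endpoint=True)
        u3 = rng.integers(s + 1, e - 1, endpoint=True)
        v3 = rng.integers(e + 1, nxt, endpoint=True)
        ue = rng.integers(p, s - 1, endpoint=True)
        ve = rng.integers(e + 1, nxt, endpoint=True)
        uc = rng.integers(s + 1, e - 2, endpoint=True)
        vc = rng.integers(uc + 1, e - 1, endpoint=True)
        coords = {
            "perfect": (s, e),
            "partial5p": (u5, v5),
            "partial3p": (u3, v3),
            "enclosing": (ue, ve),
            "contained": (uc, vc),
        }
        for i in range(n):
            target = ivs[i].id
            for cat in OVERLAP_CATEGORIES:
                serial += 1
                a, b = coords[cat]
                q = GenomicInterval(chrom, int(a[i]), int(b[i]), f"{cat}:{target}:{serial}")
                out.append(QueryRecord(q, cat, expected_ids=(target,), expected_count=1))
    return out


def make_gap_queries(ref: ReferenceSet, seed: int | None = None) -> list[QueryRecord]:
    """Emit the five zero-target gap queries per reference interval.

    All five anchor on the interval's preceding gap ``[p, q)`` (``q`` is the
    interval start) except ``gap_adj_end``, which sits in the following free
    space flush against the interval end.  The two contained sub-gaps are
    drawn disjointly from the left and right halves of the preceding gap.
    None of them overlaps any reference interval.
    """
    cfg = ref.config
    _require_query_feasible(cfg)
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + SEED_GAP)
    out: list[QueryRecord] = []
    serial = 0
    for chrom in ref.chrom_order:
        ivs, s, e, p, nxt = _chrom_arrays(ref, chrom)
        q = s  # gap end == interval start
        mid = (p + q) // 2
        ua = rng.integers(p + 1, q - 1, endpoint=True)
        vb = rng.integers(e + 1, nxt - 1, endpoint=True)
        ul = rng.integers(p + 1, mid - 1, endpoint=True)
        vl = rng.integers(ul + 1, mid, endpoint=True)
        ur = rng.integers(mid, q - 2, endpoint=True)
        vr = rng.integers(ur + 1, q - 1, endpoint=True)
        coords = {
            "gap_perfect": (p, q),
            "gap_adj_start": (ua, q),
            "gap_adj_end": (e, vb),
            "gap_contained_left": (ul, vl),
            "gap_contained_right": (ur, vr),
        }
        for i in range(len(ivs)):
            target = ivs[i].id
            for cat in GAP_CATEGORIES:
                serial += 1
                a, b = coords[cat]
                qiv = GenomicInterval(chrom, int(a[i]), int(b[i]), f"{cat}:{target}:{serial}")
                out.append(QueryRecord(qiv, cat, expected_ids=(), expected_count=0))
    return out


def make_complex_queries(ref: ReferenceSet, seed: int | None = None) -> list[QueryRecord]:
    """Emit one query per span length k = 2..n on each chromosome.

    The query runs from the start of a uniformly chosen anchor interval
    ``r_i`` to the end of ``r_{i+k-1}``, so its true overlap count is exactly
    *k*.  ``decile_bin`` buckets k/n into deciles (``ceil(10k/n)``, clamped to
    1..10).  Chromosomes with fewer than two intervals contribute nothing.
    """
    cfg = ref.config
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + SEED_COMPLEX)
    out: list[QueryRecord] = []
    serial = 0
    for chrom in ref.chrom_order:
        ivs = ref.intervals[chrom]
        n = len(ivs)
        if n < 2:
            continue
        for k in range(2, n + 1):
            i = int(rng.integers(0, n - k, endpoint=True))  # 0-based anchor
            serial += 1
            q = GenomicInterval(
                chrom, ivs[i].start, ivs[i + k - 1].end, f"complex:{k}:{serial}"
            )
            bin_ = min(10, max(1, math.ceil(10 * k / n)))
            out.append(
                QueryRecord(q, "complex", expected_ids=(), expected_count=k, decile_bin=bin_)
            )
    return out


def subsample_queries(
    queries: Sequence[QueryRecord],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> dict[float, list[QueryRecord]]:
    """Nested subsamples: one seeded shuffle, then prefixes of size
    round(f*N) (half-up), re-emitted in the input order.

    The family forms a chain under inclusion and the 1.0 member equals the
    input, so runtime curves across fractions measure query volume rather
    than set composition.
    """
    fr = list(fractions)
    if not fr or any(b <= a for a, b in zip(fr, fr[1:])) or fr[-1] != 1.0:
        raise ValueError("fractions must be strictly increasing, ending at 1.0")
    n = len(queries)
    rng = np.random.default_rng(seed + SEED_SUBSAMPLE)
    perm = rng.permutation(n)
    out: dict[float, list[QueryRecord]] = {}
    for f in fr:
        size = int(math.floor(f * n + 0.5))
        chosen = np.zeros(n, dtype=bool)
        chosen[perm[:size]] = True
        out[f] = [queries[i] for i in range(n) if chosen[i]]
    return out


# ---------------------------------------------------------------------------
# Dataset emission


def write_truth(records: Iterable[QueryRecord], path: str | Path) -> None:
    """Write the truth sidecar TSV: query id, category, expected ids,
    expected count, decile bin."""
    with open(path, "w") as fh:
        fh.write("query_id\tcategory\texpected_ids\texpected_count\tdecile_bin\n")
        for r in records:
            ids = ",".join(r.expected_ids)
            dec = "" if r.decile_bin is None else str(r.decile_bin)
            fh.write(f"{r.query.id}\t{r.category}\t{ids}\t{r.expected_count}\t{dec}\n")


def write_dataset(ref: ReferenceSet, outdir: str | Path) -> dict:
    """Simulate the full query battery for *ref* and write one dataset
    directory: ``ref.bed``, ``queries_basic.bed``, ``queries_gap.bed``,
    ``queries_complex.bed``, nested subsample files
    ``queries_{basic,gap}.p10..p100.bed`` and the ``truth.tsv`` sidecar.

    Returns a small manifest of counts (used for logging and tests).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(ref.all_intervals(), outdir / "ref.bed")

    basic = make_interval_queries(ref)
    gap = make_gap_queries(ref)
    cx = make_complex_queries(ref)
    write_bed([r.query for r in basic], outdir / "queries_basic.bed")
    write_bed([r.query for r in gap], outdir / "queries_gap.bed")
    write_bed([r.query for r in cx], outdir / "queries_complex.bed")

    fr = ref.config.subsample_fractions
    for label, qs in (("basic", basic), ("gap", gap)):
        fam = subsample_queries(qs, fr, seed=ref.config.seed)
        for f, sub in fam.items():
            pct = int(round(f * 100))
            write_bed([r.query for r in sub], outdir / f"queries_{label}.p{pct}.bed")

    write_truth([*basic, *gap, *cx], outdir / "truth.tsv")
    return {
        "intervals": len(ref),
        "chromosomes": len(ref.chrom_order),
        "basic_queries": len(basic) + len(gap),
        "complex_queries": len(cx),
    }
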