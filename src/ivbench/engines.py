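"""Built-in interval-query backends behind one contract.

Three engines answer "which reference intervals overlap this probe":

* ``naive`` — exhaustive linear scan; the ground-truth oracle.
* ``iit``   — implicit interval tree: a balanced binary search tree laid out
  over the start-sorted array purely by index arithmetic (no pointers),
  augmented with per-subtree maximum end positions for pruning.
* ``ailist`` — augmented interval list: the start-sorted array is decomposed
  into a few components such that long, containing intervals are promoted to
  later components; each component carries a running maximum-end array so a
  bounded backward scan answers the query.

All engines are single-threaded and return results normalised to
(chrom, start, end, id) order with multiset semantics (duplicate coordinates
with distinct ids are distinct results).
"""

from __future__ import annotations

import bisect
from typing import Iterable, Sequence

import numpy as np

from .core import GenomicInterval, sort_intervals


class IntervalIndex:
    """Contract shared by all backends: build from intervals, query a probe."""

    name = "abstract"

    def __init__(self, intervals: Iterable[GenomicInterval]):
        raise NotImplementedError

    def query(self, probe: GenomicInterval) -> list[GenomicInterval]:
        """All reference intervals overlapping *probe*, in normalised order.
        Unknown chromosomes yield an empty result, not an error."""
        raise NotImplementedError

    def query_ids(self, probe: GenomicInterval) -> list[str]:
        return [iv.id for iv in self.query(probe)]


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in sort_intervals(intervals):
        out.setdefault(iv.chrom, []).append(iv)
    return out


class NaiveIndex(IntervalIndex):
    """Exhaustive scan with the overlap predicate; defines ground truth."""

    name = "naive"

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._chroms: dict[str, tuple] = {}
        for chrom, ivs in _by_chrom(intervals).items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._chroms[chrom] = (ivs, starts, ends)

    def query(self, probe: GenomicInterval) -> list[GenomicInterval]:
        entry = self._chroms.get(probe.chrom)
        if entry is None:
            return []
        ivs, starts, ends = entry
        hit = (starts < probe.end) & (ends > probe.start)
        return [ivs[i] for i in np.flatnonzero(hit)]


class ImplicitIntervalTree(IntervalIndex):
    """Balanced BST over the start-sorted array, represented by index
    arithmetic alone.

    The node for the index range ``[lo, hi)`` is its midpoint; its children
    are the midpoints of the two half ranges.  ``max_end[mid]`` stores the
    maximum interval end within the subtree, enabling the classic pruning:
    skip any subtree whose max end is at or below the probe start, and stop
    descending right once the node start reaches the probe end.
    """

    name = "iit"

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._chroms: dict[str, tuple] = {}
        for chrom, ivs in _by_chrom(intervals).items():
            starts = [iv.start for iv in ivs]
            ends = [iv.end for iv in ivs]
            max_end = [0] * len(ivs)

            def build(lo: int, hi: int) -> int:
                if lo >= hi:
                    return -1
                mid = (lo + hi) // 2
                m = ends[mid]
                left = build(lo, mid)
                right = build(mid + 1, hi)
                if left > m:
                    m = left
                if right > m:
                    m = right
                max_end[mid] = m
                return m

            build(0, len(ivs))
            self._chroms[chrom] = (ivs, starts, max_end)

    def subtree_max_end(self, chrom: str, lo: int, hi: int) -> int:
        """Stored max end of the subtree rooted at the midpoint of [lo, hi);
        exposed for structural audits."""
        _, _, max_end = self._chroms[chrom]
        return max_end[(lo + hi) // 2]

    def size(self, chrom: str) -> int:
        return len(self._chroms[chrom][0])

    def query(self, probe: GenomicInterval) -> list[GenomicInterval]:
        entry = self._chroms.get(probe.chrom)
        if entry is None:
            return []
        ivs, starts, max_end = entry
        out: list[GenomicInterval] = []
        stack = [(0, len(ivs))]
        while stack:
            lo, hi = stack.pop()
            if lo >= hi:
                continue
            mid = (lo + hi) // 2
            if max_end[mid] <= probe.start:
                continue  # nothing in this subtree reaches past the probe start
            stack.append((lo, mid))
            if starts[mid] < probe.end:
                iv = ivs[mid]
                if iv.end > probe.start:
                    out.append(iv)
                stack.append((mid + 1, hi))
        out.sort(key=GenomicInterval.sort_key)
        return out


class AIListIndex(IntervalIndex):
    """Augmented interval list with containment-driven decomposition.

    An interval that covers more than ``coverage_threshold`` of the (up to
    ``2 * coverage_threshold``) intervals following it in start order is
    deferred to the next component; decomposition stops once the remaining
    list is no longer than ``min_component`` or ``max_components`` is
    reached.  Each component keeps a running maximum-end array: to query,
    binary-search the rightmost start before the probe end, then walk left
    while the running max end still exceeds the probe start.
    """

    name = "ailist"

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        coverage_threshold: int = 10,
        min_component: int = 64,
        max_components: int = 10,
    ):
        if coverage_threshold < 1 or min_component < 1 or max_components < 1:
            raise ValueError("AIList parameters must be >= 1")
        self.coverage_threshold = coverage_threshold
        self.min_component = min_component
        self.max_components = max_components
        self._chroms: dict[str, list[tuple]] = {}
        for chrom, ivs in _by_chrom(intervals).items():
            comps = []
            for comp in self._decompose(ivs):
                starts = [iv.start for iv in comp]
                run_max = []
                m = 0
                for iv in comp:
                    m = max(m, iv.end)
                    run_max.append(m)
                comps.append((comp, starts, run_max))
            self._chroms[chrom] = comps

    def _decompose(self, ivs: list[GenomicInterval]) -> list[list[GenomicInterval]]:
        cov = self.coverage_threshold
        comps: list[list[GenomicInterval]] = []
        rest = ivs
        while len(comps) < self.max_components - 1 and len(rest) > self.min_component:
            ends = [iv.end for iv in rest]
            keep: list[GenomicInterval] = []
            defer: list[GenomicInterval] = []
            for i, iv in enumerate(rest):
                window = ends[i + 1 : i + 1 + 2 * cov]
                covered = sum(1 for e in window if e <= iv.end)
                (defer if covered > cov else keep).append(iv)
            if not defer:
                break
            comps.append(keep)
            rest = defer
        comps.append(rest)
        return [c for c in comps if c]

    def components(self, chrom: str) -> list[list[GenomicInterval]]:
        """Per-component interval lists; exposed for structural audits."""
        return [comp for comp, _, _ in self._chroms.get(chrom, [])]

    def query(self, probe: GenomicInterval) -> list[GenomicInterval]:
        comps = self._chroms.get(probe.chrom)
        if comps is None:
            return []
        out: list[GenomicInterval] = []
        for comp, starts, run_max in comps:
            j = bisect.bisect_left(starts, probe.end) - 1
            while j >= 0 and run_max[j] > probe.start:
                if comp[j].end > probe.start:
                    out.append(comp[j])
                j -= 1
        out.sort(key=GenomicInterval.sort_key)
        return out


#: Registry used by the bench harness and the CLI.
ENGINES: dict[str, type[IntervalIndex]] = {
    "naive": NaiveIndex,
    "iit": ImplicitIntervalTree,
    "ailist": AIListIndex,
}


def build_engine(name: str, intervals: Iterable[GenomicInterval], **kwargs) -> IntervalIndex:
    """Instantiate a built-in engine by registry name."""
    try:
        cls = ENGINES[name]
    except KeyError:
        raise ValueError(f"unknown engine {name!r}; choose from {sorted(ENGINES)}") from None
    return cls(intervals, **kwargs)
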