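"""Benchmark harness: run a backend over a dataset, time its phases,
capture peak memory, and score query precision.

Phase accounting follows the rule that preprocessing is charged to the
phase that needs it: tools that build a persistent index pay for sorting
and index construction in the *index* phase; everything else (including the
built-in engines, which build their in-memory structure on the fly) pays in
the *query* phase.

Peak memory is a monotone upper estimate of the peak resident set size:
for external tools, the process tree's RSS is sampled from ``/proc`` at
roughly 50 Hz and combined with the kernel's exit-time high-water mark; for
in-process engines the interpreter's own high-water mark is reported.
"""

from __future__ import annotations

import os
import resource
import subprocess
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .core import GenomicInterval, read_bed, sort_intervals, write_bed
from .engines import ENGINES, build_engine
from .simulate import GAP_CATEGORIES, OVERLAP_CATEGORIES

BASIC_CLASSES = ("basic", "gap")
QUERY_CLASSES = BASIC_CLASSES + ("complex",)


# ---------------------------------------------------------------------------
# Records


@dataclass
class BenchResult:
    """One measurement: a (tool, dataset, phase, class, fraction, replicate)
    cell with wall time, peak RSS and exit status."""

    tool: str
    dataset: str
    phase: str  # "index" | "query"
    query_class: str | None = None
    fraction: float | None = None
    replicate: int = 1
    seconds: float = 0.0
    peak_rss_bytes: int = 0
    status: str = "ok"  # "ok" | "failed" | "skipped"
    detail: str = ""

    def as_row(self) -> dict:
        return {
            "tool": self.tool,
            "dataset": self.dataset,
            "phase": self.phase,
            "query_class": self.query_class or "",
            "fraction": "" if self.fraction is None else self.fraction,
            "replicate": self.replicate,
            "seconds": round(self.seconds, 6),
            "peak_rss_bytes": self.peak_rss_bytes,
            "status": self.status,
            "detail": self.detail,
        }


@dataclass
class PrecisionReport:
    """Precision metrics for one tool on one dataset.

    ``basic_precision`` pools the ten single-target/zero-target classes;
    ``per_class`` breaks the same counts out per class.  Complex queries are
    scored by the absolute distance between returned and expected overlap
    counts.
    """

    basic_precision: float | None = None
    complex_mean_abs_distance: float | None = None
    complex_exact_fraction: float | None = None
    per_class: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Truth table


@dataclass(frozen=True)
class TruthEntry:
    category: str
    expected_ids: frozenset
    expected_count: int
    decile_bin: int | None


def load_truth(path: str | Path) -> dict[str, TruthEntry]:
    """Load the simulator's truth sidecar; duplicate query ids are an error."""
    truth: dict[str, TruthEntry] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            qid = f[idx["query_id"]]
            if qid in truth:
                raise ValueError(f"duplicate query id {qid!r} in truth table")
            ids = f[idx["expected_ids"]]
            dec = f[idx["decile_bin"]]
            truth[qid] = TruthEntry(
                category=f[idx["category"]],
                expected_ids=frozenset(ids.split(",")) if ids else frozenset(),
                expected_count=int(f[idx["expected_count"]]),
                decile_bin=int(dec) if dec else None,
            )
    return truth


# ---------------------------------------------------------------------------
# Scoring


def score_basic(
    truth: Mapping[str, TruthEntry], returned: Mapping[str, set[str] | frozenset]
) -> PrecisionReport:
    """Exact-set precision over the single-target and gap classes.

    A query is correct iff its returned target-id set equals the expected
    set (empty for gap classes); queries missing from *returned* count as
    empty returns.
    """
    total = correct = 0
    per_class: dict[str, list[int]] = {}
    for qid, entry in truth.items():
        if entry.category not in OVERLAP_CATEGORIES + GAP_CATEGORIES:
            continue
        got = frozenset(returned.get(qid, frozenset()))
        ok = got == entry.expected_ids
        total += 1
        correct += ok
        bucket = per_class.setdefault(entry.category, [0, 0])
        bucket[0] += ok
        bucket[1] += 1
    rep = PrecisionReport()
    if total:
        rep.basic_precision = correct / total
        rep.per_class = {c: n_ok / n for c, (n_ok, n) in sorted(per_class.items())}
    return rep


def score_complex(
    truth: Mapping[str, TruthEntry], returned_counts: Mapping[str, int]
) -> PrecisionReport:
    """Count-distance precision over complex queries: mean |returned -
    expected| and the fraction at distance zero."""
    dists = []
    for qid, entry in truth.items():
        if entry.category != "complex":
            continue
        got = int(returned_counts.get(qid, 0))
        dists.append(abs(got - entry.expected_count))
    rep = PrecisionReport()
    if dists:
        rep.complex_mean_abs_distance = sum(dists) / len(dists)
        rep.complex_exact_fraction = sum(d == 0 for d in dists) / len(dists)
    return rep


# ---------------------------------------------------------------------------
# Peak-RSS measurement


def _proc_tree(pid: int) -> list[int]:
    pids = [pid]
    i = 0
    while i < len(pids):
        p = pids[i]
        i += 1
        try:
            for task in os.listdir(f"/proc/{p}/task"):
                path = f"/proc/{p}/task/{task}/children"
                with open(path) as fh:
                    pids.extend(int(c) for c in fh.read().split())
        except OSError:
            pass
    return pids


def _tree_rss_bytes(pid: int) -> int:
    total = 0
    for p in _proc_tree(pid):
        try:
            with open(f"/proc/{p}/status") as fh:
                for line in fh:
                    if line.startswith("VmRSS:"):
                        total += int(line.split()[1]) * 1024
                        break
        except OSError:
            pass
    return total


def self_peak_rss_bytes() -> int:
    """High-water RSS of the current process (kernel-reported, monotone)."""
    return resource.getrusage(resource.RUSAGE_SELF).ru_maxrss * 1024


def run_command(cmd: str, timeout: float | None = None, sample_interval: float = 0.02):
    """Run *cmd* through the shell, returning (exit_code, seconds,
    peak_rss_bytes, stderr_text).

    Peak RSS combines ~50 Hz sampling of the whole process tree with the
    children high-water mark the kernel reports at exit.
    """
    before_hwm = resource.getrusage(resource.RUSAGE_CHILDREN).ru_maxrss * 1024
    t0 = time.perf_counter()
    proc = subprocess.Popen(
        cmd, shell=True, stdout=subprocess.DEVNULL, stderr=subprocess.PIPE, text=True
    )
    peak = 0
    stop = threading.Event()

    def sample():
        nonlocal peak
        while not stop.is_set():
            peak = max(peak, _tree_rss_bytes(proc.pid))
            stop.wait(sample_interval)

    sampler = threading.Thread(target=sample, daemon=True)
    sampler.start()
    try:
        _, err = proc.communicate(timeout=timeout)
    except subprocess.TimeoutExpired:
        proc.kill()
        _, err = proc.communicate()
        stop.set()
        sampler.join()
        return -1, time.perf_counter() - t0, peak, "timeout: " + (err or "")
    finally:
        stop.set()
    sampler.join()
    seconds = time.perf_counter() - t0
    after_hwm = resource.getrusage(resource.RUSAGE_CHILDREN).ru_maxrss * 1024
    if after_hwm > before_hwm:
        peak = max(peak, after_hwm)
    return proc.returncode, seconds, peak, err or ""


# ---------------------------------------------------------------------------
# Tool adapters (external tools)


@dataclass
class ToolAdapter:
    """Description of how to drive one external command-line tool.

    Command templates use ``{ref}``, ``{query}``, ``{out}`` and ``{index}``
    placeholders.  The parser spec says how to pull (query id, target id)
    pairs out of the tool's output; the shipped ``paired_bed`` kind reads a
    tab-joined query+target line format (as produced by e.g.
    ``bedtools intersect -wa -wb``).
    """

    name: str
    query_cmd: str
    index_cmd: str | None = None
    requires_sorted: bool = False
    requires_index: bool = False
    parser: dict = field(default_factory=lambda: {"kind": "paired_bed",
                                                  "query_id_col": 4,
                                                  "target_id_col": 8})
    per_query: bool = False

    def __post_init__(self) -> None:
        if "{query}" not in self.query_cmd or "{out}" not in self.query_cmd:
            raise ValueError(f"adapter {self.name}: query_cmd needs {{query}} and {{out}}")
        if self.requires_index and not self.index_cmd:
            raise ValueError(f"adapter {self.name}: requires_index without an index_cmd")


def _fill(template: str, **values) -> str:
    """Literal placeholder substitution ({ref}, {query}, {out}, {index});
    unlike str.format it tolerates shell/awk braces in templates."""
    for key, val in values.items():
        template = template.replace("{" + key + "}", str(val))
    return template


def load_adapters(path: str | Path) -> dict[str, ToolAdapter]:
    """Load adapter definitions from a YAML config (``tools:`` mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    out = {}
    for name, spec in (data.get("tools") or {}).items():
        out[name] = ToolAdapter(name=name, **spec)
    return out


def parse_tool_output(parser: Mapping, path: str | Path) -> dict[str, set[str]]:
    """Extract per-query returned target-id sets from a tool's output file."""
    kind = parser.get("kind", "paired_bed")
    if kind != "paired_bed":
        raise ValueError(f"unknown parser kind {kind!r}")
    qcol = int(parser.get("query_id_col", 4)) - 1
    tcol = int(parser.get("target_id_col", 8)) - 1
    returned: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) <= max(qcol, tcol):
                continue
            returned.setdefault(f[qcol], set()).add(f[tcol])
    return returned


# ---------------------------------------------------------------------------
# Running phases


def _dataset_query_file(dataset: Path, query_class: str, fraction: float | None) -> Path:
    if fraction is None or fraction == 1.0 or query_class == "complex":
        return dataset / f"queries_{query_class}.bed"
    return dataset / f"queries_{query_class}.p{int(round(fraction * 100))}.bed"


def run_builtin_query(
    engine_name: str,
    ref_path: str | Path,
    query_path: str | Path,
    out_path: str | Path | None = None,
) -> tuple[dict[str, set[str]], float, int]:
    """Build the named in-process engine and answer every query in the file.

    Returns (per-query returned id sets, wall seconds, peak RSS bytes).
    Index construction happens here because the built-in engines, like the
    non-indexing tools they model, have no persistent index phase.
    """
    t0 = time.perf_counter()
    ref = read_bed(ref_path)
    index = build_engine(engine_name, ref)
    queries = read_bed(query_path)
    returned: dict[str, set[str]] = {}
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for q in queries:
        hits = index.query(q)
        returned[q.id] = {iv.id for iv in hits}
        if out_path is not None:
            pairs.extend((q, t) for t in hits)
    seconds = time.perf_counter() - t0
    if out_path is not None:
        with open(out_path, "w") as fh:
            for q, t in pairs:
                fh.write(f"{q.chrom}\t{q.start}\t{q.end}\t{q.id}"
                         f"\t{t.chrom}\t{t.start}\t{t.end}\t{t.id}\n")
    return returned, seconds, self_peak_rss_bytes()


def run_phase(
    tool: str | ToolAdapter,
    dataset: str | Path,
    phase: str,
    query_class: str | None = None,
    fraction: float | None = None,
    replicate: int = 1,
    workdir: str | Path | None = None,
    timeout: float | None = None,
) -> tuple[BenchResult, dict[str, set[str]] | None]:
    """Execute one (phase, class, fraction) cell for a tool on a dataset.

    Returns the measurement record and, for query phases, the per-query
    returned target sets (``None`` when the phase failed or was a no-op).
    Failures are captured in the record — a broken adapter never raises.
    """
    dataset = Path(dataset)
    label = dataset.name
    name = tool if isinstance(tool, str) else tool.name
    res = BenchResult(tool=name, dataset=label, phase=phase,
                      query_class=query_class, fraction=fraction, replicate=replicate)
    try:
        if isinstance(tool, str):  # built-in engine
            if tool not in ENGINES:
                raise ValueError(f"unknown built-in engine {tool!r}")
            if phase == "index":
                res.status = "skipped"
                res.detail = "built-in engines build in the query phase"
                return res, None
            qfile = _dataset_query_file(dataset, query_class, fraction)
            returned, seconds, peak = run_builtin_query(tool, dataset / "ref.bed", qfile)
            res.seconds, res.peak_rss_bytes = seconds, peak
            return res, returned
        return _run_adapter_phase(tool, dataset, phase, query_class, fraction,
                                  res, workdir, timeout)
    except Exception as exc:  # harness robustness: record, never crash
        res.status = "failed"
        res.detail = f"{type(exc).__name__}: {exc}"
        return res, None


def _run_adapter_phase(adapter, dataset, phase, query_class, fraction, res,
                       workdir, timeout):
    work = Path(workdir) if workdir else dataset / "work"
    work.mkdir(parents=True, exist_ok=True)
    ref_path = dataset / "ref.bed"
    index_path = work / f"{adapter.name}.index"
    total_s, peak = 0.0, 0

    if adapter.requires_sorted:
        # sorting cost is charged to the phase that first needs the sorted file
        sorted_path = work / f"{adapter.name}.ref.sorted.bed"
        charge_here = (phase == "index") == adapter.requires_index
        if charge_here or not sorted_path.exists():
            t0 = time.perf_counter()
            write_bed(sort_intervals(read_bed(ref_path)), sorted_path)
            if charge_here:
                total_s += time.perf_counter() - t0
        ref_path = sorted_path

    if phase == "index":
        if not adapter.index_cmd:
            res.status = "skipped"
            res.detail = "no index phase for this tool"
            res.seconds = total_s
            return res, None
        cmd = _fill(adapter.index_cmd, ref=ref_path, index=index_path)
        code, s, p, err = run_command(cmd, timeout=timeout)
        total_s += s
        peak = max(peak, p)
        res.seconds, res.peak_rss_bytes = total_s, peak
        if code != 0:
            res.status = "failed"
            res.detail = err.strip()[:500]
        return res, None

    qfile = _dataset_query_file(dataset, query_class, fraction)
    out_path = work / f"{adapter.name}.{query_class}.{res.replicate}.out"
    if adapter.per_query:
        # one invocation per query line (non-default; measures process overhead)
        queries = read_bed(qfile)
        returned: dict[str, set[str]] = {}
        out_path.write_text("")
        for q in queries:
            tmp_q = work / "one_query.bed"
            write_bed([q], tmp_q)
            tmp_o = work / "one_query.out"
            cmd = _fill(adapter.query_cmd, ref=ref_path, query=tmp_q,
                        out=tmp_o, index=index_path)
            code, s, p, err = run_command(cmd, timeout=timeout)
            total_s += s
            peak = max(peak, p)
            if code != 0:
                res.status = "failed"
                res.detail = err.strip()[:500]
                res.seconds, res.peak_rss_bytes = total_s, peak
                return res, None
            with open(out_path, "a") as agg, open(tmp_o) as one:
                agg.write(one.read())
    else:
        cmd = _fill(adapter.query_cmd, ref=ref_path, query=qfile,
                    out=out_path, index=index_path)
        code, s, p, err = run_command(cmd, timeout=timeout)
        total_s += s
        peak = max(peak, p)
        if code != 0:
            res.status = "failed"
            res.detail = err.strip()[:500]
            res.seconds, res.peak_rss_bytes = total_s, peak
            return res, None
    res.seconds, res.peak_rss_bytes = total_s, peak
    returned = parse_tool_output(adapter.parser, out_path)
    return res, returned


# ---------------------------------------------------------------------------
# Whole-dataset benchmark


def bench_tool(
    tool: str | ToolAdapter,
    dataset: str | Path,
    replicates: int = 3,
    fractions: Sequence[float] | None = None,
    classes: Sequence[str] = QUERY_CLASSES,
    timeout: float | None = None,
) -> tuple[list[BenchResult], PrecisionReport]:
    """Run the full protocol for one tool on one simulated dataset.

    One index-phase record per replicate, then one query-phase record per
    (class, fraction, replicate); precision is scored from the last
    replicate's returns against the dataset's truth sidecar.
    """
    dataset = Path(dataset)
    truth = load_truth(dataset / "truth.tsv")
    results: list[BenchResult] = []
    basic_returns: dict[str, set[str]] = {}
    complex_counts: dict[str, int] = {}

    for rep in range(1, replicates + 1):
        res, _ = run_phase(tool, dataset, "index", replicate=rep, timeout=timeout)
        results.append(res)
        for qc in classes:
            fr_list: list[float | None]
            if qc == "complex" or not fractions:
                fr_list = [None]
            else:
                fr_list = list(fractions)
            for fr in fr_list:
                res, returned = run_phase(tool, dataset, "query", query_class=qc,
                                          fraction=fr, replicate=rep, timeout=timeout)
                results.append(res)
                full = fr is None or fr == 1.0
                if returned is not None and full:
                    if qc == "complex":
                        complex_counts.update({q: len(t) for q, t in returned.items()})
                    else:
                        basic_returns.update(returned)

    report = PrecisionReport()
    if basic_returns:
        b = score_basic(truth, basic_returns)
        report.basic_precision = b.basic_precision
        report.per_class = b.per_class
    if complex_counts:
        c = score_complex(truth, complex_counts)
        report.complex_mean_abs_distance = c.complex_mean_abs_distance
        report.complex_exact_fraction = c.complex_exact_fraction
    return results, report


# ---------------------------------------------------------------------------
# BED x BED annotation


def annotate(
    targets: str | Path,
    queries: str | Path,
    engine: str = "ailist",
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Intersect two BED files: for every query interval, every overlapping
    target interval, as (query, target) pairs in normalised target order.

    This is the generic building block for annotating variant positions with
    the regulatory elements (or any features) they fall in.
    """
    tgt = read_bed(targets)
    qry = read_bed(queries)
    index = build_engine(engine, tgt)
    out = []
    for q in qry:
        out.extend((q, t) for t in index.query(q))
    return out


def write_annotation(pairs, path: str | Path) -> None:
    """Write annotate() output as tab-joined query+target BED columns."""
    with open(path, "w") as fh:
        for q, t in pairs:
            fh.write(f"{q.chrom}\t{q.start}\t{q.end}\t{q.id}"
                     f"\t{t.chrom}\t{t.start}\t{t.end}\t{t.id}\n")
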