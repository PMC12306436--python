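"""Tabular summaries of benchmark runs.

The product is TSV, mirroring the quantities one would plot: per tool and
dataset, the index cost, total query runtime, each class's share of query
time, and per-(class, fraction) mean runtimes across replicates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .bench import BenchResult, PrecisionReport

RESULT_COLUMNS = [
    "tool", "dataset", "phase", "query_class", "fraction",
    "replicate", "seconds", "peak_rss_bytes", "status", "detail",
]


def results_frame(results: Iterable[BenchResult]) -> pd.DataFrame:
    rows = [r.as_row() for r in results]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Iterable[BenchResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False)


def write_precision(
    reports: dict[tuple[str, str], PrecisionReport], path: str | Path
) -> None:
    """One row per (tool, dataset) with the pooled precision metrics."""
    rows = []
    for (tool, dataset), rep in sorted(reports.items()):
        row = {
            "tool": tool,
            "dataset": dataset,
            "basic_precision": rep.basic_precision,
            "complex_mean_abs_distance": rep.complex_mean_abs_distance,
            "complex_exact_fraction": rep.complex_exact_fraction,
        }
        for cls, frac in sorted(rep.per_class.items()):
            row[f"precision_{cls}"] = frac
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summarize(results: pd.DataFrame | Iterable[BenchResult]) -> pd.DataFrame:
    """Aggregate raw measurements into per-tool/dataset summary rows.

    Emits one row per (tool, dataset) with:

    * ``index_seconds`` / ``index_peak_rss`` — mean over replicates;
    * ``query_seconds_total`` — mean total query time per replicate;
    * ``frac_<class>`` — each class's share of total query time (shares sum
      to 1 for every row with nonzero query time);
    * one ``q_<class>[_p<pct>]_seconds`` column per measured cell (mean over
      replicates).
    """
    if not isinstance(results, pd.DataFrame):
        results = results_frame(results)
    if results.empty:
        raise ValueError("no results to summarize")
    df = results[results["status"] == "ok"].copy()
    rows = []
    for (tool, dataset), grp in df.groupby(["tool", "dataset"], sort=True):
        row: dict = {"tool": tool, "dataset": dataset}
        idx = grp[grp["phase"] == "index"]
        if not idx.empty:
            row["index_seconds"] = idx["seconds"].mean()
            row["index_peak_rss"] = idx["peak_rss_bytes"].mean()
        q = grp[grp["phase"] == "query"]
        if not q.empty:
            n_rep = max(1, q["replicate"].nunique())
            total = q["seconds"].sum() / n_rep
            row["query_seconds_total"] = total
            by_class = q.groupby("query_class")["seconds"].sum() / n_rep
            for cls, secs in by_class.items():
                row[f"frac_{cls}"] = secs / total if total > 0 else float("nan")
            for (cls, frac), cell in q.groupby(
                ["query_class", "fraction"], sort=False, dropna=False
            ):
                name = f"q_{cls}"
                if frac != "" and frac is not None and not pd.isna(frac):
                    name += f"_p{int(round(float(frac) * 100))}"
                row[f"{name}_seconds"] = cell["seconds"].mean()
        rows.append(row)
    return pd.DataFrame(rows)
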