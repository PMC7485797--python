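"""Pipeline orchestration, replicate summaries, and serialisation.

The pipeline reads a dissection-record file, aggregates per-plot and pooled
stage-by-cause counts, builds life tables, runs the elimination analysis and
writes CSV/JSON artifacts plus a run log sufficient to reproduce the run.
Replicate-level summaries report untransformed means and standard errors of
per-plot percentages, the conventional presentation for plot-replicated
field designs; inferential comparisons (mixed models, post-hoc letters) are
deliberately out of scope.
"""

from __future__ import annotations

import json
import math
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .elimination import Mode, analyze
from .life_table import build_mdlt, pct_in_presence
from .records import CAUSES, DissectionRecord, StageCauseCounts, aggregate, read_records

__all__ = ["ReplicateSummary", "run_pipeline", "summarize_replicates", "PipelineResult"]


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SE of a per-cause percentage across replicate plots."""

    group: str
    cause: str
    mean_pct: float
    se_pct: float | None
    n_replicates: int


def summarize_replicates(
    per_plot: pd.DataFrame,
    grouping: Sequence[str],
    value_columns: Sequence[str] | None = None,
) -> list[ReplicateSummary]:
    """Summarise per-plot percentages as mean and SE per group.

    ``per_plot`` holds one row per replicate plot with grouping columns and
    one percentage column per cause.  The SE of the mean is reported only
    when a group has at least two replicates.
    """
    if value_columns is None:
        value_columns = [c.name for c in CAUSES if c.name in per_plot.columns]
    out: list[ReplicateSummary] = []
    for key, chunk in per_plot.groupby(list(grouping)):
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        for col in value_columns:
            values = chunk[col].astype(float)
            n = len(values)
            mean = float(values.mean())
            se = float(values.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
            out.append(ReplicateSummary(label, col, mean, se, n))
    return out


@dataclass
class PipelineResult:
    pooled_table: object
    pooled_elimination: object
    per_plot_percentages: pd.DataFrame
    summaries: list[ReplicateSummary]
    warnings: list[str]
    out_dir: Path


def _per_plot_percentages(
    records: list[DissectionRecord], grouping: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    notes: list[str] = []
    rows = []
    plot_keys = list(grouping) + ["block", "plot"]
    for counts in aggregate(records, plot_keys):
        if all(counts.l[s] == 0 for s in counts.l):
            notes.append(f"stratum {counts.stratum}: no infested units; skipped")
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = build_mdlt(counts, skip_empty_stages=True)
        except ValueError as exc:
            notes.append(f"stratum {counts.stratum}: {exc}; skipped")
            continue
        pct = pct_in_presence(table)
        parts = counts.stratum.split("/")
        row = dict(zip(plot_keys, parts))
        row.update({c.name: p for c, p in zip(CAUSES, pct)})
        rows.append(row)
    return pd.DataFrame(rows), notes


def run_pipeline(
    records_path: str | Path,
    out_dir: str | Path,
    grouping: Sequence[str] = ("site", "year", "cultivar"),
    mode: Mode = "totals",
    seed: int | None = None,
) -> PipelineResult:
    """Run the full records -> life table -> elimination pipeline.

    Builds the pooled table and per-plot tables, summarises per-cause
    percentages across replicate plots, and writes the artifact set
    (life-table CSV and JSON, elimination CSV, summary CSV, run log) to
    ``out_dir``.  Strata without infested units are skipped with a warning;
    an empty records file yields empty outputs and a zero exit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, diagnostics = read_records(records_path)
    notes = [f"rejected {d}" for d in diagnostics]

    pooled_table = pooled_elim = None
    if records:
        pooled_counts = aggregate(records)[0]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            pooled_table = build_mdlt(pooled_counts, skip_empty_stages=True)
            notes.extend(str(w.message) for w in caught)
        pooled_table.to_csv(out / "life_table_pooled.csv")
        pooled_table.to_json(out / "life_table_pooled.json")
        pooled_elim = analyze(pooled_table, mode=mode)
        pooled_elim.to_frame().to_csv(out / "elimination_pooled.csv", index=False)

    per_plot, plot_notes = _per_plot_percentages(records, grouping)
    notes.extend(plot_notes)
    per_plot.to_csv(out / "per_plot_percentages.csv", index=False)

    summaries: list[ReplicateSummary] = []
    if len(per_plot):
        summaries = summarize_replicates(per_plot, grouping)
        pd.DataFrame(
            [
                {
                    "group": s.group,
                    "cause": s.cause,
                    "mean_pct": s.mean_pct,
                    "se_pct": s.se_pct,
                    "n_replicates": s.n_replicates,
                }
                for s in summaries
            ]
        ).to_csv(out / "replicate_summary.csv", index=False)

    log = {
        "records_file": str(records_path),
        "n_records": len(records),
        "n_rejected_rows": len(diagnostics),
        "grouping": list(grouping),
        "mode": mode,
        "seed": seed,
        "package_version": __version__,
        "python": sys.version.split()[0],
        "warnings": notes,
        "strata_processed": sorted(per_plot.apply(
            lambda r: "/".join(str(r[g]) for g in grouping), axis=1
        ).unique().tolist()) if len(per_plot) else [],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))

    return PipelineResult(
        pooled_table=pooled_table,
        pooled_elimination=pooled_elim,
        per_plot_percentages=per_plot,
        summaries=summaries,
        warnings=notes,
        out_dir=out,
    )


def counts_to_table_csv(
    counts_path: str | Path, out_path: str | Path, stratum: str = "POOLED"
) -> None:
    """Build and serialise a life table directly from an aggregated-counts
    CSV (stage, l_x, d_<cause> columns)."""
    frame = pd.read_csv(counts_path)
    counts = StageCauseCounts.from_frame(frame, stratum=stratum)
    table = build_mdlt(counts)
    table.to_csv(out_path)
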