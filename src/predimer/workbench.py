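"""Tables, configuration and the two analysis pipelines.

The trace pipeline chains quantification -> classification -> summaries ->
between-strain comparisons on a long-format trace table (one row per
strain, replicate, cell, channel and time point).  The grammar pipeline
reads promoters from FASTA with optional nucleosome intervals in BED-like
form and emits dimer calls and induction predictions.

All tables are plain CSV; every result bundle carries the hash of the
configuration that produced it, and re-running with the same configuration
and seed reproduces the tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import population
from .classify import (
    CellCall,
    ClassifierConfig,
    classify_cell,
    reference_threshold,
    sign_test_induction,
)
from .grammar import AffinityTable, GrammarConfig, PromoterModel, scan_promoter
from .metrics import Trace, TraceMetrics, quantify_trace
from .population import CohortSummary
from .synthetic import CohortConfig, PairedTraceSet, simulate_cohort

__all__ = [
    "TRACE_COLUMNS",
    "RunConfig",
    "read_trace_table",
    "write_trace_table",
    "cohort_to_table",
    "table_to_traces",
    "read_promoters",
    "classify_cohort",
    "summarize_cohort",
    "run_pipeline",
]

logger = logging.getLogger("predimer")

TRACE_COLUMNS = [
    "strain",
    "replicate",
    "cell_id",
    "channel",
    "time_min",
    "nuclear_enrichment",
]

KEY_COLUMNS = TRACE_COLUMNS[:5]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    reference_strain: str
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cohorts: Mapping[str, CohortConfig] | None = None
    excluded_replicates: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Mapping):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


# --------------------------------------------------------------------------
# Trace tables
# --------------------------------------------------------------------------


def write_trace_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated trace table as CSV."""
    _validate_trace_table(table)
    table.to_csv(path, index=False)


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trace-table CSV.

    Rejects missing columns, duplicate (strain, replicate, cell, channel,
    time) keys and ragged per-trace time grids, naming the offending rows.
    """
    table = pd.read_csv(path)
    _validate_trace_table(table)
    return table


def _validate_trace_table(table: pd.DataFrame) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trace table is missing columns: {missing}")
    dup = table.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        offender = table.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise ValueError(f"duplicate trace-table key: {offender}")
    sizes = table.groupby(["strain", "replicate", "cell_id", "channel"])[
        "time_min"
    ].nunique()
    per_strain = sizes.groupby(level=0).nunique()
    ragged = per_strain[per_strain > 1]
    if not ragged.empty:
        raise ValueError(
            f"ragged time grids within strain(s): {list(ragged.index)}"
        )


def cohort_to_table(cohort: PairedTraceSet, strain: str) -> pd.DataFrame:
    """Flatten a simulated cohort into the long trace-table format."""
    rows = []
    for cell in cohort.cells:
        for trace in (cell.trace_y, cell.trace_r):
            for t, v in zip(trace.times, trace.values):
                rows.append(
                    (strain, cell.replicate, cell.cell_id, trace.channel, t, v)
                )
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def table_to_traces(
    table: pd.DataFrame,
) -> list[tuple[str, int, Trace]]:
    """Explode a trace table into (strain, replicate, Trace) records."""
    out = []
    for (strain, rep, cell, channel), grp in table.groupby(
        ["strain", "replicate", "cell_id", "channel"], sort=True
    ):
        grp = grp.sort_values("time_min")
        out.append(
            (
                str(strain),
                int(rep),
                Trace(
                    cell_id=str(cell),
                    channel=str(channel),
                    times=grp["time_min"].to_numpy(float),
                    values=grp["nuclear_enrichment"].to_numpy(float),
                ),
            )
        )
    return out


# --------------------------------------------------------------------------
# Promoter inputs
# --------------------------------------------------------------------------


def read_promoters(
    fasta_path: str | Path,
    nucleosome_bed: str | Path | None = None,
    core_side: str = "3prime",
) -> dict[str, PromoterModel]:
    """Load promoters from FASTA, with optional nucleosome dyads.

    The BED-like file has three whitespace-separated columns: promoter
    name, 0-based half-open footprint start and end *in promoter
    coordinates counted from the 5' end*; the dyad is the interval
    midpoint, converted to the negative-offset promoter convention.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    dyads: dict[str, list[int]] = {name: [] for name in records}
    if nucleosome_bed is not None:
        for line_no, line in enumerate(Path(nucleosome_bed).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{nucleosome_bed}:{line_no}: need 3 columns")
            name, lo, hi = parts[0], int(parts[1]), int(parts[2])
            if name not in records:
                raise ValueError(
                    f"{nucleosome_bed}:{line_no}: unknown promoter {name!r}"
                )
            mid = (lo + hi) // 2
            dyads[name].append(mid - len(records[name]))
    return {
        name: PromoterModel(
            sequence=seq, core_side=core_side, nucleosome_dyads=tuple(dyads[name])
        )
        for name, seq in records.items()
    }


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def quantify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trace metrics (basal, EO, RT) for every trace in the table."""
    rows = []
    for strain, rep, trace in table_to_traces(table):
        m = quantify_trace(trace)
        rows.append(
            {
                "strain": strain,
                "replicate": rep,
                "cell_id": m.cell_id,
                "channel": m.channel,
                "basal": m.basal,
                "expression_output": m.expression_output,
                "response_time": m.response_time,
            }
        )
    return pd.DataFrame(rows)


def classify_table(
    table: pd.DataFrame,
    metrics: pd.DataFrame,
    reference_strain: str,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Per-cell calls against the reference strain's thresholds.

    Thresholds come from the reference strain's red (test) channel over all
    its cells; the sign test is evaluated per trace.
    """
    ref = metrics[
        (metrics["strain"] == reference_strain) & (metrics["channel"] == "R")
    ]
    if ref.empty:
        raise ValueError(f"reference strain {reference_strain!r} not in table")
    ref_metrics = [
        TraceMetrics(str(r.cell_id), "R", r.basal, r.expression_output, None)
        for r in ref.itertuples()
    ]
    thresholds = reference_threshold(ref_metrics, cfg)
    metric_index = metrics.set_index(["strain", "replicate", "cell_id", "channel"])
    rows = []
    for strain, rep, trace in table_to_traces(table):
        rec = metric_index.loc[(strain, rep, trace.cell_id, trace.channel)]
        m = TraceMetrics(
            trace.cell_id,
            trace.channel,
            float(rec["basal"]),
            float(rec["expression_output"]),
            None if pd.isna(rec["response_time"]) else float(rec["response_time"]),
        )
        st = sign_test_induction(trace, m.basal, cfg)
        call = classify_cell(m, st, thresholds, cfg)
        rows.append(
            {
                "strain": strain,
                "replicate": rep,
                "cell_id": call.cell_id,
                "channel": call.channel,
                "class": call.cls,
                "p_value": call.p_value,
                "eo_ratio": call.eo_ratio,
            }
        )
    return pd.DataFrame(rows)


def summarize_strain(
    strain: str,
    metrics: pd.DataFrame,
    calls: pd.DataFrame,
) -> CohortSummary:
    """Replicate-level fractions, mean EO and mean dRT for one strain.

    dRT per cell is RT(R) - RT(Y), restricted to cells called responding in
    both channels.
    """
    merged = metrics.merge(
        calls[["strain", "replicate", "cell_id", "channel", "class"]],
        on=["strain", "replicate", "cell_id", "channel"],
    )
    sub = merged[merged["strain"] == strain]
    if sub.empty:
        raise ValueError(f"no cells for strain {strain!r}")
    per_rep = {}
    delta_all: list[float] = []
    for rep, grp in sub.groupby("replicate"):
        red = grp[grp["channel"] == "R"].set_index("cell_id")
        yellow = grp[grp["channel"] == "Y"].set_index("cell_id")
        n = len(red)
        strong = (red["class"] == "strong").sum() / n
        weak = (red["class"] == "weak").sum() / n
        both = red.join(yellow, lsuffix="_r", rsuffix="_y", how="inner")
        responding_both = both[
            (both["class_r"] != "non")
            & (both["class_y"] != "non")
            & both["response_time_r"].notna()
            & both["response_time_y"].notna()
        ]
        drt = (
            responding_both["response_time_r"] - responding_both["response_time_y"]
        ).to_numpy(float)
        delta_all.extend(drt.tolist())
        per_rep[rep] = {
            "fraction_total": strong + weak,
            "fraction_strong": strong,
            "fraction_weak": weak,
            "mean_eo": red["expression_output"].mean(),
            "mean_delta_rt": float(np.mean(drt)) if drt.size else np.nan,
        }
    frame = pd.DataFrame(per_rep).T.sort_index()
    frame.index.name = "replicate"
    return CohortSummary(
        strain=strain, per_replicate=frame, delta_rt=np.array(delta_all)
    )


def classify_cohort(
    cohort: PairedTraceSet,
    thresholds: Mapping[str, float] | None = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[tuple]:
    """In-memory quantification + classification of a simulated cohort.

    Returns one ``(cell, metrics_y, metrics_r, call_y, call_r)`` tuple per
    cell.  When ``thresholds`` is None the cohort's own red channel serves
    as the reference.
    """
    quantified = [
        (cell, quantify_trace(cell.trace_y), quantify_trace(cell.trace_r))
        for cell in cohort.cells
    ]
    if thresholds is None:
        thresholds = reference_threshold((mr for _, _, mr in quantified), cfg)
    out = []
    for cell, my, mr in quantified:
        call_y = classify_cell(
            my, sign_test_induction(cell.trace_y, my.basal, cfg), thresholds, cfg
        )
        call_r = classify_cell(
            mr, sign_test_induction(cell.trace_r, mr.basal, cfg), thresholds, cfg
        )
        out.append((cell, my, mr, call_y, call_r))
    return out


def summarize_cohort(
    cohort: PairedTraceSet,
    strain: str = "cohort",
    thresholds: Mapping[str, float] | None = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> CohortSummary:
    """Replicate-level summary of a simulated cohort, entirely in memory.

    Fractions and mean EO are computed on the red (test) channel; dRT on
    cells responding in both channels.
    """
    classified = classify_cohort(cohort, thresholds, cfg)
    per_rep: dict[int, dict] = {}
    delta_all: list[float] = []
    for rep in cohort.replicate_ids():
        group = [rec for rec in classified if rec[0].replicate == rep]
        n = len(group)
        strong = sum(call_r.cls == "strong" for *_, call_r in group) / n
        weak = sum(call_r.cls == "weak" for *_, call_r in group) / n
        drt = [
            mr.response_time - my.response_time
            for _, my, mr, call_y, call_r in group
            if call_y.responding
            and call_r.responding
            and my.response_time is not None
            and mr.response_time is not None
        ]
        delta_all.extend(drt)
        per_rep[rep] = {
            "fraction_total": strong + weak,
            "fraction_strong": strong,
            "fraction_weak": weak,
            "mean_eo": float(
                np.mean([mr.expression_output for _, _, mr, _, _ in group])
            ),
            "mean_delta_rt": float(np.mean(drt)) if drt else np.nan,
        }
    frame = pd.DataFrame(per_rep).T.sort_index()
    frame.index.name = "replicate"
    return CohortSummary(
        strain=strain, per_replicate=frame, delta_rt=np.array(delta_all)
    )


def run_pipeline(
    config: RunConfig, outdir: str | Path | None = None
) -> dict:
    """Simulate (or accept) cohorts, then quantify, classify, summarize, compare.

    Returns a bundle with the metrics, calls and summary tables, the
    comparison records against the reference strain and the configuration
    hash; writes everything (plus a provenance copy of the configuration)
    under ``outdir`` when given.
    """
    if config.cohorts is None:
        raise ValueError("RunConfig.cohorts must map strain -> CohortConfig")
    if config.reference_strain not in config.cohorts:
        raise ValueError(
            f"reference strain {config.reference_strain!r} absent from cohorts"
        )
    tables = []
    for i, (strain, cohort_cfg) in enumerate(sorted(config.cohorts.items())):
        seeded = dataclasses.replace(
            cohort_cfg, seed=(config.seed + 7919 * i) % (2**31)
        )
        excl = {r for s, r in config.excluded_replicates if s == strain}
        cohort = simulate_cohort(seeded)
        tab = cohort_to_table(cohort, strain)
        if excl:
            logger.warning("strain %s: excluding replicates %s", strain, sorted(excl))
            tab = tab[~tab["replicate"].isin(excl)]
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True)

    metrics = quantify_table(table)
    calls = classify_table(table, metrics, config.reference_strain, config.classifier)
    summaries = {
        strain: summarize_strain(strain, metrics, calls)
        for strain in sorted(config.cohorts)
    }
    reference = summaries[config.reference_strain]
    comparisons = []
    for strain, summary in summaries.items():
        if strain == config.reference_strain:
            continue
        if summary.n_replicates < 2 or reference.n_replicates < 2:
            logger.warning(
                "strain %s: fewer than 2 replicates, comparison skipped", strain
            )
            continue
        for metric in ("EO", "timing", "fraction"):
            comparisons.append(
                population.compare_strains(summary, reference, metric)
            )
        if summary.delta_rt.size and reference.delta_rt.size:
            comparisons.append(
                population.compare_delta_rt(
                    summary.delta_rt, reference.delta_rt, strain,
                    config.reference_strain,
                )
            )
    bundle = {
        "config_hash": config.config_hash(),
        "traces": table,
        "metrics": metrics,
        "calls": calls,
        "summaries": summaries,
        "comparisons": comparisons,
    }
    if outdir is not None:
        _write_bundle(bundle, config, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = bundle["config_hash"]
    for name in ("traces", "metrics", "calls"):
        df = bundle[name].copy()
        df["config_hash"] = h
        df.to_csv(outdir / f"{name}.csv", index=False)
    summary_rows = []
    for strain, summary in bundle["summaries"].items():
        frame = summary.per_replicate.reset_index()
        frame.insert(0, "strain", strain)
        summary_rows.append(frame)
    summary_frame = pd.concat(summary_rows, ignore_index=True)
    summary_frame["config_hash"] = h
    summary_frame.to_csv(outdir / "summaries.csv", index=False)
    comp = [
        dataclasses.asdict(c) | {"config_hash": h} for c in bundle["comparisons"]
    ]
    (outdir / "comparisons.json").write_text(json.dumps(comp, indent=2))
    (outdir / "config.json").write_text(
        json.dumps(_as_jsonable(config) | {"config_hash": h}, indent=2)
    )


def scan_promoters(
    models: Mapping[str, PromoterModel],
    affinity: AffinityTable = AffinityTable(),
    min_weight: float = 0.0,
    grammar: GrammarConfig = GrammarConfig(),
) -> pd.DataFrame:
    """Grammar pass over a set of promoters, one row per called dimer."""
    rows = []
    for name, model in sorted(models.items()):
        for rec in scan_promoter(model, affinity, min_weight, grammar=grammar):
            rows.append({"promoter": name} | rec)
    return pd.DataFrame(rows)
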