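"""Population-level summaries and between-strain statistics.

Aggregates per-cell calls and metrics into the readouts used to compare
promoter variants: responding fractions per replicate, median dynamics with
interquartile band, the distribution of response-time differences between
the two reporters (dRT), EO normalisation against a reference strain, and
the replicate-level significance tests (t-test on replicate means for EO /
timing / fraction; Wilcoxon rank-sum for dRT distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CellCall
from .metrics import Trace, TraceMetrics

__all__ = [
    "CohortSummary",
    "ComparisonResult",
    "median_dynamics",
    "responding_fractions",
    "delta_response_time",
    "normalize_expression",
    "compare_strains",
    "compare_delta_rt",
    "correlate_channels",
]

ALPHA = 0.05

#: metric -> significance-flag letter (O = output, T = timing, F = fraction)
FLAG_LETTERS = {"EO": "O", "timing": "T", "fraction": "F"}


@dataclass
class CohortSummary:
    """Per-strain aggregate across replicates.

    ``per_replicate`` is a DataFrame indexed by replicate with columns
    ``fraction_total``, ``fraction_strong``, ``fraction_weak``, ``mean_eo``
    and ``mean_delta_rt``; ``delta_rt`` pools dRT values over replicates.
    """

    strain: str
    per_replicate: pd.DataFrame
    delta_rt: np.ndarray = field(default_factory=lambda: np.array([]))
    median_trajectory: pd.DataFrame | None = None

    @property
    def mean_eo(self) -> float:
        return float(self.per_replicate["mean_eo"].mean())

    @property
    def n_replicates(self) -> int:
        return int(len(self.per_replicate))


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one between-strain test.

    ``flag`` is the letter (O/T/F) when p < 0.05 under the matching test,
    or ``None`` when the difference is not significant or the test could
    not run.
    """

    strain_a: str
    strain_b: str
    metric: str
    test: str
    p_value: float | None
    flag: str | None


def median_dynamics(traces: Sequence[Trace]) -> pd.DataFrame:
    """Median and 25th/75th percentile trajectory of a trace population.

    All traces must share the time grid.  Percentiles use linear
    interpolation between order statistics (numpy's default), so for three
    constant traces at 0/1/2 the band is [0.5, 1.5].
    """
    if not traces:
        raise ValueError("no traces given")
    grid = traces[0].times
    for t in traces[1:]:
        if t.times.shape != grid.shape or not np.allclose(t.times, grid):
            raise ValueError("traces are on heterogeneous time grids")
    stack = np.vstack([t.values for t in traces])
    return pd.DataFrame(
        {
            "time_min": grid,
            "median": np.median(stack, axis=0),
            "p25": np.percentile(stack, 25, axis=0),
            "p75": np.percentile(stack, 75, axis=0),
        }
    )


def responding_fractions(
    calls: Iterable[tuple[str, CellCall]],
) -> pd.DataFrame:
    """Fractions of responding cells per replicate, plus the across-replicate mean.

    ``calls`` yields ``(replicate_id, CellCall)`` pairs.  Returns a frame
    indexed by replicate (with a final ``"mean"`` row) and columns
    ``fraction_total``, ``fraction_strong``, ``fraction_weak``; strong and
    weak always sum to total.
    """
    rows = [
        {"replicate": rep, "cls": call.cls} for rep, call in calls
    ]
    if not rows:
        raise ValueError("no calls given")
    df = pd.DataFrame(rows)
    out = {}
    for rep, grp in df.groupby("replicate"):
        n = len(grp)
        strong = float((grp["cls"] == "strong").sum()) / n
        weak = float((grp["cls"] == "weak").sum()) / n
        out[rep] = {
            "fraction_total": strong + weak,
            "fraction_strong": strong,
            "fraction_weak": weak,
        }
    frame = pd.DataFrame(out).T.sort_index()
    frame.loc["mean"] = frame.mean()
    frame.index.name = "replicate"
    return frame


def delta_response_time(
    paired: Iterable[tuple[CellCall, TraceMetrics, CellCall, TraceMetrics]],
) -> np.ndarray:
    """dRT = RT(red test) - RT(yellow reference), per doubly-responding cell.

    ``paired`` yields ``(call_Y, metrics_Y, call_R, metrics_R)`` per cell.
    Cells are included only when both channels are called responding and
    both response times are defined; the result may be empty.
    """
    out = []
    for call_y, met_y, call_r, met_r in paired:
        if not (call_y.responding and call_r.responding):
            continue
        if met_y.response_time is None or met_r.response_time is None:
            continue
        out.append(met_r.response_time - met_y.response_time)
    return np.array(out, dtype=float)


def normalize_expression(
    cohort: CohortSummary, reference: CohortSummary
) -> np.ndarray:
    """Per-replicate mean EO of ``cohort`` divided by the reference mean EO."""
    ref = reference.mean_eo
    if ref <= 0:
        raise ValueError("reference mean EO must be > 0")
    return cohort.per_replicate["mean_eo"].to_numpy() / ref


def compare_strains(
    a: CohortSummary,
    b: CohortSummary,
    metric: str,
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sample t-test on replicate-level means of one summary metric.

    ``metric`` is ``"EO"`` (mean EO, flag O), ``"timing"`` (mean dRT,
    flag T) or ``"fraction"`` (total responding fraction, flag F).  Welch's
    t-test by default (``equal_var=False``); two-sided.  With fewer than two
    replicates on either side no test is run and the flag is ``None``.
    """
    column = {
        "EO": "mean_eo",
        "timing": "mean_delta_rt",
        "fraction": "fraction_total",
    }[metric]
    xa = a.per_replicate[column].dropna().to_numpy()
    xb = b.per_replicate[column].dropna().to_numpy()
    if xa.size < 2 or xb.size < 2:
        return ComparisonResult(
            a.strain, b.strain, metric, "t-test", None, None
        )
    res = stats.ttest_ind(xa, xb, equal_var=equal_var)
    p = float(res.pvalue)
    flag = FLAG_LETTERS[metric] if (np.isfinite(p) and p < ALPHA) else None
    return ComparisonResult(a.strain, b.strain, metric, "t-test", p, flag)


def compare_delta_rt(
    a: np.ndarray,
    b: np.ndarray,
    strain_a: str = "a",
    strain_b: str = "b",
) -> ComparisonResult:
    """Wilcoxon rank-sum test between two dRT distributions (flag T).

    Uses the exact Mann-Whitney U null when both samples are small and
    tie-free, so a 1-vs-1 comparison can never be significant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both dRT distributions must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    flag = "T" if p < ALPHA else None
    return ComparisonResult(strain_a, strain_b, "dRT-distribution", "wilcoxon-ranksum", p, flag)


def correlate_channels(
    paired_traces: Iterable[tuple[Trace, Trace]],
    timepoints: Sequence[float] = (0.0, 20.0, 40.0, 60.0),
) -> Mapping[float, float]:
    """Spearman correlation between channels across cells, per time point.

    ``paired_traces`` yields ``(trace_Y, trace_R)`` per cell; for each
    requested time point the rank correlation of the per-cell values in the
    two channels is returned.  Needs at least three pairs.
    """
    pairs = list(paired_traces)
    if len(pairs) < 3:
        raise ValueError("need >= 3 paired traces for a rank correlation")
    out: dict[float, float] = {}
    for tp in timepoints:
        ys, rs = [], []
        for ty, tr in pairs:
            iy = np.nonzero(np.isclose(ty.times, tp))[0]
            ir = np.nonzero(np.isclose(tr.times, tp))[0]
            if iy.size == 0 or ir.size == 0:
                raise ValueError(f"time point {tp} not on the trace grid")
            ys.append(ty.values[iy[0]])
            rs.append(tr.values[ir[0]])
        rho = stats.spearmanr(ys, rs).statistic
        out[float(tp)] = float(rho)
    return out
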