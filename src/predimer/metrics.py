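"""Per-trace quantification of reporter induction.

A :class:`Trace` holds the nuclear-enrichment time series of one cell in one
fluorescence channel (yellow reference or red test reporter).  Three scalar
metrics summarise it:

* **basal** — mean nuclear enrichment over the first three time points,
  i.e. the pre-induction level of the reporter;
* **expression output (EO)** — maximum of the trace minus the basal level,
  the amplitude of the induction;
* **response time (RT)** — the time of the first frame whose value strictly
  exceeds ``basal + fraction * EO`` (20 % of the cell's own output by
  default).  A trace that never crosses the threshold has no response time.

No smoothing or interpolation is applied: RT is reported on the acquisition
grid, and the threshold comparison is strict (``>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trace",
    "TraceMetrics",
    "basal_level",
    "expression_output",
    "response_time",
    "quantify_trace",
]

#: Frames averaged for the basal level.
BASAL_WINDOW = 3

#: Fraction of a cell's own expression output defining its response-time
#: threshold.
RT_FRACTION = 0.20

#: Minimum trace length: the 3-frame basal window and the 5-frame induction
#: window used downstream must not overlap.
MIN_FRAMES = 8


@dataclass(frozen=True)
class Trace:
    """One cell x one channel nuclear-enrichment time series.

    Parameters
    ----------
    cell_id:
        Identifier of the cell within its replicate.
    channel:
        ``"Y"`` (yellow, reference promoter) or ``"R"`` (red, test promoter).
    times:
        Acquisition times in minutes, strictly increasing and equispaced
        within tolerance.
    values:
        Nuclear enrichment in arbitrary units, one per time point.
    """

    cell_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.channel not in ("Y", "R"):
            raise ValueError(f"channel must be 'Y' or 'R', got {self.channel!r}")
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size < MIN_FRAMES:
            raise ValueError(
                f"trace needs >= {MIN_FRAMES} frames, got {times.size}"
            )
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        # equispaced within 10% of the median interval
        if np.any(np.abs(dt - np.median(dt)) > 0.1 * np.median(dt)):
            raise ValueError("times must be equispaced (within 10% tolerance)")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise ValueError("times and values must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TraceMetrics:
    """Scalar summary of one trace: basal level, EO and RT.

    ``response_time`` is ``None`` when the trace never exceeds its
    response-time threshold (e.g. a flat trace with EO = 0); no sentinel
    number is ever used.
    """

    cell_id: str
    channel: str
    basal: float
    expression_output: float
    response_time: float | None = field(default=None)


def basal_level(trace: Trace, window: int = BASAL_WINDOW) -> float:
    """Mean nuclear enrichment of the first ``window`` time points.

    The default window of 3 frames covers the pre-induction acquisitions
    (the stimulus is added just before the third frame and the reporter
    response lags behind it).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if trace.n_frames < window:
        raise ValueError(
            f"trace has {trace.n_frames} frames, needs >= {window} for basal"
        )
    return float(np.mean(trace.values[:window]))


def expression_output(trace: Trace, basal: float) -> float:
    """Maximum of the trace minus the basal level.

    Non-negative whenever ``basal`` was computed from the trace's own first
    frames, since the global maximum is at least the mean of any subset.
    """
    return float(np.max(trace.values) - basal)


def response_time(
    trace: Trace,
    basal: float,
    eo: float,
    fraction: float = RT_FRACTION,
) -> float | None:
    """Time of the first frame strictly above ``basal + fraction * eo``.

    Returns ``None`` when no frame exceeds the threshold — in particular
    whenever ``eo`` is 0, because the comparison is strict.
    """
    if eo < 0:
        raise ValueError("expression output must be >= 0")
    threshold = basal + fraction * eo
    above = np.nonzero(trace.values > threshold)[0]
    if above.size == 0:
        return None
    return float(trace.times[above[0]])


def quantify_trace(
    trace: Trace,
    window: int = BASAL_WINDOW,
    fraction: float = RT_FRACTION,
) -> TraceMetrics:
    """Compute basal, EO and RT of one trace in the standard order."""
    basal = basal_level(trace, window=window)
    eo = expression_output(trace, basal)
    rt = response_time(trace, basal, eo, fraction=fraction)
    return TraceMetrics(
        cell_id=trace.cell_id,
        channel=trace.channel,
        basal=basal,
        expression_output=eo,
        response_time=rt,
    )
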