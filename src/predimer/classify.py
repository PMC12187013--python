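"""Per-cell responder classification.

A cell is called *expressing* only when it satisfies two independent
criteria:

1. the last five points of its trace are significantly above the basal level
   (one-sided exact sign test, p < 0.05), and
2. its expression output exceeds a threshold set at 20 % of the mean
   expression output of a reference strain (computed over *all* reference
   cells, responders or not).

Expressing cells are further split into *strong* (EO above 50 % of the
reference mean) and *weak* (between 20 % and 50 %).  A cell satisfying only
one criterion — e.g. a high-basal drifting trace that passes the sign test
but has a tiny EO — is *non*-expressing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .metrics import Trace, TraceMetrics

__all__ = [
    "ClassifierConfig",
    "SignTestResult",
    "CellCall",
    "sign_test_induction",
    "reference_threshold",
    "classify_cell",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable constants of the two-criterion classification rule.

    ``signtest_window`` — number of trailing frames tested against basal
    (default 5).  ``alpha`` — sign-test significance level (default 0.05).
    ``threshold_fraction`` / ``strong_fraction`` — the expression and
    strong-expression cutoffs as fractions of the reference strain's mean
    EO (defaults 20 % and 50 %).
    """

    signtest_window: int = 5
    alpha: float = 0.05
    threshold_fraction: float = 0.20
    strong_fraction: float = 0.50

    def __post_init__(self) -> None:
        if self.signtest_window < 1:
            raise ValueError("signtest_window must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.threshold_fraction < self.strong_fraction <= 1:
            raise ValueError(
                "need 0 < threshold_fraction < strong_fraction <= 1"
            )


@dataclass(frozen=True)
class SignTestResult:
    significant: bool
    p_value: float


@dataclass(frozen=True)
class CellCall:
    """Expression class of one cell in one channel.

    ``cls`` is one of ``"non"``, ``"weak"``, ``"strong"`` — exhaustive and
    mutually exclusive.  ``eo_ratio`` is the cell's EO divided by the
    reference strain's mean EO.
    """

    cell_id: str
    channel: str
    cls: str
    p_value: float
    eo_ratio: float

    @property
    def responding(self) -> bool:
        return self.cls != "non"


def sign_test_induction(
    trace: Trace,
    basal: float,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> SignTestResult:
    """One-sided exact sign test of the trace tail against the basal level.

    The last ``cfg.signtest_window`` values minus ``basal`` are tested for a
    positive median.  Exact ties are dropped (standard sign-test
    convention); among the ``m`` non-ties with ``k`` positives the p-value
    is ``P(Bin(m, 1/2) >= k)``.  A window that is entirely tied with the
    basal level is not significant (p = 1 by convention).
    """
    w = cfg.signtest_window
    if trace.n_frames < w + 3:
        raise ValueError(
            f"trace needs >= {w + 3} frames for a {w}-point sign test"
        )
    diffs = trace.values[-w:] - basal
    nonzero = diffs[diffs != 0]
    m = int(nonzero.size)
    if m == 0:
        return SignTestResult(significant=False, p_value=1.0)
    k = int(np.sum(nonzero > 0))
    p = stats.binomtest(k, m, p=0.5, alternative="greater").pvalue
    return SignTestResult(significant=bool(p < cfg.alpha), p_value=float(p))


def reference_threshold(
    reference_metrics: Iterable[TraceMetrics],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> dict[str, float]:
    """Expression and strong-expression thresholds from a reference cohort.

    Both are fractions of the mean EO over *all* reference cells —
    non-responders included, which anchors the thresholds to the overall
    population rather than to the responding tail.
    """
    eos = np.array([m.expression_output for m in reference_metrics], dtype=float)
    if eos.size == 0:
        raise ValueError("reference cohort is empty")
    mean_eo = float(np.mean(eos))
    return {
        "mean_reference_eo": mean_eo,
        "expr_threshold": cfg.threshold_fraction * mean_eo,
        "strong_threshold": cfg.strong_fraction * mean_eo,
    }


def classify_cell(
    metrics: TraceMetrics,
    signtest: SignTestResult,
    thresholds: dict[str, float],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> CellCall:
    """Apply the two-criterion rule to one cell.

    Responding requires a significant sign test *and* EO strictly above the
    expression threshold; responders with EO strictly above the strong
    threshold are ``"strong"``, the rest ``"weak"``.  Both boundaries are
    strict (the rule is that the output *exceeds* the cutoff).
    """
    eo = metrics.expression_output
    mean_ref = thresholds["mean_reference_eo"]
    eo_ratio = eo / mean_ref if mean_ref > 0 else float("inf")
    if signtest.significant and eo > thresholds["expr_threshold"]:
        cls = "strong" if eo > thresholds["strong_threshold"] else "weak"
    else:
        cls = "non"
    return CellCall(
        cell_id=metrics.cell_id,
        channel=metrics.channel,
        cls=cls,
        p_value=signtest.p_value,
        eo_ratio=eo_ratio,
    )
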