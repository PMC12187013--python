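"""Synthetic dual-reporter cohorts and annotated promoter sequences.

The microscopy data behind the dual dPSTR assay (paired yellow reference
and red test reporters imaged every 5 minutes for 100 minutes, pheromone
added just before the third time point) is not publicly deposited, so this
module generates cohorts with known ground truth for every downstream
stage:

* **Traces** — per cell, a basal level plus (for responders) a saturating
  induction ramp with a log-normal amplitude, a per-cell onset delay shared
  between the two channels (the cell-cycle component of the response), a
  programmed test-vs-reference channel offset (the quantity recovered as
  the response-time difference dRT), per-channel onset jitter, and i.i.d.
  Gaussian noise.
* **Promoters** — random background sequence with PRE dimers, PRE-like
  variants, poly-dA/dT tracts and nucleosome intervals planted at known
  positions.  Background bases that would spell a PRE(-like) hexamer on
  either strand outside the planted elements are rejected and redrawn, so
  every motif the scanner finds was planted — a generator guarantee the
  round-trip tests rely on.

Identical configuration and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grammar import (
    CONSENSUS,
    AffinityTable,
    PromoterModel,
    reverse_complement,
)
from .metrics import Trace

__all__ = [
    "CohortConfig",
    "PairedCell",
    "PairedTraceSet",
    "PlantedElement",
    "PromoterSpec",
    "simulate_cohort",
    "simulate_promoter",
]


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a simulated cohort.

    Acquisition follows the assay design: ``n_frames`` frames every
    ``frame_interval`` minutes (21 x 5 min = 100 min), stimulus added just
    before frame ``stimulus_frame`` (1-based; default 3, so the first three
    frames form the basal window).  ``responder_fraction`` is the Bernoulli
    probability that a cell responds at all; responder amplitudes are
    log-normal with mean ``amplitude_mean`` and coefficient of variation
    ``amplitude_cv``.  The onset of each responding cell is the stimulus
    time plus a shared normal delay (sd ``delay_shared_sd``, the cell-cycle
    component common to both channels), plus ``delay_channel_offset`` for
    the red test channel only (the programmed dRT), plus per-channel normal
    jitter (sd ``delay_channel_sd``).  The response rises as
    ``1 - exp(-(t - onset)/rise_time)`` and every sample carries additive
    Gaussian noise of sd ``noise_sd``.
    """

    n_cells: int = 200
    n_replicates: int = 3
    frame_interval: float = 5.0
    n_frames: int = 21
    stimulus_frame: int = 3
    responder_fraction: float = 0.6
    basal_mean: float = 1.0
    basal_sd: float = 0.1
    amplitude_mean: float = 5.0
    amplitude_cv: float = 0.3
    delay_shared_sd: float = 5.0
    delay_channel_offset: float = 0.0
    delay_channel_sd: float = 1.0
    rise_time: float = 15.0
    noise_sd: float = 0.1
    basal_drift: float = 0.0  # a.u./min linear drift, for robustness testing
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = (
            self.frame_interval,
            self.responder_fraction,
            self.basal_mean,
            self.basal_sd,
            self.amplitude_mean,
            self.amplitude_cv,
            self.delay_shared_sd,
            self.delay_channel_offset,
            self.delay_channel_sd,
            self.rise_time,
            self.noise_sd,
            self.basal_drift,
        )
        if not all(np.isfinite(numeric)):
            raise ValueError("all cohort parameters must be finite")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in [0, 1]")
        for name in ("basal_sd", "amplitude_cv", "delay_shared_sd",
                     "delay_channel_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < self.stimulus_frame + 2:
            raise ValueError(
                "n_frames too small: no post-stimulus frames after the basal window"
            )
        if self.rise_time <= 0 or self.frame_interval <= 0:
            raise ValueError("rise_time and frame_interval must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def stimulus_time(self) -> float:
        """Time of the stimulus frame (stimulus applied just before it)."""
        return (self.stimulus_frame - 1) * self.frame_interval


@dataclass(frozen=True)
class PairedCell:
    """One simulated cell: paired Y/R traces plus its ground truth."""

    cell_id: str
    replicate: int
    responder: bool
    trace_y: Trace
    trace_r: Trace
    shared_delay: float
    amplitude: float


@dataclass(frozen=True)
class PairedTraceSet:
    """A simulated cohort with the configuration that produced it."""

    config: CohortConfig
    cells: tuple[PairedCell, ...]

    def traces(self, channel: str) -> list[Trace]:
        return [c.trace_y if channel == "Y" else c.trace_r for c in self.cells]

    def replicate_ids(self) -> list[int]:
        return sorted({c.replicate for c in self.cells})


def _ramp(t: np.ndarray, onset: float, rise_time: float) -> np.ndarray:
    """Saturating response shape: 0 before onset, 1 - exp(-x) after."""
    x = (t - onset) / rise_time
    return np.where(x > 0, 1.0 - np.exp(-np.clip(x, 0, None)), 0.0)


def simulate_cohort(config: CohortConfig) -> PairedTraceSet:
    """Draw a paired-channel cohort from the generative model.

    Per cell *c* and channel *ch*::

        trace(t) = basal_c + drift*t + R_c * A_c * f((t - tau_c_ch)/rho) + eps(t)

    with ``R_c ~ Bernoulli(p)``, ``A_c`` log-normal, ``tau_c_ch`` the
    stimulus time plus the shared cell delay plus the channel offset (red
    only) plus channel jitter, ``f(x) = max(0, 1 - exp(-x))`` and
    ``eps ~ N(0, noise_sd^2)`` i.i.d.  Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    times = config.times
    cells: list[PairedCell] = []
    # log-normal parameterised by mean and CV
    cv2 = config.amplitude_cv**2
    sigma_ln = float(np.sqrt(np.log1p(cv2)))
    mu_ln = float(np.log(config.amplitude_mean)) - 0.5 * sigma_ln**2

    for rep in range(1, config.n_replicates + 1):
        responders = rng.random(config.n_cells) < config.responder_fraction
        basals = rng.normal(config.basal_mean, config.basal_sd, config.n_cells)
        amplitudes = rng.lognormal(mu_ln, sigma_ln, config.n_cells)
        shared = rng.normal(0.0, config.delay_shared_sd, config.n_cells)
        jitter = rng.normal(0.0, config.delay_channel_sd, (config.n_cells, 2))
        noise = rng.normal(
            0.0, config.noise_sd, (config.n_cells, 2, config.n_frames)
        )
        for i in range(config.n_cells):
            cell_id = f"r{rep}c{i:04d}"
            values = {}
            for ch_idx, channel in enumerate(("Y", "R")):
                onset = (
                    config.stimulus_time
                    + shared[i]
                    + (config.delay_channel_offset if channel == "R" else 0.0)
                    + jitter[i, ch_idx]
                )
                signal = basals[i] + config.basal_drift * times
                if responders[i]:
                    signal = signal + amplitudes[i] * _ramp(
                        times, onset, config.rise_time
                    )
                values[channel] = signal + noise[i, ch_idx]
            cells.append(
                PairedCell(
                    cell_id=cell_id,
                    replicate=rep,
                    responder=bool(responders[i]),
                    trace_y=Trace(cell_id, "Y", times, values["Y"]),
                    trace_r=Trace(cell_id, "R", times, values["R"]),
                    shared_delay=float(shared[i]),
                    amplitude=float(amplitudes[i]),
                )
            )
    return PairedTraceSet(config=config, cells=tuple(cells))


# --------------------------------------------------------------------------
# Promoter synthesis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedElement:
    """One element to plant in a synthetic promoter.

    ``kind`` is ``"pre_dimer"`` (two hexamers with the given orientation
    and gap), ``"pre_site"`` (single hexamer), ``"polyA"`` (homopolymer
    tract) or ``"nucleosome"`` (annotation only, no sequence edit).
    ``offset`` is the (negative) start coordinate; for nucleosomes it is
    the dyad position.  ``variant`` overrides the hexamer of the *second*
    dimer member (or the single site), to plant PRE-like sites.
    """

    kind: str
    offset: int
    orientation: str = "TT"
    gap: int = 3
    length: int = 20
    base: str = "A"
    variant: str = CONSENSUS

    def footprint(self, seq_len: int) -> tuple[int, int] | None:
        """Occupied interval in 0-based sequence coordinates (None for nucleosomes)."""
        start = seq_len + self.offset
        if self.kind == "pre_dimer":
            return (start, start + 12 + self.gap)
        if self.kind == "pre_site":
            return (start, start + 6)
        if self.kind == "polyA":
            return (start, start + self.length)
        return None


@dataclass(frozen=True)
class PromoterSpec:
    """Recipe for a synthetic promoter with known ground truth."""

    length: int = 600
    gc_content: float = 0.40
    elements: tuple[PlantedElement, ...] = ()
    core_side: str = "3prime"

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError("promoter length must be >= 10")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        occupied: list[tuple[int, int]] = []
        for el in self.elements:
            fp = el.footprint(self.length)
            if fp is None:
                continue
            lo, hi = fp
            if lo < 0 or hi > self.length:
                raise ValueError(f"element {el} does not fit in the promoter")
            for plo, phi in occupied:
                if lo < phi and hi > plo:
                    raise ValueError(f"element {el} collides with another element")
            occupied.append((lo, hi))


def _dimer_hexamers(el: PlantedElement) -> tuple[str, str]:
    """The two hexamer strings (as written on the + sequence) of a dimer.

    Tail-to-tail means diverging motif arrows: minus-strand first, then
    plus-strand; head-to-head the opposite; head-to-tail both on the same
    strand (plus for toward-core with the core on the 3' side).
    """
    first, second = CONSENSUS, el.variant
    if el.orientation == "TT":
        return reverse_complement(first), second
    if el.orientation == "HH":
        return first, reverse_complement(second)
    if el.orientation == "HT_toward_core":
        return first, second
    if el.orientation == "HT_away_from_core":
        return reverse_complement(first), reverse_complement(second)
    raise ValueError(f"unknown orientation {el.orientation!r}")


def simulate_promoter(
    spec: PromoterSpec,
    seed: int,
    affinity: AffinityTable = AffinityTable(),
    max_attempts: int = 200,
) -> tuple[PromoterModel, list[dict]]:
    """Generate a promoter sequence with the spec's elements planted verbatim.

    Background bases are drawn from the GC composition; any window outside
    the planted elements that matches a PRE(-like) hexamer from the
    affinity table on either strand is redrawn (rejection sampling), and
    likewise accidental background poly-dA/dT runs of 20+ bp.  Returns the
    promoter model (with nucleosome annotation) and the ground-truth
    annotation records.
    """
    rng = np.random.default_rng(seed)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    forbidden = {h for h in affinity.weights}
    forbidden |= {reverse_complement(h) for h in affinity.weights}

    # Only the hexamers and tracts themselves are fixed text; dimer gap
    # bases are redrawn with the background so rejection covers them too.
    planted: list[tuple[int, str]] = []  # (start, fixed text)
    motif_starts: set[int] = set()
    annotation: list[dict] = []
    dyads: list[int] = []
    polyA_runs: list[tuple[int, int]] = []
    for el in spec.elements:
        if el.kind == "nucleosome":
            dyads.append(el.offset)
            annotation.append({"kind": "nucleosome", "offset": el.offset})
            continue
        lo, _hi = el.footprint(spec.length)  # type: ignore[misc]
        if el.kind == "pre_dimer":
            h1, h2 = _dimer_hexamers(el)
            planted.append((lo, h1))
            planted.append((lo + 6 + el.gap, h2))
            motif_starts.update((lo, lo + 6 + el.gap))
            annotation.append(
                {
                    "kind": "pre_dimer",
                    "offset": el.offset,
                    "orientation": el.orientation,
                    "gap": el.gap,
                    "variant": el.variant,
                }
            )
        elif el.kind == "pre_site":
            planted.append((lo, el.variant))
            motif_starts.add(lo)
            annotation.append(
                {"kind": "pre_site", "offset": el.offset, "variant": el.variant}
            )
        elif el.kind == "polyA":
            planted.append((lo, el.base * el.length))
            polyA_runs.append((lo, lo + el.length))
            annotation.append(
                {
                    "kind": "polyA",
                    "offset": el.offset,
                    "length": el.length,
                    "base": el.base,
                }
            )
        else:
            raise ValueError(f"unknown element kind {el.kind!r}")

    for _ in range(max_attempts):
        seq = rng.choice(bases, size=spec.length, p=probs)
        for lo, text in planted:
            seq[lo : lo + len(text)] = list(text)
        text = "".join(seq)
        if _clean_background(text, motif_starts, polyA_runs, forbidden):
            model = PromoterModel(
                sequence=text,
                core_side=spec.core_side,
                nucleosome_dyads=tuple(dyads),
            )
            return model, annotation
    raise RuntimeError(
        "could not draw a clean background; loosen the spec or raise max_attempts"
    )


def _clean_background(
    seq: str,
    motif_starts: set[int],
    polyA_runs: list[tuple[int, int]],
    forbidden: set[str],
) -> bool:
    """True when every PRE(-like) window and every 20+ bp A/T run was planted."""
    L = len(seq)
    for i in range(L - 5):
        if i in motif_starts:
            continue
        window = seq[i : i + 6]
        if window in forbidden or reverse_complement(window) in forbidden:
            return False
    i = 0
    while i < L:
        j = i
        while j < L and seq[j] == seq[i]:
            j += 1
        if seq[i] in "AT" and j - i >= 20 and (i, j) not in polyA_runs:
            return False
        i = j
    return True
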