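"""PRE-dimer promoter grammar.

The yeast mating transcription factor Ste12 binds DNA as a homodimer on
pairs of Pheromone Response Elements (PREs, consensus ``TGAAAC``).  Whether
a pair of sites supports induction depends on the *conformation* of the
dimer — the relative orientation of the two motifs and the spacing between
them — and on the chromatin context of the promoter.

This module scans promoter sequences for PRE and PRE-like sites on both
strands, calls every candidate dimer within a spacing window, classifies
its conformation against the functional grammar (tail-to-tail dimers work
at 3 bp spacing, the other orientations at 5 bp, with one or two extra DNA
helix turns of ~10.5 bp also tolerated), annotates nucleosome coverage and
poly-dA/dT context, and turns the annotations into a qualitative induction
prediction (level, speed, stochasticity).

Coordinate convention: motif offsets are negative, counted from the 3' end
of the supplied sequence (the end abutting the core promoter in the usual
layout), so an offset of -223 means the motif starts 223 bp upstream of the
sequence end.  Any cloning offset between the sequence end and the actual
start codon is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AffinityTable",
    "GrammarConfig",
    "MotifMatch",
    "DimerCall",
    "PolyATract",
    "PromoterModel",
    "InductionPrediction",
    "CONSENSUS",
    "HELICAL_REPEAT_BP",
    "reverse_complement",
    "scan_pre_sites",
    "call_dimers",
    "classify_conformation",
    "find_polyA_tracts",
    "annotate_chromatin",
    "predict_induction",
]

#: Ste12 consensus binding motif (PRE).
CONSENSUS = "TGAAAC"

#: DNA helical repeat, bp per turn — the rationale for the 10/20 bp spacing
#: increments of the grammar (one or two helix turns restore the relative
#: rotational phasing of the two bound monomers).
HELICAL_REPEAT_BP = 10.5

#: Canonical nucleosome footprint half-width (147 bp total).
NUCLEOSOME_HALF_WIDTH = 73

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# Motif scanning
# --------------------------------------------------------------------------

#: Default relative-affinity table for single-mismatch PRE variants, on a
#: 0-1 scale with the consensus at 1.  TAAAAC costs only ~20 % of binding;
#: TGAGAC and TCAAAC nearly abolish it.  Unlisted variants are excluded
#: (weight 0) unless the user extends the table — PRE-like sites are hard
#: to identify from sequence alone.
DEFAULT_AFFINITIES: Mapping[str, float] = {
    CONSENSUS: 1.0,
    "TAAAAC": 0.80,
    "TGAGAC": 0.05,
    "TCAAAC": 0.05,
}


@dataclass(frozen=True)
class AffinityTable:
    """Hexamer variant -> relative binding weight in [0, 1]."""

    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AFFINITIES)
    )

    def __post_init__(self) -> None:
        for hexamer, w in self.weights.items():
            if len(hexamer) != 6 or set(hexamer) - set("ACGT"):
                raise ValueError(f"invalid hexamer {hexamer!r}")
            if not 0 <= w <= 1:
                raise ValueError(f"weight for {hexamer} outside [0, 1]")
        if self.weights.get(CONSENSUS, 1.0) != 1.0:
            raise ValueError("consensus weight must be 1")

    def weight(self, hexamer: str) -> float:
        return self.weights.get(hexamer.upper(), 0.0)


@dataclass(frozen=True)
class MotifMatch:
    """One PRE(-like) site.

    ``offset`` is the (negative) start coordinate of the hexamer relative
    to the sequence 3' end; ``strand`` "+" means the motif reads 5'->3' on
    the given sequence, "-" on its reverse complement.
    """

    offset: int
    strand: str
    hexamer: str
    weight: float

    @property
    def end(self) -> int:
        """Coordinate one past the last base of the hexamer."""
        return self.offset + 6


def scan_pre_sites(
    seq: str,
    affinity: AffinityTable = AffinityTable(),
    min_weight: float = 0.0,
) -> list[MotifMatch]:
    """All PRE(-like) occurrences on both strands, sorted by offset.

    A plus-strand hit at position *i* is a window equal to a table hexamer;
    a minus-strand hit is a window whose reverse complement is in the table
    (so ``GTTTCA`` is the minus-strand consensus).  Hits below
    ``min_weight`` are dropped.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over the alphabet {A,C,G,T,N}")
    L = len(seq)
    matches: list[MotifMatch] = []
    for i in range(L - 5):
        window = seq[i : i + 6]
        w_plus = affinity.weight(window)
        if w_plus >= min_weight and w_plus > 0:
            matches.append(MotifMatch(i - L, "+", window, w_plus))
        rc = reverse_complement(window)
        w_minus = affinity.weight(rc)
        if w_minus >= min_weight and w_minus > 0:
            matches.append(MotifMatch(i - L, "-", rc, w_minus))
    matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


# --------------------------------------------------------------------------
# Dimer calling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DimerCall:
    """A pair of PRE sites within the spacing window.

    ``gap`` counts the bases strictly between the two hexamers.
    ``orientation`` is derived from the two strands and the core-promoter
    side, drawing each motif as an arrow in its 5'->3' direction with the
    head at the arrowhead (3' end): diverging arrows are tail-to-tail
    (``TT``), converging head-to-head (``HH``), parallel head-to-tail with
    the sub-type given by whether the arrows point toward or away from the
    core promoter.
    """

    first: MotifMatch
    second: MotifMatch
    gap: int
    orientation: str

    @property
    def span(self) -> tuple[int, int]:
        """(start, one-past-end) of the dimer in promoter coordinates."""
        return (self.first.offset, self.second.end)

    @property
    def min_weight(self) -> float:
        return min(self.first.weight, self.second.weight)


def _orientation(
    left: MotifMatch, right: MotifMatch, core_side: str, invert_head: bool
) -> str:
    # Arrow of a "+" match points 3'-ward (right); "-" points left.
    lp, rp = left.strand == "+", right.strand == "+"
    if invert_head:
        lp, rp = not lp, not rp
    if not lp and rp:
        return "TT"  # diverging
    if lp and not rp:
        return "HH"  # converging
    toward_core = lp if core_side == "3prime" else not lp
    return "HT_toward_core" if toward_core else "HT_away_from_core"


def call_dimers(
    matches: Sequence[MotifMatch],
    max_gap: int = 40,
    core_side: str = "3prime",
    invert_head: bool = False,
) -> list[DimerCall]:
    """Every pair of sites with 0 <= gap <= ``max_gap``, all pairs reported.

    Overlapping candidate dimers are not resolved — endogenous promoters
    carry clusters of overlapping sites and every geometric pairing is a
    potential Ste12 dimer.  ``invert_head`` swaps the head/tail convention
    (exchanging TT and HH labels) to match either literature usage.
    """
    if core_side not in ("3prime", "5prime"):
        raise ValueError("core_side must be '3prime' or '5prime'")
    ordered = sorted(matches, key=lambda m: m.offset)
    calls: list[DimerCall] = []
    for i, left in enumerate(ordered):
        for right in ordered[i + 1 :]:
            gap = right.offset - left.end
            if gap < 0:
                continue  # overlapping hexamers are not a dimer
            if gap > max_gap:
                break
            calls.append(
                DimerCall(
                    first=left,
                    second=right,
                    gap=gap,
                    orientation=_orientation(left, right, core_side, invert_head),
                )
            )
    return calls


# --------------------------------------------------------------------------
# Conformation grammar
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GrammarConfig:
    """Functional spacing rule for PRE dimers.

    Tail-to-tail dimers are functional at ``tt_base_gap`` (3 bp) plus up to
    ``n_increments`` extra increments of ``increment_bp`` (10 bp, one DNA
    helix turn rounded from ``HELICAL_REPEAT_BP``); the other orientations
    at ``other_base_gap`` (5 bp) plus up to ``n_increments_other``
    increments.  The rule is an exact spacing set rather than helical
    arithmetic; ``gap_tolerance`` optionally accepts +-N bp around each
    functional spacing.
    """

    tt_base_gap: int = 3
    other_base_gap: int = 5
    increment_bp: int = 10
    n_increments_tt: int = 2
    n_increments_other: int = 1
    gap_tolerance: int = 0

    def functional_gaps(self, orientation: str) -> tuple[int, ...]:
        if orientation == "TT":
            base, n = self.tt_base_gap, self.n_increments_tt
        else:
            base, n = self.other_base_gap, self.n_increments_other
        return tuple(base + k * self.increment_bp for k in range(n + 1))


@dataclass(frozen=True)
class ConformationCall:
    functional: bool
    output_class: str  # high-fast | reduced | low-slow | non-functional


def classify_conformation(
    dimer: DimerCall, config: GrammarConfig = GrammarConfig()
) -> ConformationCall:
    """Functional flag and qualitative output class of a dimer conformation.

    Depends only on (orientation, gap).  At the default grammar: TT gaps
    {3, 13, 23} are functional with 23 giving low and slow expression;
    HH and both HT sub-types are functional at {5, 15} with 15 reduced;
    everything else is non-functional.
    """
    gaps = config.functional_gaps(dimer.orientation)
    tol = config.gap_tolerance
    matched = next(
        (g for g in gaps if abs(dimer.gap - g) <= tol), None
    )
    if matched is None:
        return ConformationCall(functional=False, output_class="non-functional")
    if dimer.orientation == "TT":
        if matched == gaps[-1] and len(gaps) >= 3:
            return ConformationCall(functional=True, output_class="low-slow")
        return ConformationCall(functional=True, output_class="high-fast")
    if matched != gaps[0]:
        return ConformationCall(functional=True, output_class="reduced")
    return ConformationCall(functional=True, output_class="high-fast")


# --------------------------------------------------------------------------
# Chromatin context
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PolyATract:
    """Maximal homopolymeric dA or dT run (nucleosome-disfavouring)."""

    offset: int
    length: int
    base: str

    @property
    def end(self) -> int:
        return self.offset + self.length


def find_polyA_tracts(seq: str, min_len: int = 20) -> list[PolyATract]:
    """Maximal runs of A or of T with length >= ``min_len``.

    Pure-base runs only: an ``AAAA...TTTT`` stretch is two tracts, one per
    base.  Offsets follow the promoter convention (negative from the 3'
    end).
    """
    seq = seq.upper()
    L = len(seq)
    tracts: list[PolyATract] = []
    i = 0
    while i < L:
        base = seq[i]
        j = i
        while j < L and seq[j] == base:
            j += 1
        if base in "AT" and j - i >= min_len:
            tracts.append(PolyATract(offset=i - L, length=j - i, base=base))
        i = j
    return tracts


def tract_dimer_distance(tract: PolyATract, dimer: DimerCall) -> int:
    """Bases strictly between a poly-dA/dT tract and a dimer span (0 if adjacent/overlapping)."""
    d_start, d_end = dimer.span
    if tract.end <= d_start:
        return d_start - tract.end
    if d_end <= tract.offset:
        return tract.offset - d_end
    return 0


@dataclass(frozen=True)
class PromoterModel:
    """A promoter sequence with its chromatin annotation.

    ``nucleosome_dyads`` are dyad positions in promoter coordinates; each
    nucleosome protects ``dyad +- half_width`` (147 bp by default).
    """

    sequence: str
    core_side: str = "3prime"
    nucleosome_dyads: tuple[int, ...] = ()
    half_width: int = NUCLEOSOME_HALF_WIDTH

    def footprints(self) -> list[tuple[int, int]]:
        return [(d - self.half_width, d + self.half_width) for d in self.nucleosome_dyads]

    def polyA_tracts(self, min_len: int = 20) -> list[PolyATract]:
        return find_polyA_tracts(self.sequence, min_len=min_len)


def annotate_chromatin(
    dimer: DimerCall,
    model: PromoterModel,
    boundary_margin: int = 30,
) -> str:
    """Nucleosome context of a dimer: ``"covered"``, ``"boundary"`` or ``"NDR"``.

    Covered when the dimer span reaches into a footprint's interior (more
    than ``boundary_margin`` bp from both edges); boundary when it touches
    a footprint only within the margin of an edge; NDR otherwise (always,
    when no nucleosomes are annotated).
    """
    d_start, d_end = dimer.span
    touched = False
    for lo, hi in model.footprints():
        inner_lo, inner_hi = lo + boundary_margin, hi - boundary_margin
        if d_start < inner_hi and d_end > inner_lo:
            return "covered"
        if d_start < hi and d_end > lo:
            touched = True
    return "boundary" if touched else "NDR"


# --------------------------------------------------------------------------
# Induction prediction
# --------------------------------------------------------------------------

_LEVELS = ["high", "reduced", "low"]


@dataclass(frozen=True)
class InductionPrediction:
    """Qualitative prediction for one dimer in its promoter context.

    ``induced`` is False for non-functional conformations (level and speed
    are then ``None``).  ``stochastic`` marks nucleosome-occluded dimers
    where only a fraction of cells manage to evict the histones and fire.
    """

    induced: bool
    level: str | None
    speed: str | None
    stochastic: bool
    context: str
    note: str = ""


def _downgrade(level: str, steps: int) -> str:
    idx = min(_LEVELS.index(level) + steps, len(_LEVELS) - 1)
    return _LEVELS[idx]


def predict_induction(
    dimer: DimerCall,
    model: PromoterModel,
    distance_to_core: int | None = None,
    grammar: GrammarConfig = GrammarConfig(),
    boundary_margin: int = 30,
    polyA_max_distance: int = 6,
    polyA_min_len: int = 20,
    cluster_min_sites: int = 3,
    n_sites_nearby: int = 2,
    far_threshold: int = 350,
) -> InductionPrediction:
    """Rule cascade combining conformation, chromatin and position.

    Order of the rules:

    1. a non-functional conformation gives no induction at all;
    2. a nucleosome-covered dimer fires slowly, at low level and only in a
       fraction of cells (stochastic) — unless a poly-dA/dT tract of at
       least ``polyA_min_len`` bp lies within ``polyA_max_distance`` bp of
       the dimer or at least ``cluster_min_sites`` PRE sites cluster on the
       promoter, which favours nucleosome eviction and restores a
       boundary-like (slow but non-stochastic) behaviour;
    3. a boundary dimer is slow but keeps its expression level;
    4. an NDR dimer is fast;
    5. the level is then downgraded one step for each of: a PRE-like member
       (weight < 1), the large-gap conformation variant, and a dimer more
       than ``far_threshold`` bp from the core promoter.
    """
    conformation = classify_conformation(dimer, grammar)
    context = annotate_chromatin(dimer, model, boundary_margin)
    if not conformation.functional:
        return InductionPrediction(
            induced=False,
            level=None,
            speed=None,
            stochastic=False,
            context=context,
            note="non-functional conformation",
        )

    notes: list[str] = []
    stochastic = False
    if context == "covered":
        tracts = model.polyA_tracts(min_len=polyA_min_len)
        near_tract = any(
            tract_dimer_distance(t, dimer) <= polyA_max_distance for t in tracts
        )
        clustered = n_sites_nearby >= cluster_min_sites
        if near_tract or clustered:
            context_effect = "boundary"
            notes.append(
                "nucleosome occlusion mitigated by poly-dA/dT tract"
                if near_tract
                else "nucleosome occlusion mitigated by PRE cluster"
            )
        else:
            context_effect = "covered"
    else:
        context_effect = context

    if context_effect == "covered":
        level, speed, stochastic = "low", "slow", True
        notes.append("nucleosome-occluded: stochastic activation")
    else:
        speed = "slow" if context_effect == "boundary" else "fast"
        level = "high"
        steps = 0
        if dimer.min_weight < 1.0:
            steps += 1
            notes.append("PRE-like member lowers level")
        if conformation.output_class in ("reduced", "low-slow"):
            steps += 1
            notes.append("large-gap conformation lowers level")
        if distance_to_core is not None and distance_to_core > far_threshold:
            steps += 1
            notes.append("far from core promoter")
        level = _downgrade(level, steps)

    return InductionPrediction(
        induced=True,
        level=level,
        speed=speed,
        stochastic=stochastic,
        context=context,
        note="; ".join(notes),
    )


def scan_promoter(
    model: PromoterModel,
    affinity: AffinityTable = AffinityTable(),
    min_weight: float = 0.0,
    max_gap: int = 40,
    grammar: GrammarConfig = GrammarConfig(),
) -> list[dict]:
    """Full grammar pass over one promoter: sites -> dimers -> predictions.

    Returns one record per called dimer with its conformation class,
    chromatin context and induction prediction; convenience driver used by
    the pipeline and the command line.
    """
    matches = scan_pre_sites(model.sequence, affinity, min_weight)
    dimers = call_dimers(matches, max_gap=max_gap, core_side=model.core_side)
    n_sites = len({(m.offset, m.strand) for m in matches})
    records = []
    for dimer in dimers:
        conformation = classify_conformation(dimer, grammar)
        distance = -dimer.span[1] if model.core_side == "3prime" else (
            len(model.sequence) + dimer.span[0]
        )
        prediction = predict_induction(
            dimer,
            model,
            distance_to_core=distance,
            grammar=grammar,
            n_sites_nearby=n_sites,
        )
        records.append(
            {
                "offset": dimer.first.offset,
                "orientation": dimer.orientation,
                "gap": dimer.gap,
                "hexamers": f"{dimer.first.hexamer}/{dimer.second.hexamer}",
                "min_weight": dimer.min_weight,
                "functional": conformation.functional,
                "output_class": conformation.output_class,
                "context": prediction.context,
                "distance_to_core": distance,
                "induced": prediction.induced,
                "level": prediction.level,
                "speed": prediction.speed,
                "stochastic": prediction.stochastic,
                "note": prediction.note,
            }
        )
    return records
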