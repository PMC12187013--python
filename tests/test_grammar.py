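"""PRE scanning, dimer calling, conformation grammar and chromatin rules."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from predimer import (
    CONSENSUS,
    HELICAL_REPEAT_BP,
    AffinityTable,
    DimerCall,
    GrammarConfig,
    MotifMatch,
    PromoterModel,
    annotate_chromatin,
    call_dimers,
    classify_conformation,
    find_polyA_tracts,
    predict_induction,
    scan_pre_sites,
)
from predimer.grammar import reverse_complement

GTTTCA = reverse_complement(CONSENSUS)


def embed(core: str, left: int = 60, right: int = 60) -> str:
    """Pad a motif arrangement with inert C/G background."""
    return "C" * left + core + "G" * right


def dimer_of(seq: str, **kw) -> DimerCall:
    calls = call_dimers(scan_pre_sites(seq), **kw)
    assert len(calls) == 1
    return calls[0]


class TestScan:
    def test_consensus_plus_strand(self):
        (m,) = scan_pre_sites(CONSENSUS)
        assert (m.strand, m.weight, m.offset) == ("+", 1.0, -6)

    def test_consensus_minus_strand(self):
        (m,) = scan_pre_sites(GTTTCA)
        assert (m.strand, m.weight, m.hexamer) == ("-", 1.0, CONSENSUS)

    def test_pre_like_variant_weight(self):
        (m,) = scan_pre_sites("TAAAAC", min_weight=0.5)
        assert m.weight == pytest.approx(0.8)

    def test_low_affinity_variants(self):
        for variant in ("TGAGAC", "TCAAAC"):
            (m,) = scan_pre_sites(variant)
            assert m.weight == pytest.approx(0.05)
        assert scan_pre_sites("TGAGAC", min_weight=0.5) == []

    def test_unlisted_mismatch_excluded(self):
        assert scan_pre_sites("TGAAAA") == []

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            scan_pre_sites("TGAAAX")

    def test_offsets_count_from_three_prime_end(self):
        seq = embed(CONSENSUS, left=100, right=94)
        (m,) = scan_pre_sites(seq)
        assert m.offset == -(94 + 6)


class TestCallDimers:
    def test_tail_to_tail(self):
        d = dimer_of(embed(GTTTCA + "CAC" + CONSENSUS))
        assert (d.orientation, d.gap) == ("TT", 3)

    def test_head_to_head(self):
        d = dimer_of(embed(CONSENSUS + "CACAC" + GTTTCA))
        assert (d.orientation, d.gap) == ("HH", 5)

    def test_head_to_tail_toward_core(self):
        d = dimer_of(embed(CONSENSUS + "CACAC" + CONSENSUS), core_side="3prime")
        assert (d.orientation, d.gap) == ("HT_toward_core", 5)

    def test_head_to_tail_away_from_core(self):
        d = dimer_of(embed(GTTTCA + "CACAC" + GTTTCA), core_side="3prime")
        assert d.orientation == "HT_away_from_core"

    def test_core_side_flips_ht_subtype(self):
        seq = embed(CONSENSUS + "CACAC" + CONSENSUS)
        assert dimer_of(seq, core_side="3prime").orientation == "HT_toward_core"
        assert dimer_of(seq, core_side="5prime").orientation == "HT_away_from_core"

    def test_invert_head_swaps_tt_and_hh(self):
        tt = embed(GTTTCA + "CAC" + CONSENSUS)
        assert dimer_of(tt, invert_head=True).orientation == "HH"

    def test_max_gap_enforced(self):
        seq = embed(GTTTCA + "CA" * 25 + CONSENSUS)
        assert call_dimers(scan_pre_sites(seq), max_gap=40) == []
        assert len(call_dimers(scan_pre_sites(seq), max_gap=50)) == 1

    def test_equals_brute_force_enumeration(self):
        """All pairs with 0 <= gap <= max_gap, nothing more, nothing less."""
        seq = embed(
            CONSENSUS + "CAC" + GTTTCA + "CC" + CONSENSUS + "C" * 35 + GTTTCA,
            left=20,
            right=20,
        )
        matches = scan_pre_sites(seq)
        called = {
            (d.first.offset, d.second.offset) for d in call_dimers(matches)
        }
        brute = {
            (a.offset, b.offset)
            for a, b in itertools.combinations(
                sorted(matches, key=lambda m: m.offset), 2
            )
            if 0 <= b.offset - (a.offset + 6) <= 40
        }
        assert called == brute

    def test_strand_symmetry(self):
        """Scanning the reverse complement with the core side flipped yields
        the same dimer set: TT and HH are preserved and the HT sub-type is
        unchanged relative to the core; keeping the core-side label fixed
        instead swaps the HT sub-types."""
        seq = embed(CONSENSUS + "CACAC" + CONSENSUS, left=30, right=50)
        rc = reverse_complement(seq)
        fwd = dimer_of(seq, core_side="3prime")
        flipped = dimer_of(rc, core_side="5prime")
        kept = dimer_of(rc, core_side="3prime")
        assert flipped.orientation == fwd.orientation
        assert kept.orientation == "HT_away_from_core"
        tt = embed(GTTTCA + "CAC" + CONSENSUS)
        assert dimer_of(reverse_complement(tt), core_side="5prime").orientation == "TT"


class TestConformationGrammar:
    @pytest.mark.parametrize(
        "gap,functional,cls",
        [
            (3, True, "high-fast"),
            (5, False, "non-functional"),
            (7, False, "non-functional"),
            (10, False, "non-functional"),
            (13, True, "high-fast"),
            (23, True, "low-slow"),
            (40, False, "non-functional"),
        ],
    )
    def test_tail_to_tail_gaps(self, gap, functional, cls):
        d = dimer_of(embed(GTTTCA + "C" * gap + CONSENSUS))
        call = classify_conformation(d)
        assert call.functional is functional
        assert call.output_class == cls

    @pytest.mark.parametrize("orientation_seq", [
        CONSENSUS + "{gap}" + CONSENSUS,       # head-to-tail
        CONSENSUS + "{gap}" + GTTTCA,          # head-to-head
    ])
    @pytest.mark.parametrize(
        "gap,functional,cls",
        [
            (3, False, "non-functional"),
            (5, True, "high-fast"),
            (15, True, "reduced"),
            (25, False, "non-functional"),
        ],
    )
    def test_other_orientations(self, orientation_seq, gap, functional, cls):
        seq = embed(orientation_seq.format(gap="C" * gap))
        call = classify_conformation(dimer_of(seq))
        assert call.functional is functional
        assert call.output_class == cls

    def test_translation_invariance(self):
        """Classification depends only on (orientation, gap), not position."""
        for left in (10, 100, 300):
            d = dimer_of(embed(GTTTCA + "C" * 13 + CONSENSUS, left=left))
            assert classify_conformation(d).functional

    def test_helical_repeat_constant(self):
        assert HELICAL_REPEAT_BP == 10.5

    def test_gap_tolerance_flag(self):
        d = dimer_of(embed(GTTTCA + "C" * 12 + CONSENSUS))
        assert not classify_conformation(d).functional
        assert classify_conformation(d, GrammarConfig(gap_tolerance=1)).functional


class TestPolyATracts:
    def test_twenty_bp_tract_found(self):
        (t,) = find_polyA_tracts(embed("A" * 20))
        assert t.length == 20 and t.base == "A"

    def test_nineteen_bp_not_reported(self):
        assert find_polyA_tracts(embed("A" * 19)) == []

    def test_mixed_run_splits_by_base(self):
        """An AA...TT stretch is two pure-base tracts; checked against a
        brute-force run-length scan."""
        seq = embed("A" * 22 + "T" * 25)
        tracts = find_polyA_tracts(seq)
        # oracle: enumerate maximal pure runs directly
        runs = []
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if seq[i] in "AT" and j - i >= 20:
                runs.append((i - len(seq), j - i, seq[i]))
            i = j
        assert [(t.offset, t.length, t.base) for t in tracts] == runs
        assert len(tracts) == 2


AGA1_DYADS = (-100, -349, -516)


def place_dimer(offset: int, length: int = 600) -> DimerCall:
    """A TT-3 consensus dimer whose span starts at ``offset``."""
    left = length + offset
    seq = "C" * left + GTTTCA + "CAC" + CONSENSUS + "G" * (length - left - 15)
    return dimer_of(seq)


class TestChromatin:
    def test_dimer_under_nucleosome_is_covered(self):
        model = PromoterModel("C" * 600, nucleosome_dyads=AGA1_DYADS)
        assert annotate_chromatin(place_dimer(-330), model) == "covered"

    def test_dimer_between_nucleosomes_is_ndr(self):
        model = PromoterModel("C" * 600, nucleosome_dyads=AGA1_DYADS)
        assert annotate_chromatin(place_dimer(-223), model) == "NDR"

    def test_no_nucleosomes_means_ndr(self):
        model = PromoterModel("C" * 600)
        assert annotate_chromatin(place_dimer(-330), model) == "NDR"

    def test_footprint_edge_is_boundary(self):
        # footprint of dyad -349 spans -422..-276; a dimer ending just
        # inside the upstream edge only grazes the 30 bp margin
        model = PromoterModel("C" * 600, nucleosome_dyads=(-349,))
        assert annotate_chromatin(place_dimer(-420), model) == "boundary"


class TestPredictInduction:
    def test_reference_configuration_high_fast(self):
        model = PromoterModel("C" * 600, nucleosome_dyads=AGA1_DYADS)
        pred = predict_induction(place_dimer(-223), model, distance_to_core=208)
        assert (pred.level, pred.speed) == ("high", "fast")
        assert pred.induced and not pred.stochastic

    def test_pre_like_member_reduces_level(self):
        seq = embed(GTTTCA + "CAC" + "TCAAAC")
        d = dimer_of(seq)
        model = PromoterModel(seq)
        pred = predict_induction(d, model, distance_to_core=60)
        assert (pred.level, pred.speed) == ("reduced", "fast")

    def test_covered_dimer_low_slow_stochastic(self):
        model = PromoterModel("C" * 600, nucleosome_dyads=AGA1_DYADS)
        pred = predict_induction(place_dimer(-330), model, distance_to_core=315)
        assert (pred.level, pred.speed, pred.stochastic) == ("low", "slow", True)

    def test_polyA_tract_mitigates_occlusion(self):
        # 20 bp poly-dA 6 bp away from the covered dimer restores
        # non-stochastic (boundary-like) behaviour
        offset, length = -330, 600
        left = length + offset
        seq = (
            "C" * (left - 26)
            + "A" * 20
            + "C" * 6
            + GTTTCA + "CAC" + CONSENSUS
            + "G" * (length - left - 15)
        )
        d = dimer_of(seq)
        model = PromoterModel(seq, nucleosome_dyads=AGA1_DYADS)
        assert annotate_chromatin(d, model) == "covered"
        pred = predict_induction(d, model, distance_to_core=315)
        assert pred.stochastic is False
        assert pred.speed == "slow" and pred.level == "high"

    def test_pre_cluster_mitigates_occlusion(self):
        model = PromoterModel("C" * 600, nucleosome_dyads=AGA1_DYADS)
        pred = predict_induction(
            place_dimer(-330), model, distance_to_core=315, n_sites_nearby=3
        )
        assert pred.stochastic is False

    def test_far_from_core_downgrades_level(self):
        model = PromoterModel("C" * 600)
        pred = predict_induction(place_dimer(-420), model, distance_to_core=405)
        assert (pred.level, pred.speed) == ("reduced", "fast")

    def test_non_functional_conformation_no_induction(self):
        d = dimer_of(embed(GTTTCA + "C" * 10 + CONSENSUS))
        pred = predict_induction(d, PromoterModel("C" * 600))
        assert not pred.induced and pred.level is None


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    gap=st.integers(min_value=0, max_value=40),
    orientation=st.sampled_from(["TT", "HH", "HT"]),
)
def test_grammar_matches_exact_spacing_sets(gap, orientation):
    """The functional spacings are exactly {3,13,23} for TT and {5,15} for
    the other orientations, independent of position."""
    core = {
        "TT": GTTTCA + "C" * gap + CONSENSUS,
        "HH": CONSENSUS + "C" * gap + GTTTCA,
        "HT": CONSENSUS + "C" * gap + CONSENSUS,
    }[orientation]
    calls = call_dimers(scan_pre_sites(embed(core)))
    d = next(c for c in calls if c.gap == gap)
    expected = gap in ({3, 13, 23} if orientation == "TT" else {5, 15})
    assert classify_conformation(d).functional == expected
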