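"""Splice distance convention, window scanning and ESR gain/loss calls.

The brute-force oracle for window scanning rebuilds the full reference
and alternate sequences and diffs the positioned motif occurrences that
overlap the mutated base — independent of the windowed implementation.
"""

import pytest
from hypothesis import given, settings, strategies as st

from synreg.model import MotifSet
from synreg.splice import (
    SpliceAnnotation,
    annotate_splice,
    classify_esr_change,
    distance_to_nearest_splice_site,
    scan_windows,
)

from conftest import make_mutation, make_transcript


def occurrence_diff_oracle(context, centre, ref, alt, motifs, k):
    """Positioned occurrences of any motif overlapping the centre, diffed
    between alleles: (gained starts, lost starts)."""
    alt_context = context[:centre] + alt + context[centre + 1 :]

    def hits(seq):
        out = set()
        for start in range(len(seq) - k + 1):
            if start <= centre <= start + k - 1 and seq[start : start + k] in motifs:
                out.add(start)
        return out

    ref_hits, alt_hits = hits(context), hits(alt_context)
    return alt_hits - ref_hits, ref_hits - alt_hits


class TestDistance:
    def two_exon(self):
        return make_transcript(
            [(100, 200), (300, 400)], "A" * 198, cds_interval=(100, 398)
        )

    def test_interior_position(self):
        t = self.two_exon()
        m = make_mutation(context="AAAAAAAAAAA", ref="A", alt="G", pos=196)
        assert distance_to_nearest_splice_site(m, t) == 5

    def test_last_base_of_exon_has_distance_one(self):
        t = self.two_exon()
        m = make_mutation(context="AAAAAAAAAAA", ref="A", alt="G", pos=200)
        assert distance_to_nearest_splice_site(m, t) == 1
        m2 = make_mutation(context="AAAAAAAAAAA", ref="A", alt="G", pos=301)
        assert distance_to_nearest_splice_site(m2, t) == 1

    def test_transcript_termini_are_not_splice_sites(self):
        t = self.two_exon()
        m = make_mutation(context="AAAAAAAAAAA", ref="A", alt="G", pos=101)
        # distance to the donor at 200, not to the transcript start at 100
        assert distance_to_nearest_splice_site(m, t) == 100

    def test_single_exon_has_no_distance(self):
        t = make_transcript([(100, 400)], "A" * 300)
        m = make_mutation(context="AAAAAAAAAAA", ref="A", alt="G", pos=250)
        assert distance_to_nearest_splice_site(m, t) is None

    def test_intronic_position_is_an_error(self):
        t = self.two_exon()
        m = make_mutation(context="AAAAAAAAAAA", ref="A", alt="G", pos=250)
        with pytest.raises(ValueError, match="not exonic"):
            distance_to_nearest_splice_site(m, t)


class TestScanWindows:
    def test_hand_enumerated_hexamer_windows(self):
        ref_w, alt_w, offsets = scan_windows("GAAGATAAGAA", 5, "T", "A", k=6)
        assert ref_w == ["GAAGAT", "AAGATA", "AGATAA", "GATAAG", "ATAAGA", "TAAGAA"]
        assert alt_w == ["GAAGAA", "AAGAAA", "AGAAAA", "GAAAAG", "AAAAGA", "AAAGAA"]
        assert offsets == [-5, -4, -3, -2, -1, 0]

    def test_truncation_near_context_edge(self):
        # centre 2 bases from the left edge: only windows fully inside remain
        ref_w, alt_w, offsets = scan_windows("GATAAGAA", 2, "T", "A", k=6)
        assert offsets == [-2, -1, 0]
        assert all(len(w) == 6 for w in ref_w + alt_w)

    def test_every_window_contains_the_centre(self):
        ref_w, _, offsets = scan_windows("GAAGATAAGAA", 5, "T", "A", k=7)
        assert len(ref_w) == 5  # truncated: context too short for all 7
        for off in offsets:
            assert off <= 0 <= off + 6

    def test_non_acgt_windows_omitted(self):
        ref_w, _, offsets = scan_windows("NNNNNTAAGAA", 5, "T", "A", k=6)
        assert offsets == [0]
        ref_w2, _, off2 = scan_windows("NNNNNTNNNNN", 5, "T", "A", k=6)
        assert ref_w2 == [] and off2 == []


class TestEsrClassification:
    def test_ese_gain_from_hand_example(self):
        ref_w, alt_w, offs = scan_windows("GAAGATAAGAA", 5, "T", "A", k=6)
        ev = classify_esr_change(ref_w, alt_w, MotifSet("ESE", frozenset({"GAAGAA"})),
                                 MotifSet("ESS", frozenset()), offs)
        assert ev.events == frozenset({"ESE_GAIN"})

    def test_ess_loss_from_hand_example(self):
        ref_w, alt_w, offs = scan_windows("GAAGATAAGAA", 5, "T", "A", k=6)
        ev = classify_esr_change(ref_w, alt_w, MotifSet("ESE", frozenset()),
                                 MotifSet("ESS", frozenset({"TAAGAA"})), offs)
        assert ev.events == frozenset({"ESS_LOSS"})

    def test_no_membership_change_no_events(self):
        ref_w, alt_w, offs = scan_windows("GAAGATAAGAA", 5, "T", "A", k=6)
        ev = classify_esr_change(ref_w, alt_w, MotifSet("ESE", frozenset({"CCCCCC"})),
                                 MotifSet("ESS", frozenset({"GGGGGG"})), offs)
        assert not ev

    @settings(derandomize=True, max_examples=300)
    @given(
        context=st.text(alphabet="ACGT", min_size=13, max_size=13),
        alt_choice=st.integers(0, 2),
        ese=st.frozensets(st.text(alphabet="ACGT", min_size=6, max_size=6), max_size=30),
        ess=st.frozensets(st.text(alphabet="ACGT", min_size=6, max_size=6), max_size=30),
    )
    def test_agrees_with_occurrence_diff_oracle(self, context, alt_choice, ese, ess):
        centre = 6
        ref = context[centre]
        alt = [b for b in "ACGT" if b != ref][alt_choice]
        ref_w, alt_w, offs = scan_windows(context, centre, ref, alt, k=6)
        ev = classify_esr_change(
            ref_w, alt_w, MotifSet("ESE", ese), MotifSet("ESS", ess), offs
        )
        ese_gain, ese_loss = occurrence_diff_oracle(context, centre, ref, alt, ese, 6)
        ess_gain, ess_loss = occurrence_diff_oracle(context, centre, ref, alt, ess, 6)
        expected = set()
        if ese_gain:
            expected.add("ESE_GAIN")
        if ese_loss:
            expected.add("ESE_LOSS")
        if ess_gain:
            expected.add("ESS_GAIN")
        if ess_loss:
            expected.add("ESS_LOSS")
        assert set(ev.events) == expected

    @settings(derandomize=True, max_examples=200)
    @given(
        context=st.text(alphabet="ACGT", min_size=13, max_size=13),
        alt_choice=st.integers(0, 2),
        ese=st.frozensets(st.text(alphabet="ACGT", min_size=6, max_size=6), max_size=30),
    )
    def test_allele_swap_swaps_gain_and_loss(self, context, alt_choice, ese):
        centre = 6
        ref = context[centre]
        alt = [b for b in "ACGT" if b != ref][alt_choice]
        swapped = context[:centre] + alt + context[centre + 1 :]
        ese_set = MotifSet("ESE", ese)
        ess_set = MotifSet("ESS", frozenset())
        fwd = classify_esr_change(*scan_windows(context, centre, ref, alt, k=6)[:2],
                                  ese_set, ess_set)
        rev = classify_esr_change(*scan_windows(swapped, centre, alt, ref, k=6)[:2],
                                  ese_set, ess_set)
        flip = {"ESE_GAIN": "ESE_LOSS", "ESE_LOSS": "ESE_GAIN"}
        assert {flip[e] for e in fwd.events} == set(rev.events)


class TestAnnotateSplice:
    def _setup(self, pos, ese_motifs):
        t = make_transcript(
            [(100, 200), (300, 400)], "A" * 198, cds_interval=(100, 398)
        )
        m = make_mutation(context="GAAGATAAGAA", ref="T", alt="A", pos=pos)
        ann = annotate_splice(
            m, t, MotifSet("ESE", frozenset(ese_motifs)), MotifSet("ESS", frozenset())
        )
        return ann

    def test_near_splice_with_esr_change_sets_composite_flag(self):
        ann = self._setup(pos=190, ese_motifs={"GAAGAA"})  # distance 11
        assert ann.distance_bp == 11 and ann.near_splice
        assert ann.esr_near_splice

    def test_far_esr_change_fails_composite(self):
        ann = self._setup(pos=150, ese_motifs={"GAAGAA"})  # distance 51
        assert ann.distance_bp == 51 and not ann.near_splice
        assert ann.esr_events and not ann.esr_near_splice

    def test_near_without_events_fails_composite(self):
        ann = self._setup(pos=190, ese_motifs=set())
        assert ann.near_splice and not ann.esr_near_splice
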