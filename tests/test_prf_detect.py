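"""Frameshift-gene detection: candidates, excision classification, the
iterative detector and its report format."""

import numpy as np
import pytest

from ciliome import (
    InputError, PRFPlan, apply_excisions, back_translate, build_prf_transcript,
    classify_event, detect_prf, find_candidates, parse_prf_report, prf_report,
    random_protein, search_translated, translate,
)
from tests.conftest import make_hit


def _planted(events, seed=0, name="g"):
    rng = np.random.default_rng(seed)
    plan = PRFPlan(name=name, events=tuple(events))
    return build_prf_transcript(plan, "euplotes", rng)


class TestFindCandidates:
    def test_two_frames_colinear_is_candidate(self):
        hits = [make_hit("t1", "ref", frame=1, q_start=1, q_end=120,
                         s_start=1, s_end=120),
                make_hit("t1", "ref", frame=2, q_start=130, q_end=300,
                         s_start=121, s_end=300)]
        assert find_candidates(hits) == [("t1", "ref")]

    def test_same_frame_twice_is_not(self):
        hits = [make_hit("t1", "ref", frame=1, s_start=1),
                make_hit("t1", "ref", frame=1, q_start=200, q_end=300,
                         s_start=150, s_end=250)]
        assert find_candidates(hits) == []

    def test_different_references_are_not(self):
        hits = [make_hit("t1", "refA", frame=1),
                make_hit("t1", "refB", frame=2, q_start=150, q_end=250)]
        assert find_candidates(hits) == []

    def test_anticolinear_is_not(self):
        # downstream hit covers a more N-terminal reference region
        hits = [make_hit("t1", "ref", frame=1, q_start=1, q_end=120,
                         s_start=200, s_end=320),
                make_hit("t1", "ref", frame=2, q_start=130, q_end=300,
                         s_start=1, s_end=100)]
        assert find_candidates(hits) == []

    def test_protein_hits_rejected(self):
        with pytest.raises(InputError, match="frame"):
            find_candidates([make_hit("t1", "ref", frame=0)])


class TestClassifyEvent:
    def test_plus1_at_aaataa(self):
        transcript, ref, truth = _planted([("AAATAA", 1)])
        pos = int(truth.position[0])
        event = classify_event(transcript, pos, ref, "euplotes")
        assert event.model == 1 and event.excised == "T"
        assert event.slippery == "AAATAA" and event.stop_codon == "TAA"

    def test_plus2_at_tgttag(self):
        transcript, ref, truth = _planted([("TGTTAG", 2)])
        event = classify_event(transcript, int(truth.position[0]), ref,
                               "euplotes")
        assert event.model == 2 and event.excised == "TA"
        assert event.slippery == "TGTTAG"

    def test_terminal_stop_yields_none(self):
        transcript, ref, _ = _planted([])
        # the terminal stop sits right after the coding region
        stop_pos = len(ref) * 3
        assert transcript[stop_pos:stop_pos + 3] in ("TAA", "TAG")
        assert classify_event(transcript, stop_pos, ref, "euplotes") is None

    def test_non_stop_position_rejected(self):
        transcript, ref, truth = _planted([("AAATAA", 1)])
        with pytest.raises(InputError, match="not a stop"):
            classify_event(transcript, 3, ref, "euplotes")


class TestDetectPrf:
    def _run(self, events, seed=0):
        transcript, ref, truth = _planted(events, seed=seed)
        transcripts = [("g", transcript)]
        refs = [("g_ref", ref)]
        hits = search_translated(transcripts, refs, "euplotes")
        return detect_prf(transcripts, refs, hits, "euplotes"), truth

    def test_bbs7_pattern_three_plus1_events(self):
        genes, truth = self._run([("AAATAA", 1), ("AAATAG", 1),
                                  ("AAATAA", 1)])
        (gene,) = genes
        assert gene.n_events == 3
        assert [e.model for e in gene.events] == [1, 1, 1]
        assert [e.position for e in gene.events] == list(truth.position)
        assert not gene.truncated

    def test_clean_transcript_no_detection(self):
        genes, _ = self._run([])
        assert genes == []

    def test_mixed_models_exact_recovery(self):
        genes, truth = self._run([("AAATAA", 1), ("TTTTAG", 2)], seed=4)
        (gene,) = genes
        assert [(e.position, e.model) for e in gene.events] == \
            [(int(r.position), int(r.model)) for r in truth.itertuples()]

    def test_order_invariance_and_determinism(self):
        t1, r1, _ = _planted([("AAATAA", 1)], seed=1, name="a")
        t2, r2, _ = _planted([("TGTTAG", 2)], seed=2, name="b")
        fwd_t, fwd_r = [("a", t1), ("b", t2)], [("a_ref", r1), ("b_ref", r2)]
        hits_fwd = search_translated(fwd_t, fwd_r, "euplotes")
        hits_rev = search_translated(fwd_t[::-1], fwd_r[::-1], "euplotes")
        out_fwd = detect_prf(fwd_t, fwd_r, hits_fwd, "euplotes")
        out_rev = detect_prf(fwd_t[::-1], fwd_r[::-1], hits_rev, "euplotes")
        assert out_fwd == out_rev

    def test_require_aaatar_strict_mode(self):
        transcript, ref, _ = _planted([("TGTTAG", 2)], seed=6)
        transcripts, refs = [("g", transcript)], [("g_ref", ref)]
        hits = search_translated(transcripts, refs, "euplotes")
        assert detect_prf(transcripts, refs, hits, "euplotes",
                          require_aaatar=True) == []
        assert len(detect_prf(transcripts, refs, hits, "euplotes")) == 1

    def test_excision_fixed_point(self):
        """Applying the detected excisions yields one uninterrupted ORF
        whose translation reproduces the reference end to end."""
        transcript, ref, _ = _planted([("AAATAA", 1), ("AAATAG", 1)], seed=7)
        transcripts, refs = [("g", transcript)], [("g_ref", ref)]
        hits = search_translated(transcripts, refs, "euplotes")
        (gene,) = detect_prf(transcripts, refs, hits, "euplotes")
        edited = apply_excisions(transcript, gene.events)
        protein = translate(edited, "euplotes").split("*")[0]
        assert protein == ref


class TestFrameArithmetic:
    def test_deletions_shift_downstream_frames(self, rng):
        """Deleting 1 base at p moves downstream codons to frame +2 of the
        original sequence; deleting 2 moves them to frame +3."""
        prot = random_protein(60, rng)
        cds = back_translate(prot, "euplotes", rng)
        p = 90  # codon boundary
        del1 = cds[:p] + cds[p + 1:]
        del2 = cds[:p] + cds[p + 2:]
        tail1 = translate(del1, "euplotes")[p // 3:]
        tail2 = translate(del2, "euplotes")[p // 3:]
        assert translate(cds[p + 1:], "euplotes", 1) == tail1
        assert translate(cds, "euplotes", 2)[p // 3:] == tail1
        assert translate(cds, "euplotes", 3)[p // 3:] == tail2


class TestReport:
    def test_report_formatting_and_round_trip(self):
        transcript, ref, _ = _planted([("AAATAA", 1), ("AAATAG", 1)], seed=9)
        transcripts, refs = [("g", transcript)], [("g_ref", ref)]
        hits = search_translated(transcripts, refs, "euplotes")
        genes = detect_prf(transcripts, refs, hits, "euplotes",
                           annotations={"g": "Ciliary basal body"})
        table = prf_report(genes)
        row = table.iloc[0]
        assert row["Slippery sequence"] == "AAATAA/AAATAG"
        assert row["Frameshifting model"] == "+1/+1"
        assert row["Numbers of frameshifting"] == 2
        assert row["Cellular localization"] == "Ciliary basal body"
        assert parse_prf_report(table) == genes

    def test_empty_report(self):
        table = prf_report([])
        assert len(table) == 0 and list(table.columns)
        assert parse_prf_report(table) == []
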