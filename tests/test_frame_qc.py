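"""Reading-frame placement, stop/indel flagging and conservative rescue."""

import numpy as np
import pytest

from wormcoi.core_model import BarcodeRecord, MethodLabel, revcomp
from wormcoi.frame_qc import (
    COI5P_FRAME_OFFSET,
    FrameUndeterminedError,
    detect_stops_indels,
    place_reading_frame,
    reference_guided_insertion_correct,
    strict_reclip_and_retry,
)
from wormcoi.synthetic_data import generate_haplotype

SID = ("DE1", MethodLabel.TISSUE_CHELEX)


@pytest.fixture(scope="module")
def haplotype():
    # derived from the packaged species pool so that the packaged
    # reference profile is a meaningful alignment target
    from wormcoi.synthetic_data import load_packaged_library, mutate_coding

    seed_seq = next(s for t, g, s in load_packaged_library() if g == "earthworm")
    return mutate_coding(seed_seq, 0.005, np.random.default_rng(21))


class TestPlaceReadingFrame:
    def test_generative_frame_recovered(self, haplotype):
        rep = place_reading_frame(haplotype)
        assert rep.strand == "+"
        assert rep.frame_offset == COI5P_FRAME_OFFSET
        assert rep.n_stops == 0 and not rep.indel_suspected

    def test_deletion_induces_stops_and_suspicion(self, haplotype):
        # mid-sequence deletion: both flanks are long enough that every
        # frame/strand combination sees out-of-frame codons
        damaged = haplotype[:300] + haplotype[301:]
        rep = place_reading_frame(damaged)
        assert rep.n_stops > 0
        assert rep.indel_suspected

    def test_reverse_complement_symmetry(self, haplotype):
        rep = place_reading_frame(revcomp(haplotype))
        assert rep.strand == "-"
        assert rep.n_stops == 0

    def test_short_sequence_rejected(self):
        with pytest.raises(FrameUndeterminedError):
            place_reading_frame("ACGT" * 10)

    def test_ambiguous_codons_not_counted_as_stops(self):
        # TAN could be tyrosine; TAR can only be a stop
        seq = generate_haplotype(4)
        site = 100 - (100 - COI5P_FRAME_OFFSET) % 3
        with_n = seq[:site] + "TAN" + seq[site + 3 :]
        rep = place_reading_frame(with_n)
        assert rep.n_stops == 0


class TestDetectStopsIndels:
    def test_clean_haplotype(self, haplotype, reference_profile):
        rep = place_reading_frame(haplotype)
        assert detect_stops_indels(haplotype, rep, reference_profile) == "CLEAN"

    def test_inframe_stop_flagged(self, haplotype, reference_profile):
        site = 300 - (300 - COI5P_FRAME_OFFSET) % 3
        damaged = haplotype[:site] + "TAA" + haplotype[site + 3 :]
        rep = place_reading_frame(damaged)
        assert detect_stops_indels(damaged, rep, reference_profile) == "FLAGGED"

    def test_net_zero_indels_with_interior_stops_flagged(self, haplotype, reference_profile):
        # +1 insertion then -1 deletion: net length shift zero, but the
        # region between reads out of frame.  Bracket a known off-frame
        # stop codon so the broken interval provably contains one.
        from wormcoi.frame_qc import STOP_CODONS

        # insert-then-delete exposes original offset-0 codons; the
        # delete-then-insert variant exposes offset-2 codons
        stop0 = next((s for s in range(99, len(haplotype) - 162, 3)
                      if haplotype[s : s + 3] in STOP_CODONS), None)
        stop2 = next((s for s in range(101, len(haplotype) - 162, 3)
                      if haplotype[s : s + 3] in STOP_CODONS), None)
        if stop0 is not None:
            a, b = stop0 - 60, stop0 + 60
            damaged = haplotype[:a] + "A" + haplotype[a:b] + haplotype[b + 1 :]
        else:
            a, b = stop2 - 60, stop2 + 60
            damaged = haplotype[:a] + haplotype[a + 1 : b] + "A" + haplotype[b:]
        assert len(damaged) == len(haplotype)
        rep = place_reading_frame(damaged)
        assert rep.n_stops > 0
        assert detect_stops_indels(damaged, rep, reference_profile) == "FLAGGED"


def _record_with_insertion(haplotype, pos, qual):
    seq = haplotype[:pos] + "A" + haplotype[pos:]
    quals = np.full(len(seq), 45)
    quals[pos] = qual
    return BarcodeRecord(sample_id=SID, sequence=seq, quals=quals,
                         bidir_mask=np.ones(len(seq), dtype=bool))


class TestReferenceGuidedCorrection:
    def test_low_quality_insertion_deleted(self, haplotype, reference_profile):
        rec = _record_with_insertion(haplotype, 333, qual=8)
        rec, rep = reference_guided_insertion_correct(rec, reference_profile)
        assert rep.n_stops == 0
        assert rec.sequence == haplotype
        assert rec.corrected_positions  # audit trail retained

    def test_high_quality_insertion_refused(self, haplotype, reference_profile):
        rec = _record_with_insertion(haplotype, 333, qual=50)
        before = rec.sequence
        rec, rep = reference_guided_insertion_correct(rec, reference_profile)
        assert rec.sequence == before
        assert rep.n_stops > 0 or rep.indel_suspected

    def test_clean_record_unchanged(self, haplotype, reference_profile):
        quals = np.full(len(haplotype), 45)
        rec = BarcodeRecord(sample_id=SID, sequence=haplotype, quals=quals)
        rec, rep = reference_guided_insertion_correct(rec, reference_profile)
        assert rec.sequence == haplotype and rep.n_stops == 0

    def test_never_more_than_two_deletions(self, haplotype, reference_profile):
        # three separated low-quality insertions: too much editing, refuse
        seq = haplotype
        for pos in (500, 300, 100):
            seq = seq[:pos] + "A" + seq[pos:]
        quals = np.full(len(seq), 45)
        for pos in (100, 301, 502):
            quals[pos] = 5
        rec = BarcodeRecord(sample_id=SID, sequence=seq, quals=quals)
        rec, rep = reference_guided_insertion_correct(rec, reference_profile)
        assert len(rec.corrected_positions) <= 2
        assert detect_stops_indels(rec.sequence, rep, reference_profile) == "FLAGGED"


class TestStrictReclip:
    @staticmethod
    def _end_artifact_pair(haplotype, ins_pos, ins_qual=14, tail=60):
        """Both reads carry a template-level insertion near the 3' end,
        inside marginal-quality (Q=14) read ends: p_err=0.04 passes the
        default Mott cutoff (0.05) but not the halved one (0.025)."""
        from wormcoi.core_model import Direction, TraceRead

        template = haplotype[:ins_pos] + "A" + haplotype[ins_pos:]
        L = len(template)
        fwd_q = np.full(L, 50)
        fwd_q[L - tail :] = ins_qual
        fwd = TraceRead(SID, Direction.FORWARD, template, fwd_q)
        rev_span = template[400:]
        rev_q = np.full(len(rev_span), 50)
        rev_q[L - 400 - tail :] = ins_qual  # same marginal template region
        rev = TraceRead(SID, Direction.REVERSE, revcomp(rev_span), rev_q[::-1].copy())
        return fwd, rev

    def test_end_artifact_rescued_by_stricter_clip(self, haplotype, reference_profile):
        from wormcoi.assembly import assemble_contig, quality_end_clip

        fwd, rev = self._end_artifact_pair(haplotype, ins_pos=640)
        rec = assemble_contig(quality_end_clip(fwd), quality_end_clip(rev))
        rep = place_reading_frame(rec.sequence)
        assert detect_stops_indels(rec.sequence, rep, reference_profile) == "FLAGGED"
        out = strict_reclip_and_retry(fwd, rev, rec, reference_profile=reference_profile)
        rep = place_reading_frame(out.sequence)
        assert detect_stops_indels(out.sequence, rep, reference_profile) == "CLEAN"

    def test_mid_sequence_artifact_not_reclippable(self, haplotype, reference_profile):
        from wormcoi.assembly import assemble_contig, quality_end_clip
        from wormcoi.core_model import Direction, TraceRead

        # high-quality interior insertion: reclipping ends cannot reach it
        template = haplotype[:300] + "A" + haplotype[300:]
        fwd = TraceRead(SID, Direction.FORWARD, template, np.full(len(template), 50))
        rev = TraceRead(SID, Direction.REVERSE, revcomp(template), np.full(len(template), 50))
        rec = assemble_contig(quality_end_clip(fwd), quality_end_clip(rev))
        out = strict_reclip_and_retry(fwd, rev, rec, reference_profile=reference_profile)
        assert out.sequence == rec.sequence

    def test_clean_record_is_noop(self, haplotype, reference_profile):
        quals = np.full(len(haplotype), 45)
        rec = BarcodeRecord(sample_id=SID, sequence=haplotype, quals=quals)
        assert strict_reclip_and_retry(None, None, rec, reference_profile=reference_profile) is rec
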