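"""Bidirectional Sanger contig assembly.

Stages: primer trimming (Hamming scan), quality end-clipping (modified
Mott rule, the de facto Sanger standard), semi-global overlap alignment
of the forward read against the reverse-complemented reverse read, and a
quality-based consensus.  Unresolved strand conflicts are written
conservatively as ``N``; a per-site record of the conflicting strand
base calls is kept so that diagnostic sites can later be re-annotated
with IUPAC codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align

from ._align_compat import set_end_gap_scores
from .core_model import (
    BarcodeRecord,
    Direction,
    PrimerSet,
    TraceRead,
    iupac_code,
    revcomp,
)

__all__ = [
    "ClipSpec",
    "ConsensusPolicy",
    "trim_primers",
    "quality_end_clip",
    "assemble_contig",
    "annotate_diagnostic_ambiguities",
]


@dataclass(frozen=True)
class ClipSpec:
    """Modified-Mott end clip: keep the contiguous segment maximising the
    running sum of (cutoff - p_err), where p_err = 10^(-Q/10)."""

    error_prob_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.error_prob_cutoff < 1.0:
            raise ValueError("error_prob_cutoff must be in (0, 1)")


@dataclass(frozen=True)
class ConsensusPolicy:
    """Quality rules for calling the consensus over the strand overlap.

    A strand disagreement is resolved toward the higher-quality base only
    when the Phred difference reaches ``conflict_quality_margin``; below
    the margin, or when both calls are low quality, the site becomes N.
    Non-overlapping flank bases are kept only above ``low_q_threshold``
    ("reliable" single-strand evidence).
    """

    conflict_quality_margin: int = 10
    low_q_threshold: int = 20

    def __post_init__(self) -> None:
        if self.conflict_quality_margin < 0 or self.low_q_threshold < 0:
            raise ValueError("thresholds must be >= 0")


def _hamming_scan(seq: str, primer: str) -> tuple[int, int]:
    """Best (mismatches, start) of `primer` over all full-length offsets."""
    k = len(primer)
    best = (k + 1, -1)
    for start in range(0, len(seq) - k + 1):
        mm = sum(1 for a, b in zip(seq[start : start + k], primer) if a != b)
        if mm < best[0]:
            best = (mm, start)
            if mm == 0:
                break
    return best


def trim_primers(read: TraceRead, primers: PrimerSet, max_mismatch: int = 3) -> TraceRead:
    """Remove the sequencing primer and anything outside it from the 5' end.

    Forward reads begin with the forward primer; reverse reads (read in
    the reverse-strand direction) begin with the reverse primer.  If no
    match within ``max_mismatch`` exists the read is returned unchanged —
    absence of a primer is legal (it may already be clipped).
    """
    if len(read) == 0:
        return read
    primer = primers.forward if read.direction is Direction.FORWARD else primers.reverse
    # scan only the leading region: primer plus a small slack
    window = min(len(read), len(primer) + 30)
    mm, start = _hamming_scan(read.bases[:window], primer)
    if start < 0 or mm > max_mismatch:
        return read
    return read.slice(start + len(primer), len(read))


def quality_end_clip(read: TraceRead, spec: ClipSpec = ClipSpec()) -> TraceRead:
    """Clip low-quality ends with the modified Mott rule.

    The running score accumulates (cutoff - p_err) and is clipped at 0;
    the retained segment is the one ending at the all-time score maximum
    and starting just after the last reset.  A read whose bases all fall
    below the cutoff clips to empty, which downstream code treats as an
    unusable trace.
    """
    if len(read) == 0:
        return read
    p_err = np.power(10.0, -read.quals / 10.0)
    gains = spec.error_prob_cutoff - p_err

    best_score = 0.0
    best_range = (0, 0)
    score = 0.0
    seg_start = 0
    for i, g in enumerate(gains):
        score += g
        if score <= 0.0:
            score = 0.0
            seg_start = i + 1
        elif score > best_score:
            best_score = score
            best_range = (seg_start, i + 1)
    return read.slice(*best_range)


def _overlap_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -2.0
    # free end gaps on both sequences -> overlap (dovetail) alignment
    set_end_gap_scores(aligner, target=0.0, query=0.0)
    return aligner


def assemble_contig(
    fwd: Optional[TraceRead],
    rev: Optional[TraceRead],
    policy: ConsensusPolicy = ConsensusPolicy(),
    min_overlap: int = 50,
    min_overlap_identity: float = 90.0,
) -> Optional[BarcodeRecord]:
    """Assemble clipped forward/reverse reads into a consensus contig.

    Returns ``None`` when no usable contig can be built (missing or empty
    read, overlap shorter than ``min_overlap``, or overlap identity below
    ``min_overlap_identity`` %) — the caller records UNUSABLE_CONTIG.

    Consensus rules over the overlap: agreement keeps the base at the
    maximum of the two qualities; a disagreement with quality margin >=
    ``policy.conflict_quality_margin`` keeps the higher-quality base; any
    other disagreement, or one where both calls are below
    ``policy.low_q_threshold``, is written as N.  Non-overlapping flanks
    contribute only bases above ``policy.low_q_threshold``.
    """
    if fwd is None or rev is None or len(fwd) == 0 or len(rev) == 0:
        return None

    sample_id = fwd.sample_id
    rseq = revcomp(rev.bases)
    rqual = rev.quals[::-1]

    aligner = _overlap_aligner()
    aln = aligner.align(fwd.bases, rseq)[0]
    fidx, ridx = aln.indices  # -1 marks a gap in that row

    cols = []  # (fwd_base|None, fwd_q, rev_base|None, rev_q)
    for k in range(fidx.shape[0]):
        fi, ri = int(fidx[k]), int(ridx[k])
        fb = fwd.bases[fi] if fi >= 0 else None
        rb = rseq[ri] if ri >= 0 else None
        fq = int(fwd.quals[fi]) if fi >= 0 else -1
        rq = int(rqual[ri]) if ri >= 0 else -1
        cols.append((fb, fq, rb, rq))

    both = [i for i, c in enumerate(cols) if c[0] is not None and c[2] is not None]
    if not both:
        return None
    ov_start, ov_end = both[0], both[-1] + 1
    overlap_cols = cols[ov_start:ov_end]
    ov_pairs = [(c[0], c[2]) for c in overlap_cols if c[0] is not None and c[2] is not None]
    overlap_len = len(ov_pairs)
    if overlap_len < min_overlap:
        return None
    matches = sum(1 for a, b in ov_pairs if a == b)
    if 100.0 * matches / overlap_len < min_overlap_identity:
        return None

    seq_chars: list[str] = []
    quals: list[int] = []
    bidir: list[bool] = []
    conflicts: dict[int, tuple[str, str]] = {}

    for i, (fb, fq, rb, rq) in enumerate(cols):
        in_overlap = ov_start <= i < ov_end
        if fb is not None and rb is not None:
            if fb == rb:
                base, q = fb, max(fq, rq)
            elif abs(fq - rq) >= policy.conflict_quality_margin and max(fq, rq) >= policy.low_q_threshold:
                base, q = (fb, fq) if fq > rq else (rb, rq)
            else:
                base, q = "N", min(fq, rq)
                conflicts[len(seq_chars)] = (fb, rb)
            seq_chars.append(base)
            quals.append(q)
            bidir.append(True)
        else:
            # single-strand column: interior gaps within the overlap are
            # alignment artifacts and are skipped; flank bases are kept
            # only when reliable (above the low-quality threshold).
            if in_overlap:
                continue
            b, q = (fb, fq) if fb is not None else (rb, rq)
            if q > policy.low_q_threshold:
                seq_chars.append(b)
                quals.append(q)
                bidir.append(False)

    if not seq_chars:
        return None
    return BarcodeRecord(
        sample_id=sample_id,
        sequence="".join(seq_chars),
        quals=np.array(quals, dtype=int),
        bidir_mask=np.array(bidir, dtype=bool),
        conflicts=conflicts,
    )


def annotate_diagnostic_ambiguities(record: BarcodeRecord, sites) -> BarcodeRecord:
    """Replace N at listed diagnostic sites with the minimal IUPAC code
    covering the two strand base calls recorded at assembly time.

    Sites without conflicting-strand evidence are left untouched.
    Positions are 0-based contig coordinates.
    """
    if record.sequence is None:
        return record
    seq = list(record.sequence)
    for pos in sites:
        if pos in record.conflicts and seq[pos] == "N":
            fb, rb = record.conflicts[pos]
            if fb in "ACGT" and rb in "ACGT":
                seq[pos] = iupac_code({fb, rb})
    record.sequence = "".join(seq)
    return record
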