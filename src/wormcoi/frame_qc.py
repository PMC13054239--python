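"""Reading-frame QC for COI-5P barcodes.

Earthworm COI is translated with the invertebrate mitochondrial genetic
code (translation table 5; stop codons TAA and TAG).  A correct Folmer
fragment contains no in-frame stop codon, so frame placement here is by
minimum stop count over all six frame/strand combinations — a behavioral
stand-in for profile-HMM frame placement.  Frameshifted sequences are
screened against a packaged reference profile and, where the empirical
base quality marks an inserted base as unreliable, conservatively
rescued by deleting the insertion (at most two deletions; heavy editing
is refused).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align, SeqIO

from ._align_compat import set_end_gap_scores
from .core_model import IUPAC_SETS, BarcodeRecord, revcomp

__all__ = [
    "STOP_CODONS",
    "FrameReport",
    "FrameUndeterminedError",
    "default_reference_profile",
    "place_reading_frame",
    "detect_stops_indels",
    "reference_guided_insertion_correct",
    "strict_reclip_and_retry",
]

#: Invertebrate mitochondrial code: only TAA and TAG terminate.
STOP_CODONS = frozenset({"TAA", "TAG"})

#: Frame offset of the first complete codon in a standard Folmer amplicon.
COI5P_FRAME_OFFSET = 1


class FrameUndeterminedError(ValueError):
    pass


@dataclass
class FrameReport:
    frame_offset: int  # 0, 1 or 2
    strand: str  # '+' or '-'
    n_stops: int
    indel_suspected: bool = False
    corrected_positions: list = field(default_factory=list)


def default_reference_profile() -> str:
    """Packaged synthetic COI-5P reference sequence (stop-free, in the
    standard barcode frame)."""
    path = resources.files("wormcoi.data") / "synthetic_coi_profile.fasta"
    with path.open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return str(rec.seq).upper()


def _codon_is_stop(codon: str) -> bool:
    """True iff every IUPAC expansion of the codon is a stop codon.

    Codons containing N or an ambiguity code that can also encode an
    amino acid are not counted as stops.
    """
    try:
        expansions = itertools.product(*(IUPAC_SETS[b] for b in codon))
    except KeyError:
        return False
    return all("".join(c) in STOP_CODONS for c in expansions)


def count_stops(seq: str, offset: int) -> int:
    n = 0
    for i in range(offset, len(seq) - 2, 3):
        if _codon_is_stop(seq[i : i + 3]):
            n += 1
    return n


def place_reading_frame(seq: str) -> FrameReport:
    """Pick the frame/strand minimising in-frame stop count.

    Ties are broken toward the + strand, then the smallest offset.
    Sequences shorter than 100 bp carry too little signal and raise
    :class:`FrameUndeterminedError`.
    """
    if len(seq) < 100:
        raise FrameUndeterminedError(f"sequence too short to place frame ({len(seq)} bp)")
    seq = seq.upper()
    candidates = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for offset in range(3):
            candidates.append((count_stops(s, offset), 0 if strand == "+" else 1, offset, strand))
    n_stops, _, offset, strand = min(candidates)
    return FrameReport(frame_offset=offset, strand=strand, n_stops=n_stops,
                       indel_suspected=n_stops > 0)


def _profile_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -2.0
    set_end_gap_scores(aligner, target=0.0, query=0.0)
    return aligner


def _net_internal_shift(query: str, reference: str) -> tuple[int, list[int]]:
    """Net insertion-minus-deletion length within the aligned core, plus
    query positions of single-base insertions relative to the reference."""
    aln = _profile_aligner().align(reference, query)[0]
    ridx, qidx = aln.indices
    core = [k for k in range(ridx.shape[0]) if ridx[k] >= 0 and qidx[k] >= 0]
    if not core:
        return 0, []
    lo, hi = core[0], core[-1] + 1
    ins_cols = [k for k in range(lo, hi) if ridx[k] < 0]  # extra base in query
    del_cols = [k for k in range(lo, hi) if qidx[k] < 0]  # base missing from query
    # single-base insertions: isolated reference-gap columns
    ins_positions = [
        int(qidx[k])
        for k in ins_cols
        if (k - 1 < lo or ridx[k - 1] >= 0) and (k + 1 >= hi or ridx[k + 1] >= 0)
    ]
    return len(ins_cols) - len(del_cols), ins_positions


def detect_stops_indels(seq: str, report: FrameReport, reference_profile: str | None = None) -> str:
    """Return ``"FLAGGED"`` when the sequence shows in-frame stops or a
    net length shift against the reference profile that is not a
    multiple of 3; otherwise ``"CLEAN"``."""
    if report.n_stops > 0:
        return "FLAGGED"
    if reference_profile:
        fwd = seq.upper()
        rev = revcomp(fwd)
        aligner = _profile_aligner()
        oriented = rev if aligner.score(reference_profile, rev) > aligner.score(reference_profile, fwd) else fwd
        shift, _ = _net_internal_shift(oriented, reference_profile)
        if shift % 3 != 0:
            return "FLAGGED"
    return "CLEAN"


def _delete_positions(record: BarcodeRecord, positions: list[int]) -> BarcodeRecord:
    keep = np.ones(len(record.sequence), dtype=bool)
    keep[positions] = False
    old_to_new = np.cumsum(keep) - 1
    record.sequence = "".join(b for b, k in zip(record.sequence, keep) if k)
    if record.quals is not None:
        record.quals = record.quals[keep]
    if record.bidir_mask is not None:
        record.bidir_mask = record.bidir_mask[keep]
    record.conflicts = {
        int(old_to_new[p]): v for p, v in record.conflicts.items() if keep[p]
    }
    return record


def reference_guided_insertion_correct(
    record: BarcodeRecord,
    reference_profile: str | None = None,
    quality_threshold: int = 20,
) -> tuple[BarcodeRecord, FrameReport]:
    """Conservatively delete likely-artifactual insertions.

    A candidate is a single-base insertion relative to the reference
    profile.  It is deleted only when its base quality is below
    ``quality_threshold`` (the empirical trace evidence marks it
    unreliable) AND the deletion restores a stop-free frame.  At most two
    deletions are attempted; anything heavier leaves the record flagged.
    """
    if reference_profile is None:
        reference_profile = default_reference_profile()
    report = place_reading_frame(record.sequence)
    if detect_stops_indels(record.sequence, report, reference_profile) == "CLEAN":
        return record, report

    # orient by profile alignment score: the stop-minimising frame of a
    # frameshifted sequence can land on the wrong strand
    fwd_seq = record.sequence.upper()
    rev_seq = revcomp(fwd_seq)
    aligner = _profile_aligner()
    use_minus = aligner.score(reference_profile, rev_seq) > aligner.score(reference_profile, fwd_seq)
    oriented = rev_seq if use_minus else fwd_seq
    _, ins_positions = _net_internal_shift(oriented, reference_profile)
    n = len(record.sequence)
    if use_minus:
        ins_positions = [n - 1 - p for p in ins_positions]
    # gap placement is ambiguous within repeats, so the reported column is
    # only a neighborhood; the quality gate picks the actual artifact base
    window = 8
    candidates: list[int] = []
    for p in ins_positions:
        for q in range(max(0, p - window), min(n, p + window + 1)):
            if (
                record.quals is not None
                and record.quals[q] < quality_threshold
                and q not in candidates
            ):
                candidates.append(q)
    candidates.sort(key=lambda q: (int(record.quals[q]), q))

    trial_sets = [[p] for p in candidates] + [
        list(pair) for pair in itertools.combinations(candidates, 2)
    ]
    for positions in trial_sets:
        trial = "".join(b for i, b in enumerate(record.sequence) if i not in positions)
        trial_report = place_reading_frame(trial)
        # acceptance condition: the deletion restores a stop-free frame
        if trial_report.n_stops == 0:
            _delete_positions(record, sorted(positions))
            record.corrected_positions = sorted(positions)
            trial_report.corrected_positions = sorted(positions)
            return record, trial_report
    return record, report


def strict_reclip_and_retry(fwd, rev, record, clip_spec=None, policy=None,
                            reference_profile: str | None = None):
    """Re-assemble a flagged record with end-clipping twice as strict.

    Returns the re-assembled record if the stricter clip resolves the
    frame problem, else the original record unchanged.
    """
    from .assembly import ClipSpec, ConsensusPolicy, assemble_contig, quality_end_clip

    if reference_profile is None:
        reference_profile = default_reference_profile()
    report = place_reading_frame(record.sequence)
    if detect_stops_indels(record.sequence, report, reference_profile) == "CLEAN":
        return record
    clip_spec = clip_spec or ClipSpec()
    policy = policy or ConsensusPolicy()
    strict = ClipSpec(error_prob_cutoff=clip_spec.error_prob_cutoff / 2.0)
    retry = assemble_contig(quality_end_clip(fwd, strict), quality_end_clip(rev, strict), policy)
    if retry is None or retry.sequence is None or len(retry.sequence) < 100:
        return record
    retry_report = place_reading_frame(retry.sequence)
    if detect_stops_indels(retry.sequence, retry_report, reference_profile) == "CLEAN":
        return retry
    return record
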