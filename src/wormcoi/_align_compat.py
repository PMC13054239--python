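"""Version-tolerant end-gap configuration for Bio.Align.PairwiseAligner.

Biopython renamed ``target_end_gap_score`` / ``query_end_gap_score`` to
``end_insertion_score`` / ``end_deletion_score``; setting the old names
still works but warns.  Targets are always the first sequence passed to
``align``.
"""

from __future__ import annotations


def _set(aligner, new: str, old: str, value: float) -> None:
    try:
        setattr(aligner, new, value)
    except AttributeError:  # pragma: no cover - older Biopython
        setattr(aligner, old, value)


def set_end_gap_scores(aligner, target: float | None = None, query: float | None = None) -> None:
    if target is not None:
        _set(aligner, "end_insertion_score", "target_end_gap_score", target)
    if query is not None:
        _set(aligner, "end_deletion_score", "query_end_gap_score", query)
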