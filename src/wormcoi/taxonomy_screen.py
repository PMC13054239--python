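"""Homology-based taxonomic assignment against a packaged reference library.

Stands in for live NCBI BLAST / BOLD identification: every query is
aligned glocally (query global, subject local) against each library
entry, identity is computed over aligned non-gap columns with ambiguous
columns excluded, and the best hit's group label (earthworm vs other)
drives the contamination screen.  Species are assigned at the common
97%-98% identity cutoff (default 97, inclusive); earthworm hits below
the cutoff keep the top taxon as a putative assignment rather than
being discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from ._align_compat import set_end_gap_scores
from .core_model import is_ambiguous

__all__ = [
    "ReferenceLibrary",
    "HitResult",
    "load_reference_library",
    "default_reference_library",
    "top_hit",
    "classify_contamination",
    "assign_species",
    "summarize_identities",
    "LOW_CONFIDENCE",
]

LOW_CONFIDENCE = "LOW_CONFIDENCE"


@dataclass(frozen=True)
class HitResult:
    taxon: str
    group: str
    identity_pct: float
    aligned_length: int
    query_cover_pct: float


class ReferenceLibrary:
    """Taxon-annotated reference sequences: (binomial, group, sequence)."""

    def __init__(self, entries):
        self.entries = [(t, g, s.upper()) for t, g, s in entries]
        if not self.entries:
            raise ValueError("reference library is empty")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def groups(self):
        return {g for _, g, _ in self.entries}


def load_reference_library(path) -> ReferenceLibrary:
    """Read a FASTA library with headers ``>taxon|<binomial>|group=<grp>``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) < 3 or "=" not in fields[2]:
            raise ValueError(f"malformed library header: {rec.description!r}")
        entries.append((fields[1], fields[2].split("=", 1)[1], str(rec.seq)))
    return ReferenceLibrary(entries)


def default_reference_library() -> ReferenceLibrary:
    path = resources.files("wormcoi.data") / "synthetic_reference_library.fasta"
    return load_reference_library(path)


def _glocal_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -2.0
    # subject (target) end gaps free: query aligns globally within subject
    set_end_gap_scores(aligner, target=0.0)
    return aligner


def _identity(query: str, subject: str) -> tuple[float, int]:
    """(identity %, aligned length) over non-gap columns; columns with an
    ambiguity code on either side are excluded from both counts."""
    aln = _glocal_aligner().align(subject, query)[0]
    sidx, qidx = aln.indices
    matches = compared = aligned = 0
    for k in range(sidx.shape[0]):
        si, qi = int(sidx[k]), int(qidx[k])
        if si < 0 or qi < 0:
            continue
        aligned += 1
        qb, sb = query[qi], subject[si]
        if is_ambiguous(qb) or is_ambiguous(sb):
            continue
        compared += 1
        if qb == sb:
            matches += 1
    pct = 100.0 * matches / compared if compared else 0.0
    return pct, aligned


def top_hit(query: str, lib: ReferenceLibrary) -> HitResult:
    """Best library hit by identity, then aligned length, then taxon name.

    Identity is matches over aligned non-gap, non-ambiguous columns.
    """
    if len(query) < 100:
        raise ValueError(f"query too short for homology search ({len(query)} bp)")
    query = query.upper()
    best = None
    for taxon, group, subject in lib.entries:
        pct, aligned = _identity(query, subject)
        key = (-pct, -aligned, taxon)
        if best is None or key < best[0]:
            cover = 100.0 * aligned / len(query)
            best = (key, HitResult(taxon, group, pct, aligned, min(cover, 100.0)))
    return best[1]


def classify_contamination(hit: HitResult) -> str:
    """EARTHWORM if the top hit belongs to the earthworm group, else
    NON_EARTHWORM (downstream: FAIL_CONTAMINATION)."""
    return "EARTHWORM" if hit.group == "earthworm" else "NON_EARTHWORM"


def assign_species(hit: HitResult, cutoff_pct: float = 97.0) -> tuple[str, float]:
    """Species-level assignment at the identity cutoff (inclusive).

    Below the cutoff the label is LOW_CONFIDENCE; the top taxon is still
    retained by callers as a putative identification.
    """
    if hit.identity_pct >= cutoff_pct:
        return hit.taxon, hit.identity_pct
    return LOW_CONFIDENCE, hit.identity_pct


def summarize_identities(records) -> pd.DataFrame:
    """Per-method descriptive statistics of top-hit identity percentages
    over earthworm-assigned records (the homology-search summary table)."""
    rows = []
    by_method: dict = {}
    for r in records:
        if r.top_identity_pct is None or r.top_group != "earthworm":
            continue
        by_method.setdefault(r.sample_id[1], []).append(r.top_identity_pct)
    for method, vals in by_method.items():
        v = np.asarray(vals, dtype=float)
        rows.append(
            {
                "method": method.value,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "median": float(np.median(v)),
                "min": float(v.min()),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)
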