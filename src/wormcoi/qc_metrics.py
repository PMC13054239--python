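"""Quality classification, tiered success rates, concordance and
intra-specimen sequencing-error statistics.

Reference-quality classification applies five criteria to each
functional barcode: contig length > 500 bp, ambiguous bases < 1%,
non-N bidirectional coverage >= 40%, a contiguous run of high-quality
bases (Phred > 20) spanning > 75% of the contig, and a mean contig
quality score (QS) > 30.  Sequencing error between two barcodes of the
same specimen is 100 - PID, where PID = (1 - p-distance) x 100 and the
p-distance uses pairwise deletion of gaps and ambiguous positions.

Printed percentages are rounded half-up to one decimal so that e.g.
26/39 reports as 66.7.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np
import pandas as pd
from Bio import Align

from ._align_compat import set_end_gap_scores
from .core_model import (
    BarcodeRecord,
    DatasetView,
    FailureCategory,
    MethodLabel,
    OutcomeTable,
    Status,
    is_ambiguous,
)

__all__ = [
    "QualityCriteria",
    "Rate",
    "RateReport",
    "UndefinedDistanceError",
    "classify_quality",
    "p_distance",
    "pid",
    "align_pair",
    "sequencing_error_table",
    "compute_rates",
    "compute_concordance",
    "round_pct",
    "normalize_binomial",
]


class UndefinedDistanceError(ValueError):
    pass


@dataclass(frozen=True)
class QualityCriteria:
    """The five reference-quality criteria with their boundary senses."""

    min_length_bp: int = 500          # strict >
    max_ambiguous_pct: float = 1.0    # strict <
    min_bidir_nonN_pct: float = 40.0  # inclusive >=
    min_contiguous_hq_pct: float = 75.0  # strict >
    hq_phred: int = 20                # strict > within the run
    min_qs: float = 30.0              # strict >


def classify_quality(record: BarcodeRecord, criteria: QualityCriteria = QualityCriteria()) -> Status:
    """Partition a functional barcode into reference quality vs
    functional-low-quality by the five criteria (all must hold)."""
    ok = (
        record.length_bp is not None
        and record.length_bp > criteria.min_length_bp
        and record.pct_ambiguous < criteria.max_ambiguous_pct
        and record.pct_bidirectional_nonN >= criteria.min_bidir_nonN_pct
        and record.pct_contiguous_hq(criteria.hq_phred) > criteria.min_contiguous_hq_pct
        and record.qs > criteria.min_qs
    )
    return Status.REFERENCE_QUALITY if ok else Status.FUNCTIONAL_LOW_QUALITY


# ---------------------------------------------------------------------------
# distances


def _comparable(a: str, b: str):
    return (
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x != "-" and y != "-" and not is_ambiguous(x) and not is_ambiguous(y)
    )


def p_distance(a: str, b: str) -> float:
    """Observed proportion of differences with pairwise deletion: columns
    holding a gap, N or any IUPAC ambiguity in either sequence are
    excluded from numerator and denominator."""
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    mism = total = 0
    for x, y in _comparable(a, b):
        total += 1
        if x != y:
            mism += 1
    if total == 0:
        raise UndefinedDistanceError("no comparable sites under pairwise deletion")
    return mism / total


def pid(a: str, b: str) -> float:
    """Percentage sequence identity: (1 - p-distance) x 100."""
    return 100.0 * (1.0 - p_distance(a, b))


_pair_aligner = Align.PairwiseAligner()
_pair_aligner.mode = "global"
_pair_aligner.match_score = 2.0
_pair_aligner.mismatch_score = -2.0
_pair_aligner.open_gap_score = -8.0
_pair_aligner.extend_gap_score = -2.0
set_end_gap_scores(_pair_aligner, target=0.0, query=0.0)


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global alignment with free end gaps, for near-identical barcodes
    that may differ in terminal coverage."""
    aln = _pair_aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb


# ---------------------------------------------------------------------------
# intra-specimen error table


def sequencing_error_table(primary: DatasetView) -> pd.DataFrame:
    """Pairwise sequencing error (%) between intra-specimen barcodes.

    For every ordered method pair, specimens holding functional barcodes
    from both methods contribute one comparison: the two barcodes are
    pairwise-aligned and the error is 100 x p-distance under pairwise
    deletion.  Any intra-specimen difference is attributed to technical
    artifacts since the true template is shared.
    """
    by_specimen: dict[str, dict[MethodLabel, BarcodeRecord]] = {}
    for rec in primary.records:
        by_specimen.setdefault(rec.sample_id[0], {})[rec.sample_id[1]] = rec

    rows = []
    for m1, m2 in itertools.combinations(MethodLabel, 2):
        errors = []
        for specimen, recs in by_specimen.items():
            if m1 in recs and m2 in recs:
                ga, gb = align_pair(recs[m1].sequence, recs[m2].sequence)
                errors.append(100.0 * p_distance(ga, gb))
        v = np.asarray(errors, dtype=float)
        rows.append(
            {
                "pair": f"{m1.value} vs {m2.value}",
                "n_comparisons": len(v),
                "mean": float(v.mean()) if len(v) else np.nan,
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "median": float(np.median(v)) if len(v) else np.nan,
                "min": float(v.min()) if len(v) else np.nan,
                "max": float(v.max()) if len(v) else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tiered rates


def round_pct(num: int, den: int) -> Optional[float]:
    """Percentage to one decimal, half-up (26/39 -> 66.7); None if den=0."""
    if den == 0:
        return None
    pct = Decimal(100 * num) / Decimal(den)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Rate:
    num: int
    den: int

    @property
    def pct(self) -> Optional[float]:
        return round_pct(self.num, self.den)

    def as_dict(self) -> dict:
        return {"num": self.num, "den": self.den, "pct": self.pct}


@dataclass
class RateReport:
    per_method: dict  # MethodLabel -> {metric: Rate}
    overall_sequencing_success: Rate
    primary_dataset_size: int
    failure_counts: dict  # MethodLabel -> {category: Rate}

    def as_dict(self) -> dict:
        return {
            "per_method": {
                m.value: {k: r.as_dict() for k, r in d.items()}
                for m, d in self.per_method.items()
            },
            "overall_sequencing_success": self.overall_sequencing_success.as_dict(),
            "primary_dataset_size": self.primary_dataset_size,
            "failure_counts": {
                m.value: {k: r.as_dict() for k, r in d.items()}
                for m, d in self.failure_counts.items()
            },
        }


def compute_rates(outcomes: OutcomeTable) -> RateReport:
    """Tiered per-method rates.

    amplification success = amplified / attempted;
    sequencing success   = functional / amplified;
    recovery (overall)   = reference quality / attempted;
    recovery (primary)   = reference quality / functional.
    """
    per_method: dict = {}
    failure_counts: dict = {}
    tot_functional = tot_amplified = 0
    for method in MethodLabel:
        rows = outcomes.rows_for_method(method)
        if not rows:
            continue
        attempted = len(rows)
        amplified = sum(r.amplified for r in rows)
        functional = sum(r.functional for r in rows)
        refq = sum(r.reference_quality for r in rows)
        tot_functional += functional
        tot_amplified += amplified
        per_method[method] = {
            "amplification_success": Rate(amplified, attempted),
            "sequencing_success": Rate(functional, amplified),
            "recovery_overall": Rate(refq, attempted),
            "recovery_within_primary": Rate(refq, functional),
        }
        failure_counts[method] = {
            cat.value: Rate(
                sum(1 for r in rows if r.failure_category is cat), amplified
            )
            for cat in FailureCategory
        }
    return RateReport(
        per_method=per_method,
        overall_sequencing_success=Rate(tot_functional, tot_amplified),
        primary_dataset_size=tot_functional,
        failure_counts=failure_counts,
    )


# ---------------------------------------------------------------------------
# concordance


def normalize_binomial(name: Optional[str]) -> Optional[str]:
    """Case-insensitive genus+species; subspecies/lineage suffixes dropped."""
    if not name:
        return None
    parts = name.strip().lower().split()
    return " ".join(parts[:2]) if parts else None


def compute_concordance(outcomes: OutcomeTable):
    """Genetic-data vs morphospecies concordance over the primary dataset.

    A barcode is concordant when its homology-based taxon equals the
    specimen's morphospecies (normalized binomials); a specimen is
    concordant when all of its functional barcodes are.  Rows lacking a
    morphospecies are excluded.
    """
    functional = [
        r for r in outcomes
        if r.functional and normalize_binomial(r.morphospecies) is not None
    ]
    barcode_hits = 0
    per_method_counts: dict[MethodLabel, list[int]] = {m: [0, 0] for m in MethodLabel}
    by_specimen: dict[str, list[bool]] = {}
    for r in functional:
        concordant = normalize_binomial(r.genetic_taxon) == normalize_binomial(r.morphospecies)
        barcode_hits += concordant
        per_method_counts[r.method][0] += concordant
        per_method_counts[r.method][1] += 1
        by_specimen.setdefault(r.specimen_id, []).append(concordant)

    sample_level = Rate(
        sum(all(v) for v in by_specimen.values()), len(by_specimen)
    )
    barcode_level = Rate(barcode_hits, len(functional))
    per_method = {
        m: Rate(c[0], c[1]) for m, c in per_method_counts.items() if c[1] > 0
    }
    return sample_level, barcode_level, per_method
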