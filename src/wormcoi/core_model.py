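"""Domain types for the COI barcode curation pipeline.

The pipeline compares three DNA collection methods (Chelex tissue
extraction, QIAGEN tissue extraction, QIAGEN swab extraction) for
recovering the ~658 bp Folmer fragment of mitochondrial COI from
earthworms.  Each (specimen, method) pair yields one bidirectionally
sequenced Sanger sample; the types below carry a sample from raw
directional reads through consensus assembly, reading-frame QC,
taxonomic screening and quality classification.

Coordinates are 0-based half-open internally; human-facing reports use
1-based inclusive positions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "MethodLabel",
    "Direction",
    "Status",
    "FailureCategory",
    "Scope",
    "Specimen",
    "TraceRead",
    "PrimerSet",
    "DEFAULT_PRIMERS",
    "BarcodeRecord",
    "OutcomeRow",
    "OutcomeTable",
    "DatasetView",
    "revcomp",
    "IUPAC_SETS",
    "iupac_code",
    "is_ambiguous",
]


class MethodLabel(enum.Enum):
    """The three DNA collection methods under comparison."""

    TISSUE_CHELEX = "Tissue-Chelex"
    TISSUE_QIAGEN = "Tissue-QIAGEN"
    SWAB_QIAGEN = "Swab-QIAGEN"

    @property
    def token(self) -> str:
        """Short token used in FASTQ record names and file stems."""
        return {"Tissue-Chelex": "TC", "Tissue-QIAGEN": "TQ", "Swab-QIAGEN": "SQ"}[self.value]

    @classmethod
    def from_token(cls, token: str) -> "MethodLabel":
        for m in cls:
            if m.token == token or m.value == token or m.name == token:
                return m
        raise ValueError(f"unknown method token: {token!r}")


class Direction(enum.Enum):
    FORWARD = "F"
    REVERSE = "R"


class Status(enum.Enum):
    """Terminal classification of one amplified sample (a partition)."""

    REFERENCE_QUALITY = "REFERENCE_QUALITY"
    FUNCTIONAL_LOW_QUALITY = "FUNCTIONAL_LOW_QUALITY"
    FAIL_UNUSABLE_CONTIG = "FAIL_UNUSABLE_CONTIG"
    FAIL_STOP_INDEL = "FAIL_STOP_INDEL"
    FAIL_CONTAMINATION = "FAIL_CONTAMINATION"

    @property
    def is_failure(self) -> bool:
        return self.name.startswith("FAIL_")

    @property
    def is_functional(self) -> bool:
        return not self.is_failure


class FailureCategory(enum.Enum):
    """The three sequencing/methodological failure categories."""

    UNUSABLE_CONTIG = "UNUSABLE_CONTIG"
    STOP_INDEL = "STOP_INDEL"
    CONTAMINATION = "CONTAMINATION"

    @property
    def status(self) -> Status:
        return {
            FailureCategory.UNUSABLE_CONTIG: Status.FAIL_UNUSABLE_CONTIG,
            FailureCategory.STOP_INDEL: Status.FAIL_STOP_INDEL,
            FailureCategory.CONTAMINATION: Status.FAIL_CONTAMINATION,
        }[self]


class Scope(enum.Enum):
    PRIMARY = "PRIMARY"
    GLOBAL = "GLOBAL"


# ---------------------------------------------------------------------------
# sequence helpers

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-"
)

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases) -> str:
    """Minimal IUPAC code covering a set of concrete bases."""
    s = frozenset().union(*(IUPAC_SETS[b] for b in bases))
    return _SET_TO_CODE[s]


def is_ambiguous(base: str) -> bool:
    return base not in "ACGT"


# ---------------------------------------------------------------------------
# core records


@dataclass(frozen=True)
class Specimen:
    """One earthworm individual; IDs follow the 'DE <n>' display style."""

    specimen_id: str
    morphospecies: str = "UNKNOWN"


SampleId = tuple[str, MethodLabel]


def sample_display(sample_id: SampleId) -> str:
    return f"{sample_id[0]} {sample_id[1].value}"


@dataclass
class TraceRead:
    """One directional Sanger read with per-base Phred qualities.

    Chromatogram-level evidence is approximated by the Phred values; the
    read therefore stands in for an .ab1 trace.
    """

    sample_id: SampleId
    direction: Direction
    bases: str
    quals: np.ndarray  # int array, same length as bases

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=int)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{sample_display(self.sample_id)} {self.direction.value}: "
                f"bases ({len(self.bases)}) and quals ({len(self.quals)}) differ in length"
            )
        if (self.quals < 0).any():
            raise ValueError("Phred qualities must be >= 0")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "TraceRead":
        return replace(self, bases=self.bases[start:stop], quals=self.quals[start:stop])


@dataclass(frozen=True)
class PrimerSet:
    forward: str
    reverse: str


#: Folmer primers; the standard pair for the animal COI barcode fragment.
DEFAULT_PRIMERS = PrimerSet(
    forward="GGTCAACAAATCATAAAGATATTGG",   # LCO1490
    reverse="TAAACTTCAGGGTGACCAAAAAATCA",  # HCO2198
)


@dataclass
class BarcodeRecord:
    """A curated consensus barcode with quality metrics and status flags.

    Quality-metric fields are populated iff a contig exists; a sample
    whose traces never assembled carries ``sequence=None``.
    """

    sample_id: SampleId
    sequence: Optional[str] = None
    quals: Optional[np.ndarray] = None
    bidir_mask: Optional[np.ndarray] = None  # bool, True where both strands covered
    status: Optional[Status] = None
    assigned_taxon: Optional[str] = None
    top_identity_pct: Optional[float] = None
    top_group: Optional[str] = None
    # per-position strand evidence retained for conflict Ns: pos -> (fwd, rev)
    conflicts: dict = field(default_factory=dict)
    corrected_positions: list = field(default_factory=list)

    # -- quality metrics -------------------------------------------------
    @property
    def length_bp(self) -> Optional[int]:
        return None if self.sequence is None else len(self.sequence)

    @property
    def pct_ambiguous(self) -> Optional[float]:
        if not self.sequence:
            return None
        n_amb = sum(1 for b in self.sequence if is_ambiguous(b))
        return 100.0 * n_amb / len(self.sequence)

    @property
    def pct_bidirectional_nonN(self) -> Optional[float]:
        """% of contig length covered by both strands, excluding ambiguous bases."""
        if not self.sequence or self.bidir_mask is None:
            return None
        covered = sum(
            1 for b, m in zip(self.sequence, self.bidir_mask) if m and not is_ambiguous(b)
        )
        return 100.0 * covered / len(self.sequence)

    def pct_contiguous_hq(self, hq_phred: int = 20) -> Optional[float]:
        """% of contig spanned by the longest run of bases with Phred > hq_phred."""
        if not self.sequence or self.quals is None:
            return None
        best = run = 0
        for q in self.quals:
            run = run + 1 if q > hq_phred else 0
            best = max(best, run)
        return 100.0 * best / len(self.sequence)

    def pct_hq_total(self, hq_phred: int = 20) -> Optional[float]:
        """% of bases above the high-quality threshold (fraction interpretation)."""
        if not self.sequence or self.quals is None:
            return None
        return 100.0 * float((self.quals > hq_phred).sum()) / len(self.sequence)

    @property
    def qs(self) -> Optional[float]:
        """Mean per-base quality of the final contig (all called positions)."""
        if self.quals is None or len(self.quals) == 0:
            return None
        return float(np.mean(self.quals))


# ---------------------------------------------------------------------------
# outcome bookkeeping


@dataclass
class OutcomeRow:
    specimen_id: str
    method: MethodLabel
    amplified: bool
    failure_category: Optional[FailureCategory] = None
    reference_quality: bool = False
    genetic_taxon: Optional[str] = None
    morphospecies: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.amplified and (
            self.failure_category is not None or self.reference_quality
        ):
            raise ValueError("non-amplified rows carry no downstream fields")
        if self.failure_category is not None and self.reference_quality:
            raise ValueError("a failed sample cannot be reference quality")

    @property
    def functional(self) -> bool:
        return self.amplified and self.failure_category is None


class OutcomeTable:
    """Per-(specimen, method) pipeline outcomes; the input to all rates."""

    def __init__(self, rows=()):
        self._rows: dict[SampleId, OutcomeRow] = {}
        for r in rows:
            self.add(r)

    def add(self, row: OutcomeRow) -> None:
        key = (row.specimen_id, row.method)
        if key in self._rows:
            raise ValueError(f"duplicate outcome row for {sample_display(key)}")
        self._rows[key] = row

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows.values())

    def __getitem__(self, key: SampleId) -> OutcomeRow:
        return self._rows[key]

    def __contains__(self, key: SampleId) -> bool:
        return key in self._rows

    def rows_for_method(self, method: MethodLabel) -> list[OutcomeRow]:
        return [r for r in self if r.method == method]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "specimen_id": r.specimen_id,
                "method": r.method.value,
                "amplified": r.amplified,
                "failure_category": r.failure_category.value if r.failure_category else None,
                "functional": r.functional,
                "reference_quality": r.reference_quality,
                "genetic_taxon": r.genetic_taxon,
                "morphospecies": r.morphospecies,
            }
            for r in self
        )


@dataclass
class DatasetView:
    """PRIMARY = functional barcodes only; GLOBAL adds earthworm-assigned
    stop/indel failures (unusable contigs and contamination stay excluded)."""

    scope: Scope
    records: list

    @classmethod
    def primary(cls, records) -> "DatasetView":
        return cls(Scope.PRIMARY, [r for r in records if r.status and r.status.is_functional])

    @classmethod
    def global_(cls, records) -> "DatasetView":
        kept = [
            r
            for r in records
            if r.status
            and (
                r.status.is_functional
                or (r.status is Status.FAIL_STOP_INDEL and r.top_group == "earthworm")
            )
        ]
        return cls(Scope.GLOBAL, kept)
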