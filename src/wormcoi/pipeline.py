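"""Top-level pipeline: traces -> curated barcodes -> rates and tree.

Per-sample stage order: primer trimming and quality end-clipping,
bidirectional consensus assembly, reading-frame QC (with strict-reclip
and reference-guided rescue of flagged sequences), homology-based
taxonomy/contamination screening, five-criterion quality
classification.  Study-level stages: tiered rates, concordance,
intra-specimen error table, identity summaries, and the NJ/bootstrap
clustering audit.  A stage error is recorded against its sample and
never aborts the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .assembly import ClipSpec, ConsensusPolicy, assemble_contig, quality_end_clip, trim_primers
from .core_model import (
    DEFAULT_PRIMERS,
    BarcodeRecord,
    DatasetView,
    Direction,
    FailureCategory,
    MethodLabel,
    OutcomeRow,
    OutcomeTable,
    PrimerSet,
    Status,
    sample_display,
)
from .frame_qc import (
    FrameUndeterminedError,
    default_reference_profile,
    detect_stops_indels,
    place_reading_frame,
    reference_guided_insertion_correct,
    strict_reclip_and_retry,
)
from .qc_metrics import (
    QualityCriteria,
    classify_quality,
    compute_concordance,
    compute_rates,
    sequencing_error_table,
)
from .taxonomy_screen import (
    ReferenceLibrary,
    assign_species,
    classify_contamination,
    default_reference_library,
    load_reference_library,
    summarize_identities,
    top_hit,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "process_sample"]


@dataclass
class PipelineConfig:
    # inputs: either an in-memory synthetic Study, or file paths
    study: Optional[object] = None
    fastq: Optional[object] = None
    metadata: Optional[object] = None
    reference_library: Optional[object] = None  # path; None -> packaged library
    primers: PrimerSet = DEFAULT_PRIMERS
    clip: ClipSpec = field(default_factory=ClipSpec)
    policy: ConsensusPolicy = field(default_factory=ConsensusPolicy)
    min_overlap: int = 50
    min_overlap_identity: float = 90.0
    criteria: QualityCriteria = field(default_factory=QualityCriteria)
    min_identity: float = 97.0           # species-assignment cutoff (%)
    contamination_min_identity: float = 80.0  # floor for calling a trace contaminated
    bootstrap_reps: int = 10000
    seed: int = 0
    out_dir: Optional[object] = None


@dataclass
class PipelineResult:
    outcomes: OutcomeTable
    records: list
    primary: DatasetView
    global_: DatasetView
    rates: object
    concordance: tuple
    error_table: object
    identity_summary: object
    tree: Optional[object]
    report: dict


def process_sample(
    reads: dict,
    config: PipelineConfig,
    library: ReferenceLibrary,
    profile: str,
):
    """Run one sample through assembly, frame QC and taxonomy.

    Returns (record_or_None, failure_category_or_None, hit_or_None).
    """
    trimmed = {
        d: trim_primers(r, config.primers) for d, r in reads.items()
    }
    clipped = {d: quality_end_clip(r, config.clip) for d, r in trimmed.items()}

    record = assemble_contig(
        clipped.get(Direction.FORWARD),
        clipped.get(Direction.REVERSE),
        config.policy,
        min_overlap=config.min_overlap,
        min_overlap_identity=config.min_overlap_identity,
    )

    if record is None or record.sequence is None or len(record.sequence) < 100:
        # no usable contig; screen the individual traces for contamination
        for read in clipped.values():
            if len(read) >= 100:
                hit = top_hit(read.bases, library)
                if (
                    classify_contamination(hit) == "NON_EARTHWORM"
                    and hit.identity_pct >= config.contamination_min_identity
                ):
                    return None, FailureCategory.CONTAMINATION, hit
        return None, FailureCategory.UNUSABLE_CONTIG, None

    # reading-frame QC with the two-stage rescue ladder
    try:
        report = place_reading_frame(record.sequence)
        flagged = detect_stops_indels(record.sequence, report, profile) == "FLAGGED"
    except FrameUndeterminedError:
        return None, FailureCategory.UNUSABLE_CONTIG, None
    if flagged:
        record = strict_reclip_and_retry(
            trimmed.get(Direction.FORWARD), trimmed.get(Direction.REVERSE),
            record, config.clip, config.policy, profile,
        )
        report = place_reading_frame(record.sequence)
        flagged = detect_stops_indels(record.sequence, report, profile) == "FLAGGED"
    if flagged:
        record, report = reference_guided_insertion_correct(record, profile)
        flagged = detect_stops_indels(record.sequence, report, profile) == "FLAGGED"

    hit = top_hit(record.sequence, library)
    record.top_identity_pct = hit.identity_pct
    record.top_group = hit.group
    record.assigned_taxon = hit.taxon
    if classify_contamination(hit) == "NON_EARTHWORM":
        record.status = Status.FAIL_CONTAMINATION
        return record, FailureCategory.CONTAMINATION, hit
    if flagged:
        record.status = Status.FAIL_STOP_INDEL
        return record, FailureCategory.STOP_INDEL, hit

    record.status = classify_quality(record, config.criteria)
    return record, None, hit


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    from . import io as wio

    if config.study is not None:
        metadata = config.study.metadata
        samples: dict = {}
        for r in config.study.reads:
            samples.setdefault(r.sample_id, {})[r.direction] = r
    else:
        metadata = wio.read_metadata(config.metadata)
        samples = wio.read_trace_pairs(config.fastq, metadata)

    library = (
        load_reference_library(config.reference_library)
        if config.reference_library is not None
        else default_reference_library()
    )
    profile = default_reference_profile()

    morpho = {
        str(row.specimen_id): str(row.morphospecies) for row in metadata.itertuples()
    }

    outcomes = OutcomeTable()
    records: list[BarcodeRecord] = []
    for row in metadata.itertuples():
        specimen = str(row.specimen_id)
        method = MethodLabel.from_token(str(row.method))
        sid = (specimen, method)
        if not bool(row.amplified):
            outcomes.add(OutcomeRow(specimen, method, amplified=False,
                                    morphospecies=morpho.get(specimen)))
            continue
        reads = samples.get(sid, {})
        try:
            record, category, hit = process_sample(reads, config, library, profile)
        except Exception:
            log.exception("stage error for %s; recorded as unusable", sample_display(sid))
            record, category, hit = None, FailureCategory.UNUSABLE_CONTIG, None
        if record is None:
            record = BarcodeRecord(sample_id=sid)
            record.status = (category or FailureCategory.UNUSABLE_CONTIG).status
            if hit is not None:
                record.assigned_taxon = hit.taxon
                record.top_identity_pct = hit.identity_pct
                record.top_group = hit.group
        records.append(record)
        outcomes.add(
            OutcomeRow(
                specimen, method, amplified=True,
                failure_category=category,
                reference_quality=record.status is Status.REFERENCE_QUALITY,
                genetic_taxon=record.assigned_taxon,
                morphospecies=morpho.get(specimen),
            )
        )

    primary = DatasetView.primary(records)
    global_ = DatasetView.global_(records)
    rates = compute_rates(outcomes)
    concordance = compute_concordance(outcomes)
    error_table = sequencing_error_table(primary)
    identity_summary = summarize_identities(primary.records)

    tree = None
    if len(primary.records) >= 4:
        from .cluster_tree import audit_clustering, bootstrap, build_msa, nj_tree

        labels = [sample_display(r.sample_id) for r in primary.records]
        aln = build_msa([r.sequence for r in primary.records], labels)
        tree = nj_tree(aln)
        if config.bootstrap_reps > 0:
            tree = bootstrap(aln, reps=config.bootstrap_reps, seed=config.seed, tree=tree)
        audit_clustering(tree)

    sample_rows = {
        sample_display(r.sample_id): {
            "status": r.status.value if r.status else None,
            "assigned_taxon": r.assigned_taxon,
            "top_identity_pct": r.top_identity_pct,
            "length_bp": r.length_bp,
            "pct_ambiguous": r.pct_ambiguous,
            "qs": r.qs,
        }
        for r in records
    }
    sample_level, barcode_level, per_method = concordance
    report = {
        "seed": config.seed,
        "bootstrap_reps": config.bootstrap_reps,
        "rates": rates.as_dict(),
        "concordance": {
            "sample_level": sample_level.as_dict(),
            "barcode_level": barcode_level.as_dict(),
            "per_method": {m.value: r.as_dict() for m, r in per_method.items()},
        },
        "sequencing_error": error_table.to_dict(orient="records"),
        "identity_summary": identity_summary.to_dict(orient="records"),
        "samples": sample_rows,
        "tree": {
            "newick": tree.newick() if tree else None,
            "audit": tree.audit if tree else None,
        },
    }

    result = PipelineResult(
        outcomes=outcomes, records=records, primary=primary, global_=global_,
        rates=rates, concordance=concordance, error_table=error_table,
        identity_summary=identity_summary, tree=tree, report=report,
    )
    if config.out_dir is not None:
        wio.write_outputs(result, config.out_dir)
    return result
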