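"""File I/O: FASTQ trace reads, metadata TSV, and pipeline outputs."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core_model import Direction, MethodLabel, TraceRead

log = logging.getLogger(__name__)

__all__ = ["read_trace_pairs", "read_metadata", "write_outputs"]


def _parse_read_name(name: str):
    try:
        specimen, token, direction = name.rsplit("_", 2)
        return specimen, MethodLabel.from_token(token), Direction(direction)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"cannot parse FASTQ record name {name!r}: "
                         "expected <specimen>_<method>_<F|R>") from exc


def read_trace_pairs(fastq_paths, metadata: pd.DataFrame | None = None):
    """Read Phred+33 FASTQ trace files into per-sample read pairs.

    Records are named ``<specimen>_<method>_<F|R>``.  Returns a dict
    mapping (specimen_id, MethodLabel) to {Direction: TraceRead}.  A
    sample may legally hold a single orphan direction (flagged with a
    warning); more than one read per direction is an error.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    samples: dict = {}
    n = 0
    for path in fastq_paths:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            specimen, method, direction = _parse_read_name(rec.id)
            read = TraceRead(
                sample_id=(specimen, method),
                direction=direction,
                bases=str(rec.seq).upper(),
                quals=np.array(rec.letter_annotations["phred_quality"], dtype=int),
            )
            slot = samples.setdefault(read.sample_id, {})
            if direction in slot:
                raise ValueError(f"duplicate {direction.value} read for {rec.id}")
            slot[direction] = read
    if n == 0:
        log.warning("no FASTQ records found in %s", fastq_paths)
    if metadata is not None:
        known = {(r.specimen_id, MethodLabel.from_token(r.method)) for r in metadata.itertuples()}
        unknown = set(samples) - known
        if unknown:
            raise ValueError(f"reads without metadata rows: {sorted(str(u) for u in unknown)[:5]}")
    for sid, slot in samples.items():
        if len(slot) == 1:
            log.warning("orphan single-direction sample %s", sid)
    return samples


def read_metadata(path) -> pd.DataFrame:
    """Metadata TSV: specimen_id, morphospecies, method, amplified."""
    df = pd.read_csv(path, sep="\t", dtype={"specimen_id": str})
    required = {"specimen_id", "morphospecies", "method", "amplified"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    for token in df["method"]:
        MethodLabel.from_token(token)  # raises on unknown token
    return df


def write_outputs(result, out_dir) -> dict[str, Path]:
    """Write pipeline outputs: barcode FASTA, outcome TSV, newick trees
    and the JSON report.  The JSON report round-trips: reading it back
    yields the in-memory report values."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "barcodes.fasta"
    with fasta.open("w") as fh:
        for rec in result.records:
            if rec.sequence:
                fh.write(f">{rec.sample_id[0]} {rec.sample_id[1].value} {rec.status.value}\n")
                for i in range(0, len(rec.sequence), 70):
                    fh.write(rec.sequence[i : i + 70] + "\n")
    paths["barcodes"] = fasta

    outcomes = out / "outcomes.tsv"
    result.outcomes.to_frame().to_csv(outcomes, sep="\t", index=False)
    paths["outcomes"] = outcomes

    if result.tree is not None:
        nwk = out / "tree.nwk"
        nwk.write_text(result.tree.newick() + "\n")
        paths["tree"] = nwk
        from .cluster_tree import midpoint_newick

        display = out / "tree_midpoint.nwk"
        # display convention: only supports above 50 are shown
        display.write_text(midpoint_newick(result.tree.newick(min_support=50)) + "\n")
        paths["tree_display"] = display

    report = out / "report.json"
    report.write_text(json.dumps(result.report, indent=1, sort_keys=True))
    paths["report"] = report
    return paths
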