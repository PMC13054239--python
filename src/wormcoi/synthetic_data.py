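"""Synthetic Sanger study generator.

Emulates the statistical structure of a three-method COI barcoding
study: every specimen carries one ~658 bp Folmer-region haplotype shared
across its three collection-method samples; each sample is sequenced
bidirectionally with Sanger-style end-of-read quality decay; and each
method has its own probabilities of amplification failure, unusable
assembly, frameshift artifacts and non-earthworm contamination.  The
default event probabilities are the per-method failure frequencies
observed in the motivating three-method comparison (e.g. swab samples:
1/40 amplification failures, 2/39 unusable contigs, 4/39 stop/indel
failures, 7/39 contaminated).

Every generated sample is logged in a ground-truth manifest so that
pipeline classifications can be audited against the injected events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core_model import (
    DEFAULT_PRIMERS,
    Direction,
    MethodLabel,
    PrimerSet,
    TraceRead,
    revcomp,
)
from .frame_qc import COI5P_FRAME_OFFSET, STOP_CODONS

__all__ = [
    "QualityProfile",
    "EventProbs",
    "SampleEvents",
    "SimulationConfig",
    "Study",
    "generate_haplotype",
    "mutate_coding",
    "inject_substitutions",
    "simulate_trace_pair",
    "generate_study",
    "load_packaged_library",
    "default_method_probs",
]

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class QualityProfile:
    """Per-read Phred profile: a plateau with linear decay at both ends.

    Defaults mimic Sanger end degradation: the first 20 and last 120
    bases ramp down to a floor of Q=8, with a Q=40 plateau between.
    """

    plateau: int = 40
    ramp_5p: int = 20
    ramp_3p: int = 120
    floor: int = 8

    @classmethod
    def flat(cls, q: int) -> "QualityProfile":
        return cls(plateau=q, ramp_5p=0, ramp_3p=0, floor=q)

    def quals(self, length: int) -> np.ndarray:
        q = np.full(length, self.plateau, dtype=float)
        r5 = min(self.ramp_5p, length)
        if r5 > 0:
            q[:r5] = np.linspace(self.floor, self.plateau, r5, endpoint=False)
        r3 = min(self.ramp_3p, length)
        if r3 > 0:
            q[length - r3 :] = np.linspace(self.plateau, self.floor, r3)
        return np.round(q).astype(int)


@dataclass(frozen=True)
class EventProbs:
    """Per-method event probabilities.  ``p_amp_fail`` is unconditional;
    the remaining three are conditional on successful amplification and
    mutually exclusive."""

    p_amp_fail: float = 0.0
    p_assembly_fail: float = 0.0
    p_frameshift: float = 0.0
    p_contamination: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_amp_fail, self.p_assembly_fail, self.p_frameshift, self.p_contamination):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.p_assembly_fail + self.p_frameshift + self.p_contamination > 1.0:
            raise ValueError("conditional event probabilities exceed 1")


def default_method_probs() -> dict[MethodLabel, EventProbs]:
    """Observed per-method failure frequencies of the motivating study."""
    return {
        MethodLabel.TISSUE_CHELEX: EventProbs(0.0, 0.0, 4 / 40, 3 / 40),
        MethodLabel.TISSUE_QIAGEN: EventProbs(0.0, 1 / 40, 1 / 40, 3 / 40),
        MethodLabel.SWAB_QIAGEN: EventProbs(1 / 40, 2 / 39, 4 / 39, 7 / 39),
    }


@dataclass
class SampleEvents:
    """Injected events for one (specimen, method) sample."""

    kind: str = "clean"  # clean | frameshift | contamination | assembly_fail
    insertion_pos: Optional[int] = None
    insertion_quality: Optional[int] = None
    contaminant: Optional[str] = None


@dataclass
class SimulationConfig:
    n_specimens: int = 40
    #: list of (taxon, sequence); None -> packaged synthetic earthworm library
    species_pool: Optional[list] = None
    method_probs: dict = field(default_factory=default_method_probs)
    quality: QualityProfile = field(default_factory=QualityProfile)
    #: list of (taxon, weight); None -> packaged non-earthworm entries, equal weight
    contamination_spectrum: Optional[list] = None
    read_length: int = 620
    intraspecific_divergence: float = 0.005
    #: quality given to injected frameshift bases; >= 20 makes them
    #: unrescuable (persistent stop/indel failures)
    insertion_quality: int = 45
    p_misidentification: float = 0.0
    primers: PrimerSet = DEFAULT_PRIMERS
    seed: int = 0


# ---------------------------------------------------------------------------
# sequence-level generators


def _stop_free(seq: list[str], frame_offset: int, pos: int) -> bool:
    """Codon containing `pos` (in the given frame) is not a stop."""
    start = pos - (pos - frame_offset) % 3
    if start < 0 or start + 3 > len(seq):
        return True
    return "".join(seq[start : start + 3]) not in STOP_CODONS


def generate_haplotype(
    rng_or_seed, length: int = 658, frame_offset: int = COI5P_FRAME_OFFSET
) -> str:
    """Random coding-like DNA with no in-frame stop codon (invertebrate
    mitochondrial code), standing in for a Folmer-region haplotype."""
    rng = np.random.default_rng(rng_or_seed) if isinstance(rng_or_seed, (int, np.integer)) else rng_or_seed
    seq = [ _BASES[i] for i in rng.integers(0, 4, size=length) ]
    for start in range(frame_offset, length - 2, 3):
        while "".join(seq[start : start + 3]) in STOP_CODONS:
            seq[start + 2] = _BASES[rng.integers(0, 4)]
    return "".join(seq)


def mutate_coding(
    seq: str, rate: float, rng, frame_offset: int = COI5P_FRAME_OFFSET
) -> str:
    """Apply iid substitutions at `rate`, never creating an in-frame stop."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for pos in hits:
        old = out[pos]
        choices = [b for b in _BASES if b != old]
        rng.shuffle(choices)
        for b in choices:
            out[pos] = b
            if _stop_free(out, frame_offset, pos):
                break
        else:
            out[pos] = old
    return "".join(out)


def inject_substitutions(seq: str, rate: float, rng) -> str:
    """Unconstrained iid substitutions (sequencing-error style)."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for pos in hits:
        out[pos] = _BASES[(_BASES.index(out[pos]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def load_packaged_library() -> list[tuple[str, str, str]]:
    """Packaged synthetic reference library as (taxon, group, sequence)."""
    path = resources.files("wormcoi.data") / "synthetic_reference_library.fasta"
    entries = []
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            fields = rec.description.split("|")
            taxon = fields[1]
            group = fields[2].split("=", 1)[1]
            entries.append((taxon, group, str(rec.seq).upper()))
    return entries


# ---------------------------------------------------------------------------
# trace simulation


def _apply_phred_errors(bases: list[str], quals: np.ndarray, rng) -> None:
    p_err = np.power(10.0, -quals / 10.0)
    hits = np.flatnonzero(rng.random(len(bases)) < p_err)
    for pos in hits:
        bases[pos] = _BASES[(_BASES.index(bases[pos]) + rng.integers(1, 4)) % 4]


def simulate_trace_pair(
    haplotype: str,
    profile: QualityProfile,
    events: SampleEvents,
    rng,
    sample_id=("SIM", MethodLabel.TISSUE_CHELEX),
    primers: PrimerSet = DEFAULT_PRIMERS,
    read_length: int = 620,
) -> tuple[TraceRead, TraceRead]:
    """Simulate one bidirectional Sanger read pair from a template.

    The forward read covers the 5' portion and the reverse read the 3'
    portion (as its reverse complement); sequencing primers are
    prepended so that primer trimming is exercised; per-base substitution
    errors follow Phred semantics (p = 10^(-Q/10)).
    """
    template = haplotype
    ins_template_pos = None
    if events.kind == "frameshift":
        ins_template_pos = events.insertion_pos
        if ins_template_pos is None:
            ins_template_pos = int(rng.integers(int(0.15 * len(template)), int(0.85 * len(template))))
            events.insertion_pos = ins_template_pos
        ins_base = _BASES[rng.integers(0, 4)]
        template = template[:ins_template_pos] + ins_base + template[ins_template_pos:]

    L = len(template)
    cov = min(read_length, L)
    fwd_span = (0, cov)
    rev_span = (L - cov, L)

    reads = []
    for direction, span, primer in (
        (Direction.FORWARD, fwd_span, primers.forward),
        (Direction.REVERSE, rev_span, primers.reverse),
    ):
        insert = template[span[0] : span[1]]
        if direction is Direction.REVERSE:
            insert = revcomp(insert)
        bases = list(primer + insert)
        quals = profile.quals(len(bases)).copy()
        if ins_template_pos is not None and span[0] <= ins_template_pos < span[1]:
            iq = events.insertion_quality if events.insertion_quality is not None else 45
            if direction is Direction.FORWARD:
                rpos = len(primer) + (ins_template_pos - span[0])
            else:
                rpos = len(primer) + (span[1] - 1 - ins_template_pos)
            quals[rpos] = iq
        if events.kind == "assembly_fail" and direction is Direction.REVERSE:
            # degraded trace: clips to nothing, contig cannot form
            quals[:] = 3
        _apply_phred_errors(bases, quals, rng)
        reads.append(TraceRead(sample_id=sample_id, direction=direction,
                               bases="".join(bases), quals=quals))
    return reads[0], reads[1]


# ---------------------------------------------------------------------------
# study-level generation


@dataclass
class Study:
    """In-memory synthetic study plus its ground-truth manifest."""

    reads: list
    metadata: pd.DataFrame
    manifest: dict
    config: SimulationConfig

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fq = out / "reads.fastq"
        with fq.open("w") as fh:
            for r in self.reads:
                name = f"{r.sample_id[0]}_{r.sample_id[1].token}_{r.direction.value}"
                qline = "".join(chr(min(int(q), 93) + 33) for q in r.quals)
                fh.write(f"@{name}\n{r.bases}\n+\n{qline}\n")
        meta = out / "metadata.tsv"
        self.metadata.to_csv(meta, sep="\t", index=False)
        man = out / "manifest.json"
        man.write_text(json.dumps(self.manifest, indent=1))
        return {"fastq": fq, "metadata": meta, "manifest": man}


def _expected_status(events: SampleEvents, rescue_threshold: int = 20) -> Optional[str]:
    if events.kind == "contamination":
        return "FAIL_CONTAMINATION"
    if events.kind == "assembly_fail":
        return "FAIL_UNUSABLE_CONTIG"
    if events.kind == "frameshift":
        iq = events.insertion_quality if events.insertion_quality is not None else 45
        return "FAIL_STOP_INDEL" if iq >= rescue_threshold else "REFERENCE_QUALITY"
    return "REFERENCE_QUALITY"


def generate_study(config: SimulationConfig) -> Study:
    """Generate a full study: reads, metadata table and truth manifest.

    Every specimen's three method samples share one haplotype, drawn
    from a species seed with configurable intraspecific divergence.
    Amplification failures emit no reads and are marked in the metadata.
    """
    rng = np.random.default_rng(config.seed)

    if config.species_pool is not None:
        pool = [(t, s) for t, s in config.species_pool]
    else:
        pool = [(t, s) for t, g, s in load_packaged_library() if g == "earthworm"]
    contaminants = {t: s for t, g, s in load_packaged_library() if g == "other"}
    if config.contamination_spectrum is not None:
        spectrum = config.contamination_spectrum
    else:
        spectrum = [(t, 1.0) for t in contaminants]
    spec_taxa = [t for t, _ in spectrum]
    w = np.array([float(x) for _, x in spectrum])
    spec_weights = w / w.sum()

    reads: list[TraceRead] = []
    meta_rows = []
    manifest: dict[str, dict] = {}

    for i in range(1, config.n_specimens + 1):
        specimen_id = f"DE{i}"
        taxon, seed_seq = pool[int(rng.integers(len(pool)))]
        haplotype = mutate_coding(seed_seq, config.intraspecific_divergence, rng)
        morpho = taxon
        if config.p_misidentification > 0 and rng.random() < config.p_misidentification:
            others = [t for t, _ in pool if t != taxon]
            morpho = others[int(rng.integers(len(others)))]

        for method in MethodLabel:
            probs = config.method_probs.get(method, EventProbs())
            sample_id = (specimen_id, method)
            key = f"{specimen_id}_{method.token}"
            if rng.random() < probs.p_amp_fail:
                meta_rows.append((specimen_id, morpho, method.token, False))
                manifest[key] = {
                    "specimen": specimen_id, "method": method.value,
                    "true_taxon": taxon, "morphospecies": morpho,
                    "event": "amp_fail", "expected_status": None,
                    "amplified": False,
                }
                continue

            r = rng.random()
            if r < probs.p_contamination:
                ct = spec_taxa[int(rng.choice(len(spec_taxa), p=spec_weights))]
                events = SampleEvents(kind="contamination", contaminant=ct)
                template = inject_substitutions(contaminants[ct], 0.01, rng)
            elif r < probs.p_contamination + probs.p_assembly_fail:
                events = SampleEvents(kind="assembly_fail")
                template = haplotype
            elif r < probs.p_contamination + probs.p_assembly_fail + probs.p_frameshift:
                events = SampleEvents(kind="frameshift", insertion_quality=config.insertion_quality)
                template = haplotype
            else:
                events = SampleEvents()
                template = haplotype

            fwd, rev = simulate_trace_pair(
                template, config.quality, events, rng,
                sample_id=sample_id, primers=config.primers,
                read_length=config.read_length,
            )
            reads.extend([fwd, rev])
            meta_rows.append((specimen_id, morpho, method.token, True))
            manifest[key] = {
                "specimen": specimen_id, "method": method.value,
                "true_taxon": events.contaminant or taxon,
                "morphospecies": morpho,
                "event": events.kind,
                "expected_status": _expected_status(events),
                "amplified": True,
                "insertion_pos": events.insertion_pos,
            }

    metadata = pd.DataFrame(
        meta_rows, columns=["specimen_id", "morphospecies", "method", "amplified"]
    )
    return Study(reads=reads, metadata=metadata, manifest=manifest, config=config)
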