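"""Shared fixtures: the published-count outcome fixture and small studies."""

from __future__ import annotations

import numpy as np
import pytest

from wormcoi.core_model import FailureCategory, MethodLabel, OutcomeRow, OutcomeTable
from wormcoi.frame_qc import default_reference_profile
from wormcoi.synthetic_data import (
    EventProbs,
    QualityProfile,
    SimulationConfig,
    generate_study,
)
from wormcoi.taxonomy_screen import default_reference_library

TC, TQ, SQ = MethodLabel.TISSUE_CHELEX, MethodLabel.TISSUE_QIAGEN, MethodLabel.SWAB_QIAGEN


@pytest.fixture(scope="session")
def reference_library():
    return default_reference_library()


@pytest.fixture(scope="session")
def reference_profile():
    return default_reference_profile()


def build_study_outcomes() -> OutcomeTable:
    """Outcome fixture reproducing the three-method study's bookkeeping.

    40 specimens x 3 methods; one swab sample failed to amplify.  Failure
    counts per method (unusable contig / stop-indel / contamination):
    tissue-Chelex 0/4/3, tissue-QIAGEN 1/1/3, swab-QIAGEN 2/4/7, leaving
    33 + 35 + 26 = 94 functional barcodes over 37 specimens.  Reference
    quality flags: 25, 24 and 21 per method.  Three specimens (all three
    barcodes each) are genetically discordant with their morphospecies.

    Specimen group structure (chosen to satisfy the per-method counts):
    22 specimens functional in all three methods, 9 in both tissue
    methods only, 4 in tissue-QIAGEN + swab, 2 in tissue-Chelex only,
    and 3 complete failures.
    """
    groups: dict[str, set] = {}
    spec_ids = [f"DE{i}" for i in range(1, 41)]
    for s in spec_ids[:22]:
        groups[s] = {TC, TQ, SQ}
    for s in spec_ids[22:31]:
        groups[s] = {TC, TQ}
    for s in spec_ids[31:35]:
        groups[s] = {TQ, SQ}
    for s in spec_ids[35:37]:
        groups[s] = {TC}
    for s in spec_ids[37:40]:
        groups[s] = set()  # complete sequencing/methodological failures

    discordant = {"DE9", "DE20", "DE21"}  # three specimens, three barcodes each

    # failure categories to hand out per method, matching the study's counts
    fail_pool = {
        TC: [FailureCategory.STOP_INDEL] * 4 + [FailureCategory.CONTAMINATION] * 3,
        TQ: [FailureCategory.UNUSABLE_CONTIG]
        + [FailureCategory.STOP_INDEL]
        + [FailureCategory.CONTAMINATION] * 3,
        SQ: [FailureCategory.UNUSABLE_CONTIG] * 2
        + [FailureCategory.STOP_INDEL] * 4
        + [FailureCategory.CONTAMINATION] * 7,
    }
    refq_quota = {TC: 25, TQ: 24, SQ: 21}
    unamplified_sq = "DE40"  # the one swab amplification failure

    table = OutcomeTable()
    for s in spec_ids:
        for m in (TC, TQ, SQ):
            morpho = "Aporrectodea caliginosa"
            if m is SQ and s == unamplified_sq:
                table.add(OutcomeRow(s, m, amplified=False, morphospecies=morpho))
                continue
            if m in groups[s]:
                refq = refq_quota[m] > 0
                refq_quota[m] -= 1
                genetic = (
                    "Octolasion lacteum" if s in discordant else "Aporrectodea caliginosa"
                )
                table.add(
                    OutcomeRow(
                        s, m, amplified=True, reference_quality=refq,
                        genetic_taxon=genetic, morphospecies=morpho,
                    )
                )
            else:
                table.add(
                    OutcomeRow(
                        s, m, amplified=True,
                        failure_category=fail_pool[m].pop(),
                        morphospecies=morpho,
                    )
                )
    assert all(not v for v in fail_pool.values())
    return table


@pytest.fixture(scope="session")
def study_outcomes() -> OutcomeTable:
    return build_study_outcomes()


def noiseless_config(n_specimens: int, seed: int) -> SimulationConfig:
    """Flat Q=60, no events: the zero-noise identity world."""
    return SimulationConfig(
        n_specimens=n_specimens,
        seed=seed,
        quality=QualityProfile.flat(60),
        method_probs={m: EventProbs() for m in MethodLabel},
    )


@pytest.fixture(scope="session")
def small_clean_study():
    return generate_study(noiseless_config(6, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
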