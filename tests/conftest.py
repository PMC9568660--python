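"""Shared fixtures: handcrafted records and small simulated cohorts."""

from __future__ import annotations

import pytest

from kirassoc import KirTypingRecord, default_config, sample_cohort
from kirassoc.loci import A_CONTENT_GENES, FRAMEWORK_GENES, KIR_MARKERS


def make_record(present=(), sample_id="S1", group="control", ds4_variant=None, **kwargs):
    """Record with frameworks + ``present`` genes present, everything else absent."""
    genes = set(present) | FRAMEWORK_GENES
    presence = {m: m in genes for m in KIR_MARKERS}
    presence.update(kwargs.get("overrides", {}))
    if ds4_variant is None:
        ds4_variant = "del" if presence["2DS4"] else "negative"
    return KirTypingRecord(
        sample_id=sample_id, group=group, presence=presence, ds4_variant=ds4_variant
    )


@pytest.fixture
def aa_record():
    """The fixed A-haplotype gene content (2DL3-2DL1-2DP1-3DL1-2DS4)."""
    return make_record(A_CONTENT_GENES)


@pytest.fixture
def all_genes_record():
    return make_record(KIR_MARKERS)


@pytest.fixture(scope="session")
def sim_cohort():
    """One default-parameter cohort (232 cases / 448 controls, seed 7)."""
    return sample_cohort(default_config(seed=7))


@pytest.fixture(scope="session")
def sim_cohort_missing():
    """A cohort with 10% per-marker missingness to exercise typed subsets."""
    import dataclasses

    cfg = dataclasses.replace(default_config(seed=11), missing_rate=0.10,
                              n_cases=60, n_controls=90)
    return sample_cohort(cfg)
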