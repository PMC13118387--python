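import numpy as np
import pytest

from biomeshare.profiles_io import CountTable, SampleMeta
from biomeshare.sharing import SubjectSharingRecord
from biomeshare.synthetic import CohortParams, generate_cohort

# Canonical published sharing combinations used across the acceptance
# surface: per-case shared sets (with 7 subjects sharing nothing) and the
# control-group counts for the same four taxa.
SO = "Streptococcus oralis"
SM = "Streptococcus mitis"
PH = "Prevotella histicola"
GS = "Gemella sanguinis"

CASE_COMBOS = (
    [{SO}] * 2
    + [{PH}] * 1
    + [{SM}] * 2
    + [{SO, SM}] * 2
    + [{SM, PH}] * 2
    + [{GS, SO, SM}] * 2
    + [{GS, PH, SO, SM}] * 2
    + [set()] * 7
)

# control subjects: SO shared by 2, SM by 6, PH by 1
CONTROL_COMBOS = [
    {SO, SM}, {SO, SM}, {SM}, {SM}, {SM}, {SM}, {PH},
] + [set()] * 13


def sharing_fixture_records() -> list[SubjectSharingRecord]:
    records = [
        SubjectSharingRecord(f"CA{i:02d}", "case", frozenset(taxa))
        for i, taxa in enumerate(CASE_COMBOS, 1)
    ]
    records += [
        SubjectSharingRecord(f"CO{i:02d}", "control", frozenset(taxa))
        for i, taxa in enumerate(CONTROL_COMBOS, 1)
    ]
    return records


@pytest.fixture
def table4_records():
    return sharing_fixture_records()


@pytest.fixture
def tiny_table():
    return CountTable(
        taxa=["Genus1 sp1", "Genus2 sp2"],
        samples=["S1", "S2"],
        counts=np.array([[3, 0], [1, 2]]),
    )


@pytest.fixture
def tiny_metadata():
    return [
        SampleMeta("A-SAL", "A", "saliva", "case"),
        SampleMeta("A-BIO", "A", "biopsy", "case"),
        SampleMeta("B-SAL", "B", "saliva", "control"),
        SampleMeta("B-BIO", "B", "biopsy", "control"),
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort, generated once per session."""
    params = CohortParams(seed=42)
    return params, generate_cohort(params)
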