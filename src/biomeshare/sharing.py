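"""Per-subject oral-to-gastric shared-taxa detection and group-level
sharing summaries.

A taxon is "shared" by a subject when it is detected (count >= a presence
threshold, default 1 classified read) in BOTH the subject's saliva sample
and their gastric biopsy. Group summaries count, for each taxon, how many
subjects of each group share it, report percentages over group size,
absolute and relative case-control differences, and flag taxa shared
exclusively in one group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .profiles_io import CountTable, SubjectPair

ONLY_CASE = "only-case"
ONLY_CONTROL = "only-control"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class SubjectSharingRecord:
    """Shared-taxa set of one subject, with its cardinality ``k``."""

    subject_id: str
    group: str
    shared_taxa: frozenset[str]

    @property
    def k(self) -> int:
        return len(self.shared_taxa)


@dataclass(frozen=True)
class SharingSummaryRow:
    """One taxon's group-level sharing summary.

    ``rel_diff`` is 100 * (case% - control%) / case% and is defined only
    when the case share is positive; otherwise ``flag`` explains why.
    ``flag`` is one of "", "only-case", "only-control", "undefined".
    """

    taxon: str
    shared_count_case: int
    shared_pct_case: float
    shared_count_control: int
    shared_pct_control: float
    pct_diff: float
    rel_diff: float | None
    flag: str


def presence_set(
    sample_counts, taxa: Sequence[str], threshold: int = 1
) -> frozenset[str]:
    """Taxa detected at >= ``threshold`` classified reads in one sample."""
    if threshold < 1:
        raise ValueError("presence threshold must be >= 1 read")
    counts = np.asarray(sample_counts)
    if counts.size != len(taxa):
        raise ValueError("counts and taxa must have equal length")
    return frozenset(t for t, c in zip(taxa, counts) if c >= threshold)


def shared_taxa(
    pair: SubjectPair, table: CountTable, threshold: int = 1
) -> SubjectSharingRecord:
    """Intersection of a subject's saliva and biopsy presence sets."""
    saliva = presence_set(table.column(pair.saliva_sample), table.taxa, threshold)
    biopsy = presence_set(table.column(pair.biopsy_sample), table.taxa, threshold)
    return SubjectSharingRecord(
        subject_id=pair.subject_id,
        group=pair.group,
        shared_taxa=saliva & biopsy,
    )


def shared_taxa_records(
    pairs: Iterable[SubjectPair], table: CountTable, threshold: int = 1
) -> list[SubjectSharingRecord]:
    return [shared_taxa(p, table, threshold) for p in pairs]


def sharing_summary(
    records: Iterable[SubjectSharingRecord],
    group_sizes: Mapping[str, int],
) -> list[SharingSummaryRow]:
    """Per-taxon sharing counts and percentages by group.

    ``group_sizes`` maps "case" and "control" to the number of subjects
    analyzed per group (percentage denominators). Rows are sorted by
    absolute percentage difference descending, ties broken by case count
    descending then taxon label.
    """
    n_case = group_sizes.get("case", 0)
    n_control = group_sizes.get("control", 0)
    if n_case <= 0 or n_control <= 0:
        raise ValueError("both group sizes must be positive")
    case_counts: Counter[str] = Counter()
    control_counts: Counter[str] = Counter()
    for rec in records:
        target = case_counts if rec.group == "case" else control_counts
        target.update(rec.shared_taxa)
    rows = []
    for taxon in sorted(set(case_counts) | set(control_counts)):
        ca, co = case_counts[taxon], control_counts[taxon]
        pct_ca = 100.0 * ca / n_case
        pct_co = 100.0 * co / n_control
        if ca > 0 and co > 0:
            rel, flag = 100.0 * (pct_ca - pct_co) / pct_ca, ""
        elif ca > 0:
            rel, flag = None, ONLY_CASE
        elif co > 0:
            rel, flag = None, ONLY_CONTROL
        else:
            rel, flag = None, UNDEFINED
        rows.append(
            SharingSummaryRow(
                taxon=taxon,
                shared_count_case=ca,
                shared_pct_case=pct_ca,
                shared_count_control=co,
                shared_pct_control=pct_co,
                pct_diff=pct_ca - pct_co,
                rel_diff=rel,
                flag=flag,
            )
        )
    rows.sort(key=lambda r: (-r.pct_diff, -r.shared_count_case, r.taxon))
    return rows


def sharing_distribution(
    records: Iterable[SubjectSharingRecord], group: str
) -> dict[int, tuple[int, float]]:
    """Histogram of shared-taxa counts k for one group.

    Returns ``{k: (n_subjects, pct_of_group)}`` for k = 0 .. max observed;
    the counts always sum to the group size.
    """
    ks = [rec.k for rec in records if rec.group == group]
    total = len(ks)
    if total == 0:
        return {}
    hist = Counter(ks)
    return {
        k: (hist[k], 100.0 * hist[k] / total)
        for k in range(max(hist) + 1)
    }


def exclusive_taxa(
    summary: Iterable[SharingSummaryRow],
) -> tuple[set[str], set[str]]:
    """Taxa shared in one group only: ``(case_only, control_only)``."""
    case_only = {r.taxon for r in summary if r.flag == ONLY_CASE}
    control_only = {r.taxon for r in summary if r.flag == ONLY_CONTROL}
    return case_only, control_only


def co_sharing_patterns(
    records: Iterable[SubjectSharingRecord],
) -> dict[str, tuple[bool, Counter[str]]]:
    """Per-taxon co-occurrence within shared sets.

    Maps each taxon appearing in at least one shared set to
    ``(never_shared_alone, partners)`` where ``never_shared_alone`` is
    True when every record containing the taxon has k >= 2, and
    ``partners`` is the multiset of taxa it was co-shared with.
    """
    never_alone: dict[str, bool] = {}
    partners: dict[str, Counter[str]] = {}
    for rec in records:
        for taxon in rec.shared_taxa:
            partners.setdefault(taxon, Counter()).update(rec.shared_taxa - {taxon})
            if rec.k < 2:
                never_alone[taxon] = False
            else:
                never_alone.setdefault(taxon, True)
    return {t: (never_alone[t], partners[t]) for t in sorted(partners)}
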