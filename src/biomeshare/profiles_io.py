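"""Reading, validation and writing of taxa-by-sample count tables and
sample metadata, and construction of per-subject saliva/biopsy pairs.

The count-table format is plain TSV (optionally gzipped): a header row of
sample IDs with first cell ``taxon``, one row per taxon labelled with the
two-token ``"Genus species"`` convention (``unknown_species`` is an
ordinary species token), and non-negative integer read counts in cells.

Metadata is a four-column TSV: ``sample_id``, ``subject_id``,
``compartment`` (saliva/biopsy) and ``group`` (case/control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("saliva", "biopsy")
GROUPS = ("case", "control")


class ValidationError(ValueError):
    """A table or metadata file violated a structural invariant."""


@dataclass
class CountTable:
    """Taxa-by-sample matrix of classified read counts.

    Parameters
    ----------
    taxa
        Ordered taxon labels (rows). Must be unique.
    samples
        Ordered sample IDs (columns). Must be unique.
    counts
        Non-negative integer matrix of shape ``(len(taxa), len(samples))``.
    """

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.samples = list(self.samples)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at taxon {self.taxa[bad[0]]!r}, "
                    f"sample {self.samples[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxa[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        _check_unique(self.taxa, "taxon label")
        _check_unique(self.samples, "sample ID")
        zeros = self.zero_samples()
        if zeros:
            logger.warning("all-zero sample column(s): %s", ", ".join(zeros))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def zero_samples(self) -> list[str]:
        """Sample IDs whose column sums to zero (flagged, never dropped)."""
        totals = self.counts.sum(axis=0)
        return [s for s, t in zip(self.samples, totals) if t == 0]

    def column(self, sample_id: str) -> np.ndarray:
        """Count vector for one sample, in taxon order."""
        try:
            j = self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample ID {sample_id!r}") from None
        return self.counts[:, j]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """New table restricted to ``sample_ids``, preserving their order."""
        idx = [self.samples.index(s) for s in sample_ids]
        return CountTable(list(self.taxa), list(sample_ids), self.counts[:, idx])

    def subset_taxa(self, taxa: Sequence[str]) -> "CountTable":
        idx = [self.taxa.index(t) for t in taxa]
        return CountTable(list(taxa), list(self.samples), self.counts[idx, :])

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1; zero columns stay 0)."""
        totals = self.counts.sum(axis=0).astype(float)
        safe = np.where(totals == 0, 1.0, totals)
        return self.counts / safe

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)
        df.index.name = "taxon"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass(frozen=True)
class SampleMeta:
    """Annotations for one sample: owning subject, compartment and group."""

    sample_id: str
    subject_id: str
    compartment: str
    group: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r} for sample "
                f"{self.sample_id!r}; allowed: {', '.join(COMPARTMENTS)}"
            )
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"allowed: {', '.join(GROUPS)}"
            )


@dataclass(frozen=True)
class SubjectPair:
    """One subject's saliva sample matched with their biopsy sample."""

    subject_id: str
    group: str
    saliva_sample: str
    biopsy_sample: str


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


def read_count_table(path: str | Path) -> CountTable:
    """Read and validate a taxa-by-sample TSV (``.gz`` accepted).

    Counts are parsed strictly as integers; a negative or non-integer cell
    raises with its row/column coordinates. Row and column order of the
    input file is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    taxa = [str(t) for t in df.index]
    samples = [str(s) for s in df.columns]
    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-integer count {raw!r} at taxon {taxa[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
            if val < 0:
                raise ValidationError(
                    f"negative count {val} at taxon {taxa[i]!r}, "
                    f"sample {samples[j]!r}"
                )
            counts[i, j] = val
    return CountTable(taxa, samples, counts)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as TSV; inverse of :func:`read_count_table`."""
    table.to_frame().to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read and validate the four-column sample metadata TSV.

    Compartment and group tokens are normalized case-insensitively. Raises
    on unknown tokens, duplicate sample IDs, duplicate (subject,
    compartment) pairs, or a subject annotated with two different groups.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "subject_id", "compartment", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {', '.join(missing)}")
    records = [
        SampleMeta(
            sample_id=row.sample_id,
            subject_id=row.subject_id,
            compartment=row.compartment.strip().lower(),
            group=row.group.strip().lower(),
        )
        for row in df.itertuples()
    ]
    _check_unique((m.sample_id for m in records), "sample ID")
    _check_unique(
        (f"{m.subject_id}/{m.compartment}" for m in records),
        "(subject, compartment) pair",
    )
    by_subject: dict[str, str] = {}
    for m in records:
        prev = by_subject.setdefault(m.subject_id, m.group)
        if prev != m.group:
            raise ValidationError(
                f"subject {m.subject_id!r} annotated with both groups "
                f"{prev!r} and {m.group!r}"
            )
    return records


def write_metadata(metadata: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            (m.sample_id, m.subject_id, m.compartment, m.group)
            for m in metadata
        ],
        columns=["sample_id", "subject_id", "compartment", "group"],
    ).to_csv(path, sep="\t", index=False)


def build_pairs(
    metadata: Sequence[SampleMeta], table: CountTable | None = None
) -> list[SubjectPair]:
    """One :class:`SubjectPair` per subject with BOTH compartments.

    Subjects missing a compartment are logged and excluded (they remain
    usable for per-compartment statistics). If ``table`` is given, a pair
    whose sample IDs are absent from it raises.
    """
    by_subject: dict[str, dict[str, SampleMeta]] = {}
    for m in metadata:
        by_subject.setdefault(m.subject_id, {})[m.compartment] = m
    pairs: list[SubjectPair] = []
    excluded: list[str] = []
    for subject_id, comps in by_subject.items():
        if "saliva" in comps and "biopsy" in comps:
            pair = SubjectPair(
                subject_id=subject_id,
                group=comps["saliva"].group,
                saliva_sample=comps["saliva"].sample_id,
                biopsy_sample=comps["biopsy"].sample_id,
            )
            if table is not None:
                for sid in (pair.saliva_sample, pair.biopsy_sample):
                    if sid not in table.samples:
                        raise ValidationError(
                            f"sample {sid!r} of subject {subject_id!r} not in count table"
                        )
            pairs.append(pair)
        else:
            excluded.append(subject_id)
    if excluded:
        logger.warning(
            "excluded %d subject(s) missing one compartment: %s",
            len(excluded),
            ", ".join(excluded),
        )
    return pairs


def metadata_for(
    metadata: Sequence[SampleMeta], compartment: str | None = None
) -> list[SampleMeta]:
    """Filter metadata by compartment (validating the token)."""
    if compartment is None:
        return list(metadata)
    if compartment not in COMPARTMENTS:
        raise ValidationError(
            f"unknown compartment {compartment!r}; allowed: {', '.join(COMPARTMENTS)}"
        )
    return [m for m in metadata if m.compartment == compartment]
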