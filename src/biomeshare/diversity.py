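"""Shannon-Wiener alpha-diversity per sample and group comparison per
compartment. Natural-log units (nats) by default; base configurable."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import filtering_stats
from .filtering_stats import TTestResult
from .profiles_io import CountTable, SampleMeta, metadata_for


@dataclass(frozen=True)
class DiversityRecord:
    sample_id: str
    compartment: str
    group: str
    richness: int
    shannon: float


def shannon_index(counts, base: float | None = None) -> float:
    """H = -sum p_i log p_i over taxa with positive counts.

    ``base=None`` means natural log; pass 2 for bits etc. Raises on an
    all-zero vector.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no defined diversity")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def diversity_records(
    table: CountTable,
    metadata: Sequence[SampleMeta],
    compartment: str,
    base: float | None = None,
) -> list[DiversityRecord]:
    """Per-sample richness and Shannon index for one compartment.

    Samples with zero classified reads are skipped (diversity undefined).
    """
    records = []
    for m in metadata_for(metadata, compartment):
        if m.sample_id not in table.samples:
            continue
        col = table.column(m.sample_id)
        if col.sum() == 0:
            continue
        records.append(
            DiversityRecord(
                sample_id=m.sample_id,
                compartment=m.compartment,
                group=m.group,
                richness=int((col > 0).sum()),
                shannon=shannon_index(col, base=base),
            )
        )
    return records


def diversity_by_group(
    table: CountTable,
    metadata: Sequence[SampleMeta],
    compartment: str,
    base: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[list[DiversityRecord], TTestResult, float]:
    """Case/control comparison of Shannon diversity within a compartment.

    Returns the per-sample records, the bootstrap-supported Welch t-test
    on the per-sample indices, and the post hoc power at the observed
    effect (NaN when either group has zero variance).
    """
    records = diversity_records(table, metadata, compartment, base=base)
    case = [r.shannon for r in records if r.group == "case"]
    control = [r.shannon for r in records if r.group == "control"]
    if len(case) < 2 or len(control) < 2:
        raise ValueError(
            f"compartment {compartment!r} needs >=2 samples per group "
            f"(got {len(case)} case, {len(control)} control)"
        )
    ttest = filtering_stats.bootstrap_t_test(case, control, n_boot=n_boot, seed=seed)
    sd_case = float(np.std(case, ddof=1))
    sd_control = float(np.std(control, ddof=1))
    if sd_case > 0 and sd_control > 0:
        power = filtering_stats.posthoc_power_t(
            float(np.mean(case)), sd_case, len(case),
            float(np.mean(control)), sd_control, len(control),
        )
    else:
        power = float("nan")
    return records, ttest, power
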