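"""Seeded generator of paired saliva/biopsy cohorts with ground-truth
bookkeeping, for recovery and calibration experiments.

The model: each compartment has a base taxon pool with log-normal base
abundances. A sample is a multinomial draw of classified reads at a
log-normally distributed depth (deep for saliva, shallow for biopsies).
Case biopsies are optionally (a) evenness-penalized, concentrating the
community, and (b) augmented with designated "translocator" taxa from the
oral pool seeded at a fixed relative abundance — the mechanism the
sharing analysis is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .association import AssociationRow
from .profiles_io import CountTable, SampleMeta


@dataclass(frozen=True)
class CohortParams:
    """All generator knobs. Defaults target a 20+20 cohort with saliva
    depth median ~2.6e4 reads and biopsy depth medians ~1.6e2 (case) /
    ~1.1e2 (control)."""

    n_case: int = 20
    n_control: int = 20
    oral_pool: int = 500
    gastric_pool: int = 130
    pool_overlap: int = 30
    oral_depth_log_mean: float = 10.17     # exp -> ~2.6e4
    oral_depth_log_sd: float = 0.8
    biopsy_depth_case_log_mean: float = 5.07   # exp -> ~159
    biopsy_depth_case_log_sd: float = 1.1
    biopsy_depth_control_log_mean: float = 4.73  # exp -> ~113
    biopsy_depth_control_log_sd: float = 0.9
    taxon_abundance_shape: float = 1.5
    subject_noise_sd: float = 0.5
    case_biopsy_evenness_penalty: float = 0.7
    translocators: int = 4
    transloc_prob: float = 0.2
    transloc_rel_abundance: float = 0.05
    transloc_saliva_rel_abundance: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_case, self.n_control, self.oral_pool, self.gastric_pool) < 1:
            raise ValueError("cohort sizes and pool sizes must be positive")
        if not 0 <= self.pool_overlap <= min(self.oral_pool, self.gastric_pool):
            raise ValueError("pool_overlap must fit in both pools")
        if self.translocators > self.oral_pool - self.pool_overlap:
            raise ValueError(
                "translocators must be drawable from the oral-only pool "
                f"({self.translocators} > {self.oral_pool - self.pool_overlap})"
            )
        if not 0 <= self.transloc_prob <= 1:
            raise ValueError("transloc_prob must be in [0, 1]")
        if not 0 < self.case_biopsy_evenness_penalty <= 1:
            raise ValueError("evenness penalty must be in (0, 1]")
        if not 0 <= self.transloc_rel_abundance < 1:
            raise ValueError("transloc_rel_abundance must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Everything the analysis is later asked to recover."""

    translocator_taxa: list[str]
    seeded: dict[str, set[str]]          # subject_id -> translocators seeded
    depths: dict[str, int]               # sample_id -> drawn read depth
    saliva_support: dict[str, set[str]]  # sample_id -> taxa with >=1 read
    params: CohortParams
    seed: int


def _taxon_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d} species{i:03d}" for i in range(1, n + 1)]


def _sample_community(
    rng: np.random.Generator,
    base_abund: np.ndarray,
    noise_sd: float,
    depth: int,
    concentration_exponent: float = 1.0,
    spike: dict[int, float] | None = None,
    ensure_detected: Iterable[int] = (),
) -> np.ndarray:
    """One multinomial read draw over a pool.

    ``spike`` maps pool indices to relative abundances mixed in after
    normalization; ``ensure_detected`` indices are guaranteed >= 1 read
    (moved from the most abundant taxon, conserving depth).
    """
    w = base_abund * rng.lognormal(0.0, noise_sd, size=base_abund.size)
    p = w / w.sum()
    if concentration_exponent != 1.0:
        p = p**concentration_exponent
        p /= p.sum()
    if spike:
        total_spike = sum(spike.values())
        p = p * (1.0 - total_spike)
        for idx, a in spike.items():
            p[idx] += a
    counts = rng.multinomial(depth, p)
    for idx in ensure_detected:
        if counts[idx] == 0 and depth > 0:
            donor = int(np.argmax(counts))
            if donor != idx and counts[donor] > 0:
                counts[donor] -= 1
                counts[idx] = 1
    return counts


def generate_cohort(
    params: CohortParams,
) -> tuple[CountTable, list[SampleMeta], SyntheticTruth]:
    """Generate one paired cohort: a count table over the union of the
    oral and gastric pools, metadata, and the ground truth.

    Reproducible bit-for-bit given ``params.seed``. Every sample column
    sums exactly to its drawn depth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    oral_taxa = _taxon_labels("Oralgenus", params.oral_pool)
    shared_pool = oral_taxa[: params.pool_overlap]
    gastric_only = _taxon_labels(
        "Gastrogenus", params.gastric_pool - params.pool_overlap
    )
    gastric_taxa = shared_pool + gastric_only
    all_taxa = oral_taxa + gastric_only
    tax_index = {t: i for i, t in enumerate(all_taxa)}

    # translocators come from the oral-only part so zero overlap keeps
    # them out of control biopsies entirely
    candidates = oral_taxa[params.pool_overlap:]
    transloc = [
        str(t) for t in rng.choice(candidates, size=params.translocators, replace=False)
    ] if params.translocators else []

    oral_base = rng.lognormal(0.0, params.taxon_abundance_shape, params.oral_pool)
    gastric_base = rng.lognormal(
        0.0, params.taxon_abundance_shape, params.gastric_pool
    )
    oral_idx = np.array([tax_index[t] for t in oral_taxa])
    gastric_idx = np.array([tax_index[t] for t in gastric_taxa])
    transloc_oral_pos = {t: oral_taxa.index(t) for t in transloc}

    subjects = [(f"CA{i + 1:02d}", "case") for i in range(params.n_case)] + [
        (f"CO{i + 1:02d}", "control") for i in range(params.n_control)
    ]

    samples: list[str] = []
    metadata: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    seeded: dict[str, set[str]] = {}
    depths: dict[str, int] = {}
    saliva_support: dict[str, set[str]] = {}

    for subject_id, group in subjects:
        # --- saliva ---
        sal_id = f"{subject_id}-SAL"
        depth = max(1, int(round(rng.lognormal(
            params.oral_depth_log_mean, params.oral_depth_log_sd
        ))))
        spike = {
            pos: params.transloc_saliva_rel_abundance / max(len(transloc), 1)
            for pos in transloc_oral_pos.values()
        }
        sal_counts = _sample_community(
            rng,
            oral_base,
            params.subject_noise_sd,
            depth,
            spike=spike,
            ensure_detected=list(transloc_oral_pos.values()),
        )
        col = np.zeros(len(all_taxa), dtype=np.int64)
        col[oral_idx] = sal_counts
        samples.append(sal_id)
        columns.append(col)
        depths[sal_id] = depth
        saliva_support[sal_id] = {
            all_taxa[i] for i in np.flatnonzero(col)
        }
        metadata.append(SampleMeta(sal_id, subject_id, "saliva", group))

        # --- biopsy ---
        bio_id = f"{subject_id}-BIO"
        if group == "case":
            log_mean = params.biopsy_depth_case_log_mean
            log_sd = params.biopsy_depth_case_log_sd
            exponent = 1.0 / params.case_biopsy_evenness_penalty
        else:
            log_mean = params.biopsy_depth_control_log_mean
            log_sd = params.biopsy_depth_control_log_sd
            exponent = 1.0
        depth = max(1, int(round(rng.lognormal(log_mean, log_sd))))
        seeded_here: set[str] = set()
        spike = {}
        if group == "case" and transloc:
            for t in transloc:
                if rng.random() < params.transloc_prob:
                    seeded_here.add(t)
        bio_counts = _sample_community(
            rng,
            gastric_base,
            params.subject_noise_sd,
            depth,
            concentration_exponent=exponent,
        )
        col = np.zeros(len(all_taxa), dtype=np.int64)
        col[gastric_idx] = bio_counts
        if seeded_here:
            # reassign a slice of the biopsy reads to the seeded taxa,
            # donating from the most abundant non-translocator taxon so
            # depth is conserved and earlier seeds are not cannibalized
            n_reads_each = max(1, int(round(depth * params.transloc_rel_abundance)))
            transloc_positions = [tax_index[t] for t in transloc]
            for t in sorted(seeded_here):
                moved = 0
                while moved < n_reads_each:
                    donors = col.copy()
                    donors[transloc_positions] = 0
                    donor = int(np.argmax(donors))
                    if donors[donor] == 0:
                        break
                    col[donor] -= 1
                    col[tax_index[t]] += 1
                    moved += 1
        samples.append(bio_id)
        columns.append(col)
        depths[bio_id] = depth
        seeded[subject_id] = seeded_here
        metadata.append(SampleMeta(bio_id, subject_id, "biopsy", group))

    table = CountTable(all_taxa, samples, np.column_stack(columns))
    truth = SyntheticTruth(
        translocator_taxa=sorted(transloc),
        seeded=seeded,
        depths=depths,
        saliva_support=saliva_support,
        params=params,
        seed=params.seed,
    )
    return table, metadata, truth


@dataclass(frozen=True)
class RecoveryResult:
    """Recovery of the seeded translocators by the downstream analysis."""

    sensitivity_exclusive: float  # NaN when no translocators exist
    fpr_exclusive: float
    sensitivity_top_rho: float
    n_translocators: int


def evaluate_recovery(
    case_only: set[str],
    association_rows: Sequence[AssociationRow],
    truth: SyntheticTruth,
    universe: Sequence[str],
) -> RecoveryResult:
    """Score case-exclusive sharing calls and top-|rho| association ranks
    against the generator's translocator set.

    ``universe`` is the full taxon list of the analyzed table (the FPR
    denominator). Raises if the truth's translocators are not in it.
    """
    translocators = set(truth.translocator_taxa)
    universe_set = set(universe)
    if not translocators <= universe_set:
        raise ValueError("translocator labels missing from the analyzed table")
    if not case_only <= universe_set:
        raise ValueError("case-exclusive labels missing from the analyzed table")
    k = len(translocators)
    non_transloc = len(universe_set) - k
    fpr = len(case_only - translocators) / non_transloc if non_transloc else 0.0
    if k == 0:
        return RecoveryResult(float("nan"), fpr, float("nan"), 0)
    sens_excl = len(case_only & translocators) / k
    ca_rows = [
        r for r in association_rows
        if r.view == "CA" and not np.isnan(r.rho) and r.rho > 0
    ]
    top = {r.taxon for r in sorted(ca_rows, key=lambda r: -r.rho)[:k]}
    sens_rho = len(top & translocators) / k
    return RecoveryResult(sens_excl, fpr, sens_rho, k)
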