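"""Per-taxon Spearman correlation of abundance or presence with group
membership, per compartment, with Benjamini-Hochberg FDR adjustment.

Midrank tie handling makes the coefficient for two binary vectors equal
to the phi coefficient of their 2x2 contingency table, which is why a
4-of-20 vs 0-of-20 presence pattern yields exactly rho = 1/3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles_io import CountTable, SampleMeta, metadata_for

logger = logging.getLogger(__name__)

MODES = ("relative-abundance", "presence")


@dataclass(frozen=True)
class AssociationRow:
    taxon: str
    compartment: str
    view: str       # "CA" (case-positive coding) or "CO" (mirrored)
    rho: float
    p: float
    q: float
    direction: str  # "case-enriched" | "control-enriched"


def spearman_with_ties(x, y) -> float:
    """Spearman rank correlation with midrank (average) tie handling.

    Returns NaN with a warning if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the t approximation,
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom."""
    if n < 4:
        raise ValueError("need n >= 4")
    if np.isnan(rho):
        return float("nan")
    if abs(rho) >= 1:
        logger.warning("|rho| = 1: t approximation degenerate, reporting p = 0")
        return 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return float(2 * stats.t.sf(abs(t), n - 2))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are passed through unadjusted and excluded from the
    correction.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if ok.sum() > 0:
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def group_association_scan(
    table: CountTable,
    metadata: Sequence[SampleMeta],
    compartment: str,
    mode: str = "relative-abundance",
    presence_threshold: int = 1,
) -> list[AssociationRow]:
    """Spearman group-association scan over every taxon of a compartment.

    The case-view codes case = 1, control = 0 and correlates the group
    indicator with per-taxon relative abundance (default) or binary
    presence. BH-FDR is applied across the compartment's testable taxa.
    Rows are sorted by rho descending within each view; the control view
    is the exact mirror (rho negated, identical p/q).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    metas = [m for m in metadata_for(metadata, compartment) if m.sample_id in table.samples]
    groups = {m.group for m in metas}
    if groups != {"case", "control"}:
        raise ValueError(f"compartment {compartment!r} must contain both groups")
    sample_ids = [m.sample_id for m in metas]
    sub = table.subset_samples(sample_ids)
    x = np.array([1.0 if m.group == "case" else 0.0 for m in metas])
    if mode == "presence":
        values = (sub.counts >= presence_threshold).astype(float)
    else:
        values = sub.relative_abundance()
    n = x.size
    rhos = np.empty(sub.n_taxa)
    for i in range(sub.n_taxa):
        y = values[i, :]
        rhos[i] = float("nan") if np.ptp(y) == 0 else spearman_with_ties(x, y)
    ps = np.array([spearman_p(r, n) for r in rhos])
    qs = bh_fdr(ps)
    order = sorted(
        range(sub.n_taxa),
        key=lambda i: (-rhos[i] if not np.isnan(rhos[i]) else np.inf, sub.taxa[i]),
    )
    rows: list[AssociationRow] = []
    for view, sign in (("CA", 1.0), ("CO", -1.0)):
        idx = order if view == "CA" else order[::-1]
        for i in idx:
            if np.isnan(rhos[i]):
                direction = "undefined"
            elif rhos[i] >= 0:
                direction = "case-enriched"
            else:
                direction = "control-enriched"
            rows.append(
                AssociationRow(
                    taxon=sub.taxa[i],
                    compartment=compartment,
                    view=view,
                    rho=sign * rhos[i],
                    p=float(ps[i]),
                    q=float(qs[i]),
                    direction=direction,
                )
            )
    return rows
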