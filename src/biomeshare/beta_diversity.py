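"""Bray-Curtis dissimilarity, principal coordinates analysis (classical
scaling) and a PERMANOVA-style permutation test for group separation."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform

from .profiles_io import CountTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal, values in [0, 1]."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.matrix < -1e-12):
            raise ValueError("negative dissimilarity")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class PcoaResult:
    """Classical-scaling ordination: sample coordinates on the positive
    eigenvalue axes, with per-axis variance proportions."""

    ids: list[str]
    coordinates: np.ndarray          # samples x axes
    eigenvalues: np.ndarray          # positive eigenvalues kept, descending
    proportion_explained: np.ndarray
    n_negative_discarded: int


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity on relative abundances.

    Both vectors are normalized to sum 1 first, so the measure is
    invariant to sequencing depth. Raises if either vector is all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        raise ValueError("cannot compute Bray-Curtis for an all-zero sample")
    return float(braycurtis(x / sx, y / sy))


def bray_curtis_matrix(table: CountTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances between the table's samples."""
    if any(t == 0 for t in table.counts.sum(axis=0)):
        raise ValueError(
            f"all-zero sample(s) in table: {', '.join(table.zero_samples())}"
        )
    rel = table.relative_abundance().T  # samples x taxa
    mat = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(list(table.samples), mat)


def pcoa(dist: DistanceMatrix, n_axes: int = 3) -> PcoaResult:
    """Principal coordinates analysis by classical scaling.

    Double-centers -0.5 * J D^2 J, eigendecomposes, and returns
    coordinates scaled by the square roots of the positive eigenvalues.
    Negative eigenvalues (non-Euclidean distances) are counted and
    discarded; requesting more axes than positive eigenvalues truncates
    with a warning.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d2 = dist.matrix**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    n_negative = int(np.sum(eigvals < -tol))
    pos_vals = eigvals[positive]
    pos_vecs = eigvecs[:, positive]
    keep = min(n_axes, pos_vals.size)
    if keep < n_axes:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; truncating",
            n_axes,
            pos_vals.size,
        )
    coords = pos_vecs[:, :keep] * np.sqrt(pos_vals[:keep])
    total = pos_vals.sum()
    proportions = pos_vals[:keep] / total if total > 0 else np.zeros(keep)
    return PcoaResult(
        ids=list(dist.ids),
        coordinates=coords,
        eigenvalues=pos_vals[:keep],
        proportion_explained=proportions,
        n_negative_discarded=n_negative,
    )


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and integer-coded labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    a = groups.size
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permutation_group_test(
    dist: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int | str = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """PERMANOVA-style permutation test for group separation.

    Returns ``(pseudo_F, p)`` with ``p = (1 + #{permuted F >= observed})
    / (1 + n_perm)``. Pass ``n_perm="all"`` to enumerate every distinct
    label assignment exactly (small n only); exhaustive p is
    ``#{F >= observed} / #assignments`` with the identity included.
    """
    labels = np.asarray(labels)
    if labels.size != len(dist.ids):
        raise ValueError("one label per sample required")
    _, counts = np.unique(labels, return_counts=True)
    if counts.size < 2 or np.any(counts < 2):
        raise ValueError("need >=2 groups with >=2 members each")
    d2 = dist.matrix**2
    codes = np.unique(labels, return_inverse=True)[1]
    f_obs = _pseudo_f(d2, codes)
    if n_perm == "all":
        assignments = {perm for perm in itertools.permutations(codes)}
        hits = sum(_pseudo_f(d2, np.array(a)) >= f_obs - 1e-12 for a in assignments)
        return f_obs, hits / len(assignments)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_perm)):
        if _pseudo_f(d2, rng.permutation(codes)) >= f_obs - 1e-12:
            hits += 1
    return f_obs, (1 + hits) / (1 + int(n_perm))
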