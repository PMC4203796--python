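"""Expression-profile clustering: row z-scores, Pearson distance, UPGMA.

The concatenated three-species relative-expression matrix (one row per
ortholog triad, columns ordered species 1 stages, species 2 stages,
species 3 stages) is normalized row-by-row (subtract mean, divide by the
sample standard deviation), profile similarity is the Pearson correlation
r, distance is 1 - r, and rows are agglomerated by unweighted average
linkage (UPGMA).  Cutting the dendrogram below its k-1 highest merges
yields k clusters (default 8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ProfileSet
from .orthology import OrthologTriad
from .stages import validate_stage_subset

logger = logging.getLogger("crossdev")

__all__ = [
    "assemble_matrix",
    "zscore_rows",
    "pearson_distance",
    "Dendrogram",
    "upgma",
    "cut_tree",
]


def assemble_matrix(
    profiles: ProfileSet,
    triads: Sequence[OrthologTriad],
    species_ids: Sequence[str],
    stages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the triads x (species x stage) relative-level matrix.

    Triads with a missing or uninformative member profile are dropped
    (logged).  Columns are named ``species:stage`` and ordered species
    first, canonical stages within species.
    """
    if len(species_ids) != 3:
        raise ValueError("exactly 3 species ids required")
    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    dropped = 0
    col_stages: tuple[str, ...] | None = (
        validate_stage_subset(stages) if stages is not None else None
    )
    for triad in triads:
        vals: list[float] = []
        ok = True
        for sp, gene in zip(species_ids, triad.genes):
            if (sp, gene) not in profiles:
                ok = False
                break
            prof = profiles.get(sp, gene)
            if prof.uninformative:
                ok = False
                break
            if col_stages is None:
                col_stages = prof.stages
            vals.extend(prof.level_at(s) for s in col_stages)
        if ok:
            rows.append(np.asarray(vals))
            row_ids.append(triad.triad_id)
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "matrix assembly: dropped %d/%d triads with missing or "
            "uninformative profiles",
            dropped,
            len(triads),
        )
    if not rows:
        raise ValueError("no complete triads to assemble")
    assert col_stages is not None
    columns = [f"{sp}:{s}" for sp in species_ids for s in col_stages]
    return pd.DataFrame(np.vstack(rows), index=row_ids, columns=columns)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Normalize each row to mean 0 and sample (n-1) standard deviation 1.

    Constant rows (zero variance) cannot be normalized and are excluded
    with a logged warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to z-score rows")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    constant = sds[:, 0] == 0.0
    if constant.any():
        logger.warning(
            "zscore_rows: excluding %d constant row(s): %s",
            int(constant.sum()),
            list(matrix.index[constant][:10]),
        )
    keep = ~constant
    z = (values[keep] - means[keep]) / sds[keep]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def pearson_distance(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise distance 1 - Pearson r between rows; in [0, 2], zero diagonal."""
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if (values.std(axis=1) == 0.0).any():
        raise ValueError("zero-variance row: exclude constant rows before distance")
    r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` holds ``(node_a, node_b, height, size)`` per agglomeration;
    leaves are nodes ``0..n-1`` and the i-th merge creates node ``n+i``
    (scipy linkage numbering).
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return np.asarray([m[2] for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage array."""
        return np.asarray([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def upgma(
    dist: np.ndarray, leaf_ids: Sequence[str] | None = None
) -> Dendrogram:
    """Unweighted average-linkage agglomeration of a distance matrix.

    At each step the closest pair of clusters is merged (ties broken by
    the lowest current row-index pair) and the distance from the merged
    cluster to every other cluster is the size-weighted (Lance-Williams)
    mean, which equals the unweighted mean over all inter-cluster leaf
    pairs.  UPGMA is reducible, so merge heights are non-decreasing.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    leaf_ids = list(leaf_ids)
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids length must match matrix size")

    cur = d.copy()
    np.fill_diagonal(cur, np.inf)
    node_ids = list(range(n))
    sizes = [1] * n
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        m = cur.shape[0]
        flat = int(np.argmin(cur))
        i, j = divmod(flat, m)
        if i > j:  # row-major argmin lands on the upper triangle first
            i, j = j, i
        height = float(cur[i, j])
        ni, nj = sizes[i], sizes[j]
        merges.append((node_ids[i], node_ids[j], height, ni + nj))
        merged = (ni * cur[i, :] + nj * cur[j, :]) / (ni + nj)
        cur[i, :] = merged
        cur[:, i] = merged
        cur[i, i] = np.inf
        cur = np.delete(np.delete(cur, j, axis=0), j, axis=1)
        node_ids[i] = next_id
        sizes[i] = ni + nj
        del node_ids[j], sizes[j]
        next_id += 1
    return Dendrogram(merges=merges, leaf_ids=leaf_ids)


def cut_tree(dend: Dendrogram, k: int = 8) -> dict[str, int]:
    """Cut a dendrogram into exactly k clusters.

    The k-1 highest (last) merges are discarded; connected components of
    the remaining merges are the clusters.  Labels 1..k are assigned in
    order of first leaf occurrence.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, _h, _s) in enumerate(dend.merges[: n - k]):
        new = n + idx
        parent[find(a)] = new
        parent[find(b)] = new

    labels: dict[str, int] = {}
    root_label: dict[int, int] = {}
    for leaf, leaf_id in enumerate(dend.leaf_ids):
        root = find(leaf)
        if root not in root_label:
            root_label[root] = len(root_label) + 1
        labels[leaf_id] = root_label[root]
    return labels
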