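"""Functional-category overrepresentation by the hypergeometric tail.

Each gene set (typically an expression cluster) is tested against the
annotated universe: with M genes in the universe, K of them carrying a
category, and a set of n genes of which x carry the category, the
enrichment P value is the upper tail P(X >= x) of
Hypergeometric(M, K, n).  Hierarchical category identifiers (FunCat-style
dot paths such as ``01.03.16``) are rolled up to their ancestors by
default, genes without any annotation are counted under ``unclassified``,
and Benjamini-Hochberg q values are added per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UNCLASSIFIED",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "rollup_categories",
    "enrich_sets",
    "results_to_frame",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class EnrichmentResult:
    """One (gene set, category) enrichment test."""

    set_id: str
    category_id: str
    x: int  # genes in the set carrying the category
    n: int  # set size
    K: int  # category size in the universe
    M: int  # universe size
    p_value: float
    q_value: float


def hypergeom_upper_tail(x: int, n: int, K: int, M: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(M, K, n).

    Computed via scipy's survival function, which works on log-gamma
    binomial coefficients and is stable for large parameters.
    """
    if not (0 <= x <= n <= M):
        raise ValueError(f"need 0 <= x <= n <= M, got x={x}, n={n}, M={M}")
    if not (0 <= K <= M):
        raise ValueError(f"need 0 <= K <= M, got K={K}, M={M}")
    return float(stats.hypergeom.sf(x - 1, M, K, n))


def rollup_categories(categories: Iterable[str]) -> set[str]:
    """Expand dot-path category ids with all their ancestors.

    ``{"01.03.16"}`` becomes ``{"01", "01.03", "01.03.16"}``.  The
    ``unclassified`` label has no hierarchy and passes through unchanged.
    """
    out: set[str] = set()
    for cat in categories:
        if cat == UNCLASSIFIED:
            out.add(cat)
            continue
        parts = cat.split(".")
        for i in range(1, len(parts) + 1):
            out.add(".".join(parts[:i]))
    return out


def _gene_categories(
    gene: str,
    annotation: Mapping[str, Iterable[str]],
    rollup: bool,
) -> set[str]:
    cats = set(annotation.get(gene, ()))
    if not cats:
        return {UNCLASSIFIED}
    return rollup_categories(cats) if rollup else cats


def enrich_sets(
    sets: Mapping[str, Iterable[str]],
    annotation: Mapping[str, Iterable[str]],
    universe: Sequence[str],
    rollup: bool = True,
    q_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every (set, category) pair with x >= 1 for overrepresentation.

    Parameters
    ----------
    sets
        set id -> gene ids (e.g. cluster label -> member genes).  Cluster
        assignments from :func:`crossdev.clustering.cut_tree` can be passed
        after grouping by label.
    annotation
        gene -> category ids; genes absent here count as ``unclassified``.
    universe
        The background gene list; every set gene must belong to it.
    rollup
        Count a gene annotated to ``01.03.16`` under ``01.03`` and ``01``
        as well (hierarchical roll-up, on by default).

    Returns results sorted by (set, q, p, category); ``q_value`` is the
    Benjamini-Hochberg adjustment across all tests of this analysis.
    The ``unclassified`` pseudo-category appears as an ordinary row, so
    the per-set unclassified count is always reported.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    uni_set = set(universe)
    if len(uni_set) != len(universe):
        raise ValueError("duplicate genes in universe")

    cat_by_gene = {g: _gene_categories(g, annotation, rollup) for g in universe}
    K_counts: dict[str, int] = {}
    for cats in cat_by_gene.values():
        for cat in cats:
            K_counts[cat] = K_counts.get(cat, 0) + 1
    M = len(universe)

    raw: list[tuple[str, str, int, int, int, float]] = []
    for set_id in sorted(sets):
        genes = list(sets[set_id])
        stray = [g for g in genes if g not in uni_set]
        if stray:
            raise ValueError(
                f"set {set_id!r}: {len(stray)} gene(s) outside the universe, "
                f"e.g. {stray[:5]}"
            )
        n = len(genes)
        x_counts: dict[str, int] = {}
        for g in genes:
            for cat in cat_by_gene[g]:
                x_counts[cat] = x_counts.get(cat, 0) + 1
        for cat in sorted(x_counts):
            x = x_counts[cat]
            p = hypergeom_upper_tail(x, n, K_counts[cat], M)
            raw.append((set_id, cat, x, n, K_counts[cat], p))

    if not raw:
        return []
    pvals = np.asarray([r[5] for r in raw])
    qvals = stats.false_discovery_control(pvals, method="bh")
    results = [
        EnrichmentResult(
            set_id=s, category_id=c, x=x, n=n, K=K, M=M, p_value=float(p),
            q_value=float(q),
        )
        for (s, c, x, n, K, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.set_id, r.q_value, r.p_value, r.category_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_id, r.category_id, r.x, r.n, r.K, r.M, r.p_value, r.q_value)
            for r in results
        ],
        columns=["set_id", "category_id", "x", "n", "K", "M", "p_value", "q_value"],
    )
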