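"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct route available
(enumeration, exact rational arithmetic, from-scratch averaging) and
never shares code with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import product

import numpy as np


def naive_best_hits(hits):
    """argmax by explicit pairwise comparison: bitscore, then smaller
    e-value, then lexicographically smaller subject."""
    per_query = {}
    for h in hits:
        per_query.setdefault(h.query_id, []).append(h)
    out = {}
    for q, rows in per_query.items():
        best = rows[0]
        for h in rows[1:]:
            if h.bitscore != best.bitscore:
                better = h.bitscore > best.bitscore
            elif h.evalue != best.evalue:
                better = h.evalue < best.evalue
            else:
                better = h.subject_id < best.subject_id
            if better:
                best = h
        out[q] = best.subject_id
    return out


def exhaustive_triads(bh_ab, bh_ba, bh_ac, bh_ca, bh_bc, bh_cb,
                      genes_a, genes_b, genes_c):
    """All (a, b, c) triples satisfying the three mutual-best conditions,
    by direct enumeration over every candidate triple."""
    found = set()
    for a, b, c in product(genes_a, genes_b, genes_c):
        if (
            bh_ab.get(a) == b and bh_ba.get(b) == a
            and bh_ac.get(a) == c and bh_ca.get(c) == a
            and bh_bc.get(b) == c and bh_cb.get(c) == b
        ):
            found.add((a, b, c))
    return found


def upgma_oracle(dist):
    """Average-linkage agglomeration recomputing every cluster-pair
    distance from scratch as the mean over all leaf pairs of the input
    matrix (no Lance-Williams update).

    Returns a list of (merged_leafset, height) in merge order, using the
    same positional lowest-row-index-pair tie rule as the implementation.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [d[p, q] for p in clusters[i] for q in clusters[j]]
                mean = math.fsum(pairs) / len(pairs)
                if best is None or mean < best[0]:
                    best = (mean, i, j)
        mean, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, mean))
        clusters[i] = merged
        del clusters[j]
    return merges


def hypergeom_upper_tail_exact(x, n, K, M):
    """P(X >= x) by exact rational enumeration of the hypergeometric pmf."""
    total = Fraction(0)
    denom = math.comb(M, n)
    for i in range(x, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, n - i), denom)
    return float(total)


def pearson_manual(a, b):
    """Pearson r via explicit covariance / sigma-sigma computation."""
    a = list(map(float, a))
    b = list(map(float, b))
    n = len(a)
    ma = math.fsum(a) / n
    mb = math.fsum(b) / n
    cov = math.fsum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = math.fsum((x - ma) ** 2 for x in a)
    vb = math.fsum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)
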