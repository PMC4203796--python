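"""Conservative cross-species candidate ranking by credible-interval gaps.

For each ortholog triad, each species pair and each post-crossing stage,
the between-species difference is scored conservatively: if the 95%
credible intervals of the two relative expression levels are disjoint,
the gap is the lower bound of the higher species minus the upper bound of
the lower species; if they overlap, the gap is zero.  A pair's score for
a gene is the maximum gap over the ranking stages (sum available as an
option).  Candidates are genes with a positive score in every relevant
comparison, ranked by the minimum (most conservative) pairwise score, and
the top M (default 130) are selected.

Two qualification modes exist:

* ``all-pairs`` (default): positive score required in all three pairwise
  comparisons.
* ``focal``: positive score required only in the two comparisons that
  involve a named focal species — the screen for genes whose expression
  diverged specifically in that species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .expression import ExpressionProfile, ProfileSet
from .orthology import OrthologTriad
from .stages import RANKING_STAGE_NAMES, STAGE_INDEX

logger = logging.getLogger("crossdev")

__all__ = [
    "ci_gap",
    "ComparisonScore",
    "comparison_scores",
    "CandidateRow",
    "CandidateRanking",
    "rank_and_select",
    "ranking_to_frame",
    "write_ranking",
]

DEFAULT_M = 130


def ci_gap(
    profile_a: ExpressionProfile, profile_b: ExpressionProfile, stage: str
) -> tuple[float, str | None]:
    """Conservative gap between two species' 95% intervals at one stage.

    Returns ``(gap, direction)`` where direction is the species id of the
    higher species, or ``None`` when the intervals overlap (gap 0).
    """
    a_lo, a_hi = profile_a.bounds(stage)
    b_lo, b_hi = profile_b.bounds(stage)
    if a_lo > b_hi:
        return a_lo - b_hi, profile_a.species_id
    if b_lo > a_hi:
        return b_lo - a_hi, profile_b.species_id
    return 0.0, None


@dataclass
class ComparisonScore:
    """Per-gene scores for one species pair across the ranking stages."""

    triad_id: str
    pair: tuple[str, str]
    gap: dict[str, float]
    direction: dict[str, str | None]
    score: float
    best_stage: str | None = None


def comparison_scores(
    profiles: ProfileSet,
    triads: Sequence[OrthologTriad],
    species_ids: Sequence[str],
    pair: tuple[str, str],
    ranking_stages: Sequence[str] = RANKING_STAGE_NAMES,
    stat: str = "max",
) -> list[ComparisonScore]:
    """CI-gaps at every ranking stage for one species pair, for all triads.

    ``stat`` aggregates per-stage gaps into the scalar score: ``max``
    (default, the single biggest confident change) or ``sum``.  Triads
    with a missing or uninformative profile in either species are skipped
    with a log message.
    """
    if stat not in ("max", "sum"):
        raise ValueError(f"stat must be 'max' or 'sum', got {stat!r}")
    sp_gene = {sp: i for i, sp in enumerate(species_ids)}
    for sp in pair:
        if sp not in sp_gene:
            raise ValueError(f"pair species {sp!r} not among {list(species_ids)}")
    stages = sorted(ranking_stages, key=STAGE_INDEX.__getitem__)
    out: list[ComparisonScore] = []
    skipped = 0
    for triad in triads:
        gene_a = triad.genes[sp_gene[pair[0]]]
        gene_b = triad.genes[sp_gene[pair[1]]]
        if (pair[0], gene_a) not in profiles or (pair[1], gene_b) not in profiles:
            skipped += 1
            continue
        prof_a = profiles.get(pair[0], gene_a)
        prof_b = profiles.get(pair[1], gene_b)
        if prof_a.uninformative or prof_b.uninformative:
            skipped += 1
            continue
        gaps: dict[str, float] = {}
        dirs: dict[str, str | None] = {}
        for stage in stages:
            g, d = ci_gap(prof_a, prof_b, stage)
            gaps[stage] = g
            dirs[stage] = d
        if stat == "max":
            score = max(gaps.values())
            best = next((s for s in stages if gaps[s] == score), None) if score > 0 else None
        else:
            score = sum(gaps.values())
            best = max(stages, key=lambda s: gaps[s]) if score > 0 else None
        out.append(
            ComparisonScore(
                triad_id=triad.triad_id,
                pair=(pair[0], pair[1]),
                gap=gaps,
                direction=dirs,
                score=score,
                best_stage=best,
            )
        )
    if skipped:
        logger.info(
            "comparison %s-%s: skipped %d triads with missing/uninformative profiles",
            pair[0],
            pair[1],
            skipped,
        )
    return out


@dataclass
class CandidateRow:
    rank: int
    triad_id: str
    combined_score: float
    pair_scores: dict[tuple[str, str], float]
    best_stage: str | None
    direction: str | None


@dataclass
class CandidateRanking:
    """Ordered top-M candidate list with per-comparison scores."""

    rows: list[CandidateRow]
    selection_size: int
    mode: str
    focal_species: str | None = None
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def triad_ids(self) -> list[str]:
        return [r.triad_id for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def rank_and_select(
    scores_by_pair: Mapping[tuple[str, str], Sequence[ComparisonScore]],
    m: int = DEFAULT_M,
    mode: str = "all-pairs",
    focal_species: str | None = None,
) -> CandidateRanking:
    """Select the top-M candidates common to all relevant comparisons.

    A gene qualifies when its score is positive in every relevant pair:
    all three pairs in ``all-pairs`` mode, or the two pairs containing
    ``focal_species`` in ``focal`` mode.  The combined score is the
    minimum of the relevant pairwise scores (conservative); ties are
    broken by triad id.  If fewer than M genes qualify, all are returned
    with a warning.
    """
    if m < 1:
        raise ValueError(f"selection size must be >= 1, got {m}")
    if mode not in ("all-pairs", "focal"):
        raise ValueError(f"mode must be 'all-pairs' or 'focal', got {mode!r}")
    pairs = sorted(scores_by_pair)
    if len(pairs) != 3:
        raise ValueError(f"expected scores for 3 species pairs, got {len(pairs)}")
    if mode == "focal":
        if focal_species is None:
            raise ValueError("focal mode requires focal_species")
        relevant = [p for p in pairs if focal_species in p]
        if len(relevant) != 2:
            raise ValueError(
                f"focal species {focal_species!r} must appear in exactly 2 pairs"
            )
    else:
        relevant = pairs

    by_triad: dict[str, dict[tuple[str, str], ComparisonScore]] = {}
    for pair in pairs:
        for cs in scores_by_pair[pair]:
            by_triad.setdefault(cs.triad_id, {})[pair] = cs
    common = [t for t, d in by_triad.items() if len(d) == len(pairs)]
    if len(common) != len(by_triad):
        logger.info(
            "ranking: %d triads lack scores in some comparison and are dropped",
            len(by_triad) - len(common),
        )

    qualifying: list[tuple[float, str]] = []
    for triad_id in common:
        per_pair = by_triad[triad_id]
        if all(per_pair[p].score > 0 for p in relevant):
            combined = min(per_pair[p].score for p in relevant)
            qualifying.append((combined, triad_id))
    qualifying.sort(key=lambda t: (-t[0], t[1]))

    if len(qualifying) < m:
        logger.warning(
            "ranking: only %d genes qualify (< selection size %d); returning all",
            len(qualifying),
            m,
        )
    rows: list[CandidateRow] = []
    for rank, (combined, triad_id) in enumerate(qualifying[:m], start=1):
        per_pair = by_triad[triad_id]
        # the limiting (minimum-score) comparison supplies stage/direction
        limiting = min(relevant, key=lambda p: (per_pair[p].score, p))
        cs = per_pair[limiting]
        direction = cs.direction.get(cs.best_stage) if cs.best_stage else None
        rows.append(
            CandidateRow(
                rank=rank,
                triad_id=triad_id,
                combined_score=combined,
                pair_scores={p: by_triad[triad_id][p].score for p in pairs},
                best_stage=cs.best_stage,
                direction=direction,
            )
        )
    return CandidateRanking(
        rows=rows,
        selection_size=m,
        mode=mode,
        focal_species=focal_species,
        pairs=pairs,
    )


def ranking_to_frame(ranking: CandidateRanking) -> pd.DataFrame:
    cols = [f"score_{a}_{b}" for a, b in ranking.pairs]
    records = []
    for row in ranking.rows:
        records.append(
            (
                row.rank,
                row.triad_id,
                row.combined_score,
                *[row.pair_scores[p] for p in ranking.pairs],
                row.best_stage or "",
                row.direction or "",
            )
        )
    return pd.DataFrame(
        records,
        columns=["rank", "triad_id", "combined_score", *cols, "best_stage", "direction"],
    )


def write_ranking(ranking: CandidateRanking, path: str | Path) -> None:
    ranking_to_frame(ranking).to_csv(path, sep="\t", index=False)
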