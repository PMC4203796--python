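"""Synthetic three-species developmental tag-count datasets with known truth.

The generator emulates the structure of a cross-species sexual-development
time course: three species, eight stages (protoperithecia before crossing
through 144 h), one pooled library per (species, stage), and single-copy
ortholog triads.  Per-gene expression trajectories are smooth log-scale
random walks (optionally drawn from a small number of shared archetype
trajectories); a configurable fraction of genes is planted as divergent —
their expression in a focal species is multiplied by a known fold change
at known stages while the other two species keep the shared level.  Tag
counts are Poisson with mean ``library_size x rate`` (one pooled library
per stage, hence no replicate dispersion; an optional negative-binomial
dispersion is available but off by default).

Alongside the counts the generator can emit every support file the
downstream modules consume: the true triad table, six directed
similarity-hit tables constructed so reciprocal-best-hit search recovers
exactly the true triads (with optional lower-scoring decoy hits and
above-threshold decoys), and a FunCat-style annotation table in which one
marker category is enriched among the divergent genes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountDataset, write_annotation
from .orthology import OrthologTriad, write_triads, OUTFMT6_COLUMNS
from .stages import RANKING_STAGE_NAMES, STAGE_NAMES

__all__ = [
    "GenerationConfig",
    "Divergence",
    "SyntheticTruth",
    "generate_truth",
    "simulate_counts",
    "emit_support_files",
]

#: FunCat-style hierarchical category vocabulary (leaf ids).
_CATEGORY_VOCABULARY = (
    "01.01.03",
    "01.03.16",
    "01.05.02",
    "01.06.05",
    "01.20",
    "02.10",
    "02.13.03",
    "10.01.05",
    "10.03.01",
    "11.02.03",
    "14.07.02",
    "16.03.01",
    "20.01.01",
    "20.09.07",
    "32.01.09",
    "34.11.03",
    "41.01.01",
    "42.04.05",
    "43.01.03",
    "99.33",
)

#: Marker category planted preferentially in divergent genes.
MARKER_CATEGORY = "88.01"


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the synthetic truth.

    Defaults mirror the study conditions the generator emulates: 2352
    ortholog triads across three species and eight stages, pooled
    libraries of ~2x10^7 mapped tags, log-normal baseline rates giving a
    median of ~200 tags per gene per sample, smooth trajectories, and a
    ~5.5% planted-divergent fraction (130/2352) with fold changes >= 8 in
    the first (focal) species at a contiguous block of post-crossing
    stages.
    """

    n_genes: int = 2352
    species_ids: tuple[str, str, str] = ("Ncra", "Ntet", "Ndis")
    fraction_divergent: float = 130 / 2352
    fold_min: float = 8.0
    fold_max: float = 16.0
    focal_species: str | None = None  # default: first species
    affected_block: tuple[int, int] = (2, 4)  # contiguous stages, min/max length
    divergence_stage_pool: tuple[str, ...] = RANKING_STAGE_NAMES
    baseline_log_mean: float = math.log(1e-5)
    baseline_log_sd: float = 1.0
    walk_step_sd: float = 0.4
    n_archetypes: int | None = None
    archetype_step_sd: float = 1.2
    archetype_jitter_sd: float = 0.05
    #: archetype trajectories are redrawn until every pair of
    #: expression-scale shapes correlates below this bound, so planted
    #: archetypes are mutually distinct by construction
    archetype_max_corr: float = 0.7
    #: and until each archetype's span across stages falls in this
    #: log-unit window: flat trajectories have no shape signal to recover,
    #: while extreme spans push the lowest stage below measurable depth
    archetype_log_range: tuple[float, float] = (1.5, 3.0)
    p_unannotated: float = 0.10
    p_marker_divergent: float = 0.80
    p_marker_background: float = 0.02
    nb_dispersion: float | None = None  # gamma shape; None = pure Poisson

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if not 0.0 <= self.fraction_divergent < 1.0:
            raise ValueError(
                f"fraction_divergent must be in [0, 1), got {self.fraction_divergent}"
            )
        if self.fold_min < 1.0 or self.fold_max < self.fold_min:
            raise ValueError(
                f"fold range must satisfy 1 <= fold_min <= fold_max, got "
                f"[{self.fold_min}, {self.fold_max}]"
            )
        if len(self.species_ids) != 3 or len(set(self.species_ids)) != 3:
            raise ValueError("species_ids must be 3 distinct identifiers")
        lo, hi = self.affected_block
        pool = len(self.divergence_stage_pool)
        if not 1 <= lo <= hi <= pool:
            raise ValueError(
                f"affected_block must satisfy 1 <= lo <= hi <= {pool}"
            )
        if self.focal_species is not None and self.focal_species not in self.species_ids:
            raise ValueError(f"focal_species {self.focal_species!r} not in species_ids")
        if self.n_archetypes is not None and self.n_archetypes < 1:
            raise ValueError("n_archetypes must be >= 1 when set")


@dataclass(frozen=True)
class Divergence:
    """Planted divergence descriptor for one gene."""

    focal_species: str
    stages: tuple[str, ...]
    fold: float


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset.

    ``levels[species]`` is a genes x stages DataFrame of true expression
    rates per library-size unit, indexed by that species' gene ids.
    ``divergent`` maps triad index -> :class:`Divergence`; non-divergent
    genes have identical true levels in all three species.
    """

    config: GenerationConfig
    seed: int
    species_ids: tuple[str, str, str]
    stage_names: tuple[str, ...]
    triad_ids: list[str]
    gene_ids: dict[str, list[str]]
    levels: dict[str, pd.DataFrame]
    divergent: dict[int, Divergence]
    archetype: np.ndarray | None
    category_map: dict[str, set[str]]  # focal-species gene id -> categories

    @property
    def n_genes(self) -> int:
        return len(self.triad_ids)

    def triads(self) -> list[OrthologTriad]:
        return [
            OrthologTriad(
                triad_id=tid,
                genes=tuple(self.gene_ids[sp][i] for sp in self.species_ids),
            )
            for i, tid in enumerate(self.triad_ids)
        ]

    def divergent_triad_ids(self) -> set[str]:
        return {self.triad_ids[i] for i in self.divergent}


def _sub_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-operation sub-stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


def _distinct_archetype_walks(
    rng: np.random.Generator,
    k: int,
    n_stages: int,
    step_sd: float,
    max_corr: float,
    log_range: tuple[float, float],
    max_attempts: int = 2000,
) -> np.ndarray:
    """Random-walk archetype trajectories, redrawn until mutually distinct.

    Distinctness is judged on the expression scale (Pearson correlation
    of exp(walk) shapes < ``max_corr``), since downstream clustering
    correlates relative levels, not log levels.  Each archetype's span
    across stages must also fall inside ``log_range``: a flat trajectory
    carries no shape signal that any correlation-based clustering could
    recover, and an extreme span drives the lowest stage below the depth
    at which its relative level is measurable.
    """

    def draw(m: int) -> np.ndarray:
        out = np.zeros((m, n_stages))
        out[:, 1:] = np.cumsum(
            rng.normal(0.0, step_sd, size=(m, n_stages - 1)), axis=1
        )
        return out

    walks = draw(k)
    for _ in range(max_attempts):
        span = np.ptp(walks, axis=1)
        flat = (span < log_range[0]) | (span > log_range[1])
        r = np.corrcoef(np.exp(walks)) if k > 1 else np.zeros((1, 1))
        np.fill_diagonal(r, 0.0)
        bad = set(np.flatnonzero(flat)) | set(np.argwhere(r > max_corr).ravel())
        if not bad:
            return walks
        bad_idx = sorted(bad)
        walks[bad_idx] = draw(len(bad_idx))
    raise RuntimeError(
        f"could not draw {k} archetypes with pairwise correlation < {max_corr} "
        f"and log range in {log_range}"
    )


def generate_truth(config: GenerationConfig, seed: int = 0) -> SyntheticTruth:
    """Draw a ground-truth expression landscape.

    Identical (config, seed) yields identical output.  Divergent genes
    satisfy ``level_focal = fold x level_shared`` exactly at their
    affected stages; all other cells are equal across species.
    """
    config.validate()
    n = config.n_genes
    n_stages = len(STAGE_NAMES)
    focal = config.focal_species or config.species_ids[0]

    baseline = _sub_rng(seed, "baseline").normal(
        config.baseline_log_mean, config.baseline_log_sd, size=n
    )

    rng_traj = _sub_rng(seed, "trajectory")
    archetype: np.ndarray | None = None
    if config.n_archetypes:
        k = config.n_archetypes
        walks = _distinct_archetype_walks(
            rng_traj, k, n_stages, config.archetype_step_sd,
            config.archetype_max_corr, config.archetype_log_range,
        )
        archetype = rng_traj.permutation(np.arange(n) % k)
        jitter = rng_traj.normal(0.0, config.archetype_jitter_sd, size=(n, n_stages))
        log_level = baseline[:, None] + walks[archetype] + jitter
    else:
        steps = rng_traj.normal(0.0, config.walk_step_sd, size=(n, n_stages - 1))
        log_level = baseline[:, None] + np.concatenate(
            [np.zeros((n, 1)), np.cumsum(steps, axis=1)], axis=1
        )
    shared = np.exp(log_level)

    rng_div = _sub_rng(seed, "divergence")
    n_div = int(round(config.fraction_divergent * n))
    div_idx = np.sort(rng_div.choice(n, size=n_div, replace=False))
    divergent: dict[int, Divergence] = {}
    stage_pos = {s: i for i, s in enumerate(STAGE_NAMES)}
    lo, hi = config.affected_block
    for g in div_idx:
        fold = float(
            np.exp(
                rng_div.uniform(math.log(config.fold_min), math.log(config.fold_max))
            )
        )
        block_len = int(rng_div.integers(lo, hi + 1))
        start = int(
            rng_div.integers(0, len(config.divergence_stage_pool) - block_len + 1)
        )
        stages = tuple(config.divergence_stage_pool[start : start + block_len])
        divergent[int(g)] = Divergence(focal_species=focal, stages=stages, fold=fold)

    gene_ids = {
        sp: [f"{sp}_g{i:05d}" for i in range(n)] for sp in config.species_ids
    }
    triad_ids = [f"tri{i:05d}" for i in range(n)]
    levels: dict[str, pd.DataFrame] = {}
    for sp in config.species_ids:
        mat = shared.copy()
        if sp == focal:
            for g, div in divergent.items():
                cols = [stage_pos[s] for s in div.stages]
                mat[g, cols] *= div.fold
        levels[sp] = pd.DataFrame(
            mat, index=gene_ids[sp], columns=list(STAGE_NAMES)
        )

    rng_cat = _sub_rng(seed, "categories")
    category_map: dict[str, set[str]] = {}
    div_set = set(int(g) for g in div_idx)
    vocab = list(_CATEGORY_VOCABULARY)
    for g in range(n):
        gene = gene_ids[focal][g]
        if rng_cat.random() < config.p_unannotated:
            continue
        n_cats = int(rng_cat.integers(1, 4))
        cats = set(rng_cat.choice(vocab, size=n_cats, replace=False))
        p_marker = (
            config.p_marker_divergent if g in div_set else config.p_marker_background
        )
        if rng_cat.random() < p_marker:
            cats.add(MARKER_CATEGORY)
        category_map[gene] = cats

    return SyntheticTruth(
        config=config,
        seed=seed,
        species_ids=config.species_ids,
        stage_names=STAGE_NAMES,
        triad_ids=triad_ids,
        gene_ids=gene_ids,
        levels=levels,
        divergent=divergent,
        archetype=archetype,
        category_map=category_map,
    )


def _depth_table(
    truth: SyntheticTruth, depth: float | Mapping[str, Mapping[str, float]]
) -> dict[str, pd.Series]:
    out: dict[str, pd.Series] = {}
    for sp in truth.species_ids:
        if isinstance(depth, Mapping):
            if sp not in depth:
                raise ValueError(f"missing depth for species {sp!r}")
            row = depth[sp]
            missing = [s for s in truth.stage_names if s not in row]
            if missing:
                raise ValueError(f"missing depth for samples {sp}:{missing}")
            series = pd.Series(
                [float(row[s]) for s in truth.stage_names], index=truth.stage_names
            )
        else:
            series = pd.Series(
                float(depth), index=list(truth.stage_names), dtype=float
            )
        if (series <= 0).any():
            raise ValueError(f"non-positive depth for species {sp!r}")
        out[sp] = series
    return out


def simulate_counts(
    truth: SyntheticTruth,
    depth: float | Mapping[str, Mapping[str, float]] = 2e7,
    seed: int = 0,
) -> CountDataset:
    """Draw Poisson tag counts with mean ``depth x true_level`` per sample.

    ``depth`` is either one library size for every sample or a nested
    ``species -> stage -> size`` mapping.  With ``nb_dispersion`` set in
    the config, counts are gamma-Poisson (negative binomial) instead.
    """
    depths = _depth_table(truth, depth)
    counts: dict[str, pd.DataFrame] = {}
    libs: dict[str, pd.Series] = {}
    shape = truth.config.nb_dispersion
    for sp in truth.species_ids:
        rng = _sub_rng(seed, f"counts:{sp}")
        lam = truth.levels[sp].to_numpy() * depths[sp].to_numpy()[None, :]
        if shape is not None:
            lam = rng.gamma(shape, lam / shape)
        counts[sp] = pd.DataFrame(
            rng.poisson(lam),
            index=truth.gene_ids[sp],
            columns=list(truth.stage_names),
        )
        libs[sp] = depths[sp].round().astype(np.int64)
    return CountDataset(counts, libs)


def _emit_hit_table(
    truth: SyntheticTruth,
    sp_q: str,
    sp_s: str,
    rng: np.random.Generator,
    n_decoys: int,
    p_superthreshold: float,
    path: Path,
) -> None:
    n = truth.n_genes
    q_ids = truth.gene_ids[sp_q]
    s_ids = truth.gene_ids[sp_s]
    rows: list[tuple] = []

    def row(q: str, s: str, evalue: float, bitscore: float) -> tuple:
        pident = float(np.round(rng.uniform(60.0, 99.9), 1))
        length = int(rng.integers(150, 600))
        mismatch = int(rng.integers(0, 40))
        return (
            q, s, pident, length, mismatch, 0, 1, length, 1, length,
            float(f"{evalue:.2e}"), float(np.round(bitscore, 1)),
        )

    for i in range(n):
        true_bit = float(rng.uniform(350.0, 900.0))
        rows.append(row(q_ids[i], s_ids[i], 1e-180 * 10 ** rng.uniform(0, 40), true_bit))
        if n > 1 and n_decoys > 0:
            k = min(n_decoys, n - 1)
            others = rng.choice(np.setdiff1d(np.arange(n), [i]), size=k, replace=False)
            for j in others:
                rows.append(
                    row(
                        q_ids[i],
                        s_ids[int(j)],
                        10.0 ** rng.uniform(-40, -6),
                        true_bit * rng.uniform(0.3, 0.8),
                    )
                )
        if rng.random() < p_superthreshold and n > 1:
            j = int(rng.choice(np.setdiff1d(np.arange(n), [i])))
            # stronger bitscore but e-value above the cutoff: must be filtered out
            rows.append(row(q_ids[i], s_ids[j], 1e-3, true_bit * 1.5))
    pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS)).to_csv(
        path, sep="\t", index=False, header=False
    )


def emit_support_files(
    truth: SyntheticTruth,
    outdir: str | Path,
    n_decoys: int = 2,
    p_superthreshold_decoy: float = 0.1,
    seed: int = 0,
) -> dict[str, Path]:
    """Write triad, similarity-hit and annotation tables for a truth.

    Hit tables are constructed so that reciprocal-best-hit search at the
    default e-value cutoff recovers exactly the true triads: true
    ortholog pairs get mutual top bitscores, decoy hits score strictly
    lower, and optional above-threshold decoys score higher but carry an
    e-value of 1e-3 (> 1e-4) so filtering removes them.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        triad_path = outdir / "triads.tsv"
        write_triads(truth.triads(), triad_path, species_ids=truth.species_ids)
        paths["triads"] = triad_path

        for a in truth.species_ids:
            for b in truth.species_ids:
                if a == b:
                    continue
                rng = _sub_rng(seed, f"hits:{a}:{b}")
                path = outdir / f"hits_{a}_{b}.tsv"
                _emit_hit_table(
                    truth, a, b, rng, n_decoys, p_superthreshold_decoy, path
                )
                paths[f"hits_{a}_{b}"] = path

        ann_path = outdir / "annotation.tsv"
        write_annotation(truth.category_map, ann_path)
        paths["annotation"] = ann_path
        return paths
    except OSError as exc:
        raise OSError(f"cannot write support files to {outdir}: {exc}") from exc
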