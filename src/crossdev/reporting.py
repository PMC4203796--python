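"""Per-gene trajectory reports and the end-to-end pipeline.

``extract_profiles`` produces the long-format table behind per-gene
cross-species trajectory plots (level with 95% credible bounds per
species per stage, joined with cluster label and candidate rank).
``run_pipeline`` chains every stage — count simulation or loading,
credible-interval expression estimation, ortholog triads, matrix
assembly, UPGMA clustering, functional enrichment, CI-gap ranking and the
trajectory report — and writes a plain-text manifest of inputs, seeds,
parameters and output checksums so a run is byte-for-byte reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import pandas as pd
import yaml

from . import clustering, enrichment, orthology, ranking, synthetic
from .expression import ProfileSet, estimate_all, write_profiles
from .io import CountDataset, read_annotation, read_counts, write_counts
from .orthology import OrthologTriad
from .stages import RANKING_STAGE_NAMES, STAGE_INDEX

logger = logging.getLogger("crossdev")

__all__ = [
    "extract_profiles",
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
]


def extract_profiles(
    gene_ids: Sequence[str],
    profiles: ProfileSet,
    triads: Sequence[OrthologTriad],
    species_ids: Sequence[str],
    assignments: Mapping[str, int] | None = None,
    candidate_ranking: ranking.CandidateRanking | None = None,
) -> pd.DataFrame:
    """Long-format trajectory table for a set of genes.

    ``gene_ids`` may be triad ids or any member species' gene ids; each
    is resolved through the triad map.  One row per (gene, species,
    stage) with level and credible bounds, plus cluster label and
    candidate rank where available (empty otherwise).  Unknown ids raise
    a ``ValueError`` listing all offenders.
    """
    by_any_id: dict[str, OrthologTriad] = {}
    for triad in triads:
        by_any_id[triad.triad_id] = triad
        for gene in triad.genes:
            by_any_id[gene] = triad
    unknown = [g for g in gene_ids if g not in by_any_id]
    if unknown:
        raise ValueError(f"unknown gene ids (not in triad map): {unknown}")

    rank_of: dict[str, int] = {}
    if candidate_ranking is not None:
        rank_of = {r.triad_id: r.rank for r in candidate_ranking.rows}
    assignments = assignments or {}

    rows: list[tuple] = []
    for gid in gene_ids:
        triad = by_any_id[gid]
        cluster = assignments.get(triad.triad_id)
        rank = rank_of.get(triad.triad_id)
        for sp, gene in zip(species_ids, triad.genes):
            if (sp, gene) not in profiles:
                continue
            prof = profiles.get(sp, gene)
            for i, stage in enumerate(prof.stages):
                rows.append(
                    (
                        triad.triad_id,
                        gene,
                        sp,
                        stage,
                        prof.level[i],
                        prof.ci_lo[i],
                        prof.ci_hi[i],
                        cluster if cluster is not None else "",
                        rank if rank is not None else "",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "triad_id",
            "gene_id",
            "species",
            "stage",
            "level",
            "ci_lo",
            "ci_hi",
            "cluster",
            "rank",
        ],
    )


def plot_profiles(report: pd.DataFrame, path: str | Path) -> None:
    """Optional line plot (one panel per gene) of an extract_profiles table.

    Levels are drawn per species with 95% credible error bars.  Requires
    matplotlib (install the ``plots`` extra); the tabular report is the
    tested contract, this rendering is a convenience.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .stages import STAGE_INDEX

    triad_ids = list(dict.fromkeys(report["triad_id"]))
    fig, axes = plt.subplots(
        len(triad_ids), 1, figsize=(6, 2.2 * len(triad_ids)), squeeze=False
    )
    for ax, tid in zip(axes[:, 0], triad_ids):
        sub = report[report["triad_id"] == tid]
        for sp, grp in sub.groupby("species"):
            grp = grp.sort_values("stage", key=lambda s: s.map(STAGE_INDEX))
            ax.errorbar(
                grp["stage"],
                grp["level"],
                yerr=[grp["level"] - grp["ci_lo"], grp["ci_hi"] - grp["level"]],
                label=sp,
                capsize=2,
            )
        ax.set_title(tid, fontsize=9)
        ax.set_ylabel("relative level")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    Either ``generation`` is set (synthetic mode: counts and support
    files are generated) or the input paths point at existing tables.
    """

    generation: synthetic.GenerationConfig | None = None
    depth: float = 2e7
    counts_path: str | None = None
    library_size_path: str | None = None
    triads_path: str | None = None
    annotation_path: str | None = None
    species_ids: tuple[str, str, str] | None = None
    n_draws: int = 10_000
    k_clusters: int = 8
    m_candidates: int = ranking.DEFAULT_M
    mode: str = "all-pairs"
    focal_species: str | None = None
    ranking_stages: tuple[str, ...] = RANKING_STAGE_NAMES
    score_stat: str = "max"
    e_threshold: float = orthology.E_THRESHOLD_DEFAULT
    #: rebuild triads from the similarity-hit tables via reciprocal best
    #: hits instead of trusting the triad table (synthetic mode exercises
    #: the orthology stage this way)
    use_rbh: bool = False
    hits_dir: str | None = None
    report_top: int = 8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generation", None)
        config = cls(**{k: v for k, v in raw.items()})
        if gen is not None:
            gen = {
                k: tuple(v) if isinstance(v, list) else v for k, v in gen.items()
            }
            config.generation = synthetic.GenerationConfig(**gen)
        if config.species_ids is not None:
            config.species_ids = tuple(config.species_ids)
        config.ranking_stages = tuple(config.ranking_stages)
        return config

    def flat_items(self) -> list[tuple[str, str]]:
        """Deterministic key=value flattening for the manifest."""
        out: list[tuple[str, str]] = []

        def emit(prefix: str, obj: Any) -> None:
            if hasattr(obj, "__dataclass_fields__"):
                for key, val in sorted(asdict(obj).items()):
                    emit(f"{prefix}.{key}" if prefix else key, val)
            elif isinstance(obj, dict):
                for key in sorted(obj):
                    emit(f"{prefix}.{key}", obj[key])
            else:
                out.append((prefix, repr(obj)))

        emit("", self)
        return out


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    outdir: Path
    artifacts: dict[str, Path]
    profiles: ProfileSet
    triads: list[OrthologTriad]
    assignments: dict[str, int]
    enrichment: list[enrichment.EnrichmentResult]
    ranking: ranking.CandidateRanking
    manifest_path: Path


@contextmanager
def _stage(name: str) -> Iterator[None]:
    start = time.perf_counter()
    try:
        yield
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - start)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, seed: int = 0
) -> PipelineResult:
    """Execute estimate -> triads -> matrix -> cluster -> enrich -> rank -> report.

    Writes all artifacts into ``outdir`` plus a ``manifest.txt`` with the
    full configuration, seed and sha256 checksum of every output; the
    manifest is byte-identical across reruns with the same config and
    seed.  Stage timings are logged, not written to the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    truth: synthetic.SyntheticTruth | None = None
    with _stage("counts"):
        if config.generation is not None:
            truth = synthetic.generate_truth(config.generation, seed=seed)
            dataset = synthetic.simulate_counts(truth, depth=config.depth, seed=seed)
            support = synthetic.emit_support_files(truth, outdir, seed=seed)
            artifacts.update(support)
            species_ids = truth.species_ids
            write_counts(dataset, outdir / "counts.tsv", outdir / "library_sizes.tsv")
            artifacts["counts"] = outdir / "counts.tsv"
            artifacts["library_sizes"] = outdir / "library_sizes.tsv"
            annotation = truth.category_map
            triads_path = support["triads"]
        else:
            if not (config.counts_path and config.library_size_path):
                raise ValueError("need counts_path and library_size_path (or generation)")
            dataset = read_counts(config.counts_path, config.library_size_path)
            species_ids = tuple(config.species_ids or dataset.species)
            annotation = (
                read_annotation(config.annotation_path)
                if config.annotation_path
                else {}
            )
            triads_path = Path(config.triads_path) if config.triads_path else None

    with _stage("expression"):
        profiles = estimate_all(dataset, n_draws=config.n_draws, seed=seed)
        write_profiles(profiles, outdir / "profiles.tsv")
        artifacts["profiles"] = outdir / "profiles.tsv"

    with _stage("triads"):
        hits_dir = Path(config.hits_dir) if config.hits_dir else None
        if config.use_rbh or (triads_path is None and hits_dir is not None):
            base = hits_dir or outdir
            a, b, c = species_ids
            hit_tables = [
                orthology.read_hits(base / f"hits_{x}_{y}.tsv")
                for x, y in ((a, b), (b, a), (a, c), (c, a), (b, c), (c, b))
            ]
            triads = orthology.triads_from_hits(
                *hit_tables, e_threshold=config.e_threshold
            )
            # keep the generator's triad ids where membership matches
            if triads_path is not None:
                known = {
                    t.genes: t.triad_id for t in orthology.read_triads(triads_path)
                }
                triads = [
                    orthology.OrthologTriad(known.get(t.genes, t.triad_id), t.genes)
                    for t in triads
                ]
        elif triads_path is not None:
            triads = orthology.read_triads(triads_path)
        else:
            raise ValueError("no triad table or hit tables available")
        if "triads" not in artifacts:
            out_path = outdir / "triads.tsv"
            orthology.write_triads(triads, out_path, species_ids=species_ids)
            artifacts["triads"] = out_path

    with _stage("clustering"):
        matrix = clustering.assemble_matrix(profiles, triads, species_ids)
        zmat = clustering.zscore_rows(matrix)
        dist = clustering.pearson_distance(zmat)
        dend = clustering.upgma(dist, leaf_ids=list(zmat.index))
        assignments = clustering.cut_tree(dend, k=min(config.k_clusters, len(zmat)))
        cl = pd.DataFrame(
            sorted(assignments.items()), columns=["triad_id", "cluster"]
        )
        cl.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        artifacts["clusters"] = outdir / "clusters.tsv"

    with _stage("enrichment"):
        # translate triad ids to the first species' gene ids, the
        # namespace of the annotation table
        gene_of = {t.triad_id: t.genes[0] for t in triads}
        sets: dict[str, list[str]] = {}
        for triad_id, label in assignments.items():
            sets.setdefault(f"cluster_{label}", []).append(gene_of[triad_id])
        universe = [gene_of[t] for t in assignments]
        results = enrichment.enrich_sets(sets, annotation, universe)
        enrichment.results_to_frame(results).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        artifacts["enrichment"] = outdir / "enrichment.tsv"

    with _stage("ranking"):
        pairs = [
            (species_ids[0], species_ids[1]),
            (species_ids[0], species_ids[2]),
            (species_ids[1], species_ids[2]),
        ]
        scores_by_pair = {
            pair: ranking.comparison_scores(
                profiles,
                triads,
                species_ids,
                pair,
                ranking_stages=config.ranking_stages,
                stat=config.score_stat,
            )
            for pair in pairs
        }
        selected = ranking.rank_and_select(
            scores_by_pair,
            m=config.m_candidates,
            mode=config.mode,
            focal_species=config.focal_species,
        )
        ranking.write_ranking(selected, outdir / "ranking.tsv")
        artifacts["ranking"] = outdir / "ranking.tsv"

    with _stage("report"):
        top = [r.triad_id for r in selected.rows[: config.report_top]]
        report = extract_profiles(
            top, profiles, triads, species_ids, assignments, selected
        )
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        artifacts["report"] = outdir / "report.tsv"

    with _stage("manifest"):
        manifest_path = outdir / "manifest.txt"
        lines = [f"seed={seed}"]
        lines += [f"config.{k}={v}" for k, v in config.flat_items()]
        for name in sorted(artifacts):
            lines.append(f"sha256.{name}={_sha256(artifacts[name])}")
        manifest_path.write_text("\n".join(lines) + "\n")

    return PipelineResult(
        outdir=outdir,
        artifacts=artifacts,
        profiles=profiles,
        triads=triads,
        assignments=assignments,
        enrichment=results,
        ranking=selected,
        manifest_path=manifest_path,
    )
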