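"""Single-copy ortholog triads from reciprocal best similarity hits.

Pairwise proteome similarity hits (BLAST outfmt-6-style TSV) are filtered
at an e-value cutoff (default 1e-4), reduced to best hits per query, and a
gene triple (a, b, c) across the three species is kept only when all three
pairwise links are mutual best hits — the complete-family intersection of
reciprocal best hits.  Phylogenetic (gene-tree) refinement of families is
intentionally out of scope; an externally supplied triad TSV can bypass
this stage entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "E_THRESHOLD_DEFAULT",
    "HitRecord",
    "OrthologTriad",
    "read_hits",
    "filter_hits",
    "best_hits",
    "build_triads",
    "triads_from_hits",
    "read_triads",
    "write_triads",
]

#: Default e-value cutoff for retaining similarity hits.
E_THRESHOLD_DEFAULT = 1e-4

#: BLAST tabular (outfmt 6) column names.
OUTFMT6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class HitRecord:
    """One query->subject similarity hit."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")
        if self.bitscore <= 0:
            raise ValueError(f"bitscore must be positive, got {self.bitscore}")


@dataclass(frozen=True)
class OrthologTriad:
    """One single-copy ortholog family: exactly one gene per species."""

    triad_id: str
    genes: tuple[str, str, str]


def read_hits(path: str | Path) -> list[HitRecord]:
    """Parse an outfmt-6-style TSV into hit records.

    Malformed rows raise a ``ValueError`` naming the 1-based line number.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return hits


def filter_hits(
    hits: Iterable[HitRecord], e_threshold: float = E_THRESHOLD_DEFAULT
) -> list[HitRecord]:
    """Keep hits with ``evalue <= e_threshold``; deduplicate (query, subject).

    Duplicated (query, subject) pairs keep the record with the best
    (largest) bitscore, ties resolved to the smaller e-value.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for hit in hits:
        if hit.evalue > e_threshold:
            continue
        key = (hit.query_id, hit.subject_id)
        prev = best.get(key)
        if (
            prev is None
            or hit.bitscore > prev.bitscore
            or (hit.bitscore == prev.bitscore and hit.evalue < prev.evalue)
        ):
            best[key] = hit
    return [best[k] for k in sorted(best)]


def best_hits(hits: Iterable[HitRecord]) -> dict[str, str]:
    """Best subject per query: max bitscore, then min e-value, then
    lexicographically smallest subject id."""
    chosen: dict[str, HitRecord] = {}
    for hit in hits:
        prev = chosen.get(hit.query_id)
        if (
            prev is None
            or hit.bitscore > prev.bitscore
            or (hit.bitscore == prev.bitscore and hit.evalue < prev.evalue)
            or (
                hit.bitscore == prev.bitscore
                and hit.evalue == prev.evalue
                and hit.subject_id < prev.subject_id
            )
        ):
            chosen[hit.query_id] = hit
    return {q: h.subject_id for q, h in chosen.items()}


def _reciprocal(fwd: Mapping[str, str], rev: Mapping[str, str], a: str) -> str | None:
    """Return fwd[a] if (a, fwd[a]) is a mutual best pair, else None."""
    b = fwd.get(a)
    if b is not None and rev.get(b) == a:
        return b
    return None


def build_triads(
    bh_ab: Mapping[str, str],
    bh_ba: Mapping[str, str],
    bh_ac: Mapping[str, str],
    bh_ca: Mapping[str, str],
    bh_bc: Mapping[str, str],
    bh_cb: Mapping[str, str],
) -> list[OrthologTriad]:
    """Intersect reciprocal best pairs into complete three-species families.

    (a, b, c) is a triad iff a<->b, a<->c and b<->c are each reciprocal
    best-hit pairs.  Triads are sorted by the species-1 gene id and
    numbered sequentially; RBH uniqueness guarantees each gene appears in
    at most one triad.
    """
    triads: list[tuple[str, str, str]] = []
    for a in sorted(bh_ab):
        b = _reciprocal(bh_ab, bh_ba, a)
        if b is None:
            continue
        c = _reciprocal(bh_ac, bh_ca, a)
        if c is None:
            continue
        if _reciprocal(bh_bc, bh_cb, b) != c:
            continue
        triads.append((a, b, c))
    width = max(5, len(str(len(triads))))
    return [
        OrthologTriad(triad_id=f"tri{i:0{width}d}", genes=genes)
        for i, genes in enumerate(triads)
    ]


def triads_from_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    hits_ac: Iterable[HitRecord],
    hits_ca: Iterable[HitRecord],
    hits_bc: Iterable[HitRecord],
    hits_cb: Iterable[HitRecord],
    e_threshold: float = E_THRESHOLD_DEFAULT,
) -> list[OrthologTriad]:
    """Filter six directed hit tables and build the triad list."""
    maps = [
        best_hits(filter_hits(h, e_threshold))
        for h in (hits_ab, hits_ba, hits_ac, hits_ca, hits_bc, hits_cb)
    ]
    return build_triads(*maps)


def read_triad_species(path: str | Path) -> tuple[str, ...]:
    """Species order encoded in a triad TSV header (``gene_<species>``)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != 4:
        raise ValueError(f"{path}: triad table must have 4 columns, got {len(header)}")
    return tuple(
        col[5:] if col.startswith("gene_") else col for col in header[1:]
    )


def read_triads(path: str | Path) -> list[OrthologTriad]:
    """Read a triad TSV: ``triad_id  gene_sp1  gene_sp2  gene_sp3``."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] != 4:
        raise ValueError(
            f"{path}: triad table must have 4 columns (triad_id + 3 genes), "
            f"got {table.shape[1]}"
        )
    out = [
        OrthologTriad(triad_id=row[0], genes=(row[1], row[2], row[3]))
        for row in table.itertuples(index=False)
    ]
    seen: set[str] = set()
    for triad in out:
        for gene in triad.genes:
            if gene in seen:
                raise ValueError(f"{path}: gene {gene!r} appears in more than one triad")
            seen.add(gene)
    return out


def write_triads(
    triads: Sequence[OrthologTriad],
    path: str | Path,
    species_ids: Sequence[str] = ("sp1", "sp2", "sp3"),
) -> None:
    rows = [(t.triad_id, *t.genes) for t in triads]
    cols = ["triad_id"] + [f"gene_{sp}" for sp in species_ids]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
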