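"""Tabular input/output and the tag-count container.

All interchange formats are tab-separated text:

* counts: long format with header ``species  gene_id  stage  count``
* library sizes: ``species  stage  library_size``
* functional annotation: ``gene_id  category_id`` (one row per assignment)
* expression profiles: long format, one row per (species, gene, stage)

Ortholog-triad and similarity-hit tables live in :mod:`crossdev.orthology`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .stages import order_stages

logger = logging.getLogger("crossdev")

__all__ = [
    "CountDataset",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_profiles_table",
]


@dataclass
class CountDataset:
    """Per-gene tag counts for several species across developmental stages.

    Parameters
    ----------
    counts
        ``species -> (genes x stages)`` integer DataFrame.  Within one
        species every stage sample covers the same gene set.
    library_size
        ``species -> per-stage`` positive totals of mapped tags.  This is
        an independent normalizer; it need not equal the column sums.
    """

    counts: dict[str, pd.DataFrame] = field(default_factory=dict)
    library_size: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def species(self) -> list[str]:
        return list(self.counts)

    def stages(self, species: str) -> list[str]:
        return list(self.counts[species].columns)

    def genes(self, species: str) -> list[str]:
        return list(self.counts[species].index)

    def validate(self) -> None:
        if set(self.counts) != set(self.library_size):
            raise ValueError("counts and library_size must cover the same species")
        for sp, mat in self.counts.items():
            vals = mat.to_numpy()
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.allclose(vals, np.round(vals)):
                    raise ValueError(f"non-integer counts for species {sp!r}")
                self.counts[sp] = mat.astype(np.int64)
                vals = self.counts[sp].to_numpy()
            if (vals < 0).any():
                raise ValueError(f"negative counts for species {sp!r}")
            stages = order_stages(mat.columns)
            self.counts[sp] = self.counts[sp][stages]
            lib = self.library_size[sp]
            if set(lib.index) != set(stages):
                raise ValueError(
                    f"library sizes for species {sp!r} do not match count stages"
                )
            lib = lib[stages].astype(np.int64)
            if (lib <= 0).any():
                raise ValueError(f"non-positive library size for species {sp!r}")
            self.library_size[sp] = lib

    def to_long(self) -> pd.DataFrame:
        frames = []
        for sp, mat in self.counts.items():
            long = mat.reset_index(names="gene_id").melt(
                id_vars="gene_id", var_name="stage", value_name="count"
            )
            long.insert(0, "species", sp)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(
        cls, counts: pd.DataFrame, library_size: pd.DataFrame
    ) -> "CountDataset":
        required = {"species", "gene_id", "stage", "count"}
        if not required.issubset(counts.columns):
            raise ValueError(f"counts table needs columns {sorted(required)}")
        lib_required = {"species", "stage", "library_size"}
        if not lib_required.issubset(library_size.columns):
            raise ValueError(f"library-size table needs columns {sorted(lib_required)}")
        count_map: dict[str, pd.DataFrame] = {}
        lib_map: dict[str, pd.Series] = {}
        for sp, sub in counts.groupby("species", sort=True):
            mat = sub.pivot_table(
                index="gene_id", columns="stage", values="count", aggfunc="sum"
            )
            if mat.isna().any().any():
                missing = int(mat.isna().sum().sum())
                raise ValueError(
                    f"species {sp!r}: {missing} missing (gene, stage) count cells"
                )
            count_map[str(sp)] = mat.astype(np.int64)
        for sp, sub in library_size.groupby("species", sort=True):
            lib_map[str(sp)] = pd.Series(
                sub["library_size"].to_numpy(), index=sub["stage"].to_numpy()
            )
        return cls(count_map, lib_map)


def read_counts(counts_path: str | Path, library_size_path: str | Path) -> CountDataset:
    """Read a long-format count TSV plus its library-size TSV."""
    counts = pd.read_csv(counts_path, sep="\t")
    lib = pd.read_csv(library_size_path, sep="\t")
    return CountDataset.from_long(counts, lib)


def write_counts(
    dataset: CountDataset, counts_path: str | Path, library_size_path: str | Path
) -> None:
    long = dataset.to_long()
    long.to_csv(counts_path, sep="\t", index=False)
    rows = []
    for sp in dataset.species:
        for stage, size in dataset.library_size[sp].items():
            rows.append((sp, stage, int(size)))
    pd.DataFrame(rows, columns=["species", "stage", "library_size"]).to_csv(
        library_size_path, sep="\t", index=False
    )


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a ``gene_id<TAB>category_id`` table into a gene -> categories map."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "category_id"}.issubset(table.columns):
        raise ValueError("annotation table needs columns gene_id, category_id")
    out: dict[str, set[str]] = {}
    for gene, cat in zip(table["gene_id"], table["category_id"]):
        out.setdefault(gene, set()).add(cat)
    return out


def write_annotation(category_map: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [
        (gene, cat)
        for gene in sorted(category_map)
        for cat in sorted(category_map[gene])
    ]
    pd.DataFrame(rows, columns=["gene_id", "category_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format profile TSV written by :func:`crossdev.expression.write_profiles`."""
    table = pd.read_csv(path, sep="\t")
    required = {
        "species",
        "gene_id",
        "stage",
        "level",
        "ci_lo",
        "ci_hi",
        "reference_stage",
        "uninformative",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    return table
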