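"""Canonical developmental stage grid.

Sexual development is sampled at eight stages: mature protoperithecia just
before crossing (``BC``, hour 0) and 2, 24, 48, 72, 96, 120 and 144 hours
after fertilization.  All tabular layouts in this package order stages by
this grid.  Candidate ranking by default uses only the six post-crossing
stages 2–144 h (120 h excluded); see :mod:`crossdev.ranking`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "StageLabel",
    "CANONICAL_STAGES",
    "STAGE_NAMES",
    "STAGE_INDEX",
    "RANKING_STAGE_NAMES",
    "order_stages",
]


@dataclass(frozen=True)
class StageLabel:
    """A named developmental stage with its time in hours after crossing."""

    name: str
    hours: float

    def __post_init__(self) -> None:
        if self.hours < 0:
            raise ValueError(f"stage hours must be non-negative, got {self.hours}")


CANONICAL_STAGES: tuple[StageLabel, ...] = (
    StageLabel("BC", 0.0),
    StageLabel("2h", 2.0),
    StageLabel("24h", 24.0),
    StageLabel("48h", 48.0),
    StageLabel("72h", 72.0),
    StageLabel("96h", 96.0),
    StageLabel("120h", 120.0),
    StageLabel("144h", 144.0),
)

STAGE_NAMES: tuple[str, ...] = tuple(s.name for s in CANONICAL_STAGES)
STAGE_INDEX: dict[str, int] = {s.name: i for i, s in enumerate(CANONICAL_STAGES)}

#: Stages used for the cross-species CI-gap screen (post-crossing, 120h excluded).
RANKING_STAGE_NAMES: tuple[str, ...] = ("2h", "24h", "48h", "72h", "96h", "144h")


def order_stages(names: Iterable[str]) -> list[str]:
    """Return ``names`` sorted into canonical stage order.

    Raises
    ------
    ValueError
        If a name is not one of the eight canonical stage labels.
    """
    names = list(names)
    unknown = [n for n in names if n not in STAGE_INDEX]
    if unknown:
        raise ValueError(f"unknown stage labels: {unknown}; expected one of {STAGE_NAMES}")
    if len(set(names)) != len(names):
        raise ValueError("duplicate stage labels")
    return sorted(names, key=STAGE_INDEX.__getitem__)


def validate_stage_subset(names: Sequence[str]) -> tuple[str, ...]:
    """Validate and canonically order a stage subset, returned as a tuple."""
    return tuple(order_stages(names))
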