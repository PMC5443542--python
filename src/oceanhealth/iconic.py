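"""Iconic-species subgoal: range-weighted risk scoring of COSEWIC statuses."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import clamp

# Risk weight per COSEWIC status category.
DEFAULT_RISK_WEIGHTS: dict[str, float] = {
    "Not Assessed": 0.0,
    "Non-active": 0.0,
    "Data Deficient": 0.0,
    "Not at Risk": 0.0,
    "Special Concern": 0.2,
    "Threatened": 0.4,
    "Endangered": 0.6,
    "Extinct": 1.0,
    "Extirpated": 1.0,
}

__all__ = [
    "DEFAULT_RISK_WEIGHTS",
    "SpeciesRecord",
    "risk_weight",
    "ico_status",
    "ico_trend",
]


@dataclass(frozen=True)
class SpeciesRecord:
    common_name: str
    scientific_name: str
    cosewic_status: str
    range_weight: float = 1.0
    in_original_ohi: bool = False

    def __post_init__(self) -> None:
        if self.range_weight < 0:
            raise ValueError(f"range_weight must be >= 0, got {self.range_weight!r}")


def risk_weight(
    status: str, table: Mapping[str, float] = DEFAULT_RISK_WEIGHTS
) -> float:
    """Risk weight (0-1) for a COSEWIC status category."""
    try:
        return table[status]
    except KeyError:
        valid = ", ".join(sorted(table))
        raise ValueError(
            f"unknown COSEWIC status {status!r}; valid categories: {valid}"
        ) from None


def ico_status(
    records: Sequence[SpeciesRecord],
    table: Mapping[str, float] = DEFAULT_RISK_WEIGHTS,
) -> float:
    """Range-weighted mean of (1 - risk), scaled to 0-100."""
    if len(records) == 0:
        raise ValueError("need at least one species record")
    w = np.asarray([r.range_weight for r in records], dtype=float)
    if w.sum() == 0:
        raise ValueError("all range weights are zero")
    risk = np.asarray([risk_weight(r.cosewic_status, table) for r in records])
    return float(100.0 * (w * (1.0 - risk)).sum() / w.sum())


def ico_trend(
    current: float, previous: float, years_between: int, window: int = 5
) -> float:
    """Proportional status change rescaled to the engine's trend window.

    (current - previous)/100 per ``years_between`` years, expressed as total
    change over ``window`` years and clamped to [-1, 1].
    """
    for name, v in (("current", current), ("previous", previous)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must be in [0, 100], got {v!r}")
    if years_between <= 0:
        raise ValueError(f"years_between must be > 0, got {years_between!r}")
    return clamp((current - previous) / 100.0 / years_between * window, -1.0, 1.0)
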