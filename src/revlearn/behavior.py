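"""Behavioral preference indices from quadrant-assay fly counts.

In the four-quadrant two-odor choice arena, avoidance of the shocked odor is
quantified as

    AI = (N_CS- - N_CS+) / (N_CS- + N_CS+)

so AI = 1 means every fly chose CS- quadrants and AI = 0 an even split.
Reciprocal cohorts (odor identities swapped) are averaged to cancel innate
odor bias.  The innate red-light preference assay uses the same arithmetic
over illuminated versus dark quadrants, averaged over the two alternating
illumination configurations to cancel place preference.

Flies that cannot be assigned to a quadrant class (e.g. sitting on a border)
are excluded from both counts: the denominator is classified flies only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError
from .simulate import QuadrantCounts

__all__ = [
    "PreferenceIndex",
    "avoidance_index",
    "reciprocal_balance",
    "light_preference_index",
    "single_fly_preference",
]


@dataclass(frozen=True)
class PreferenceIndex:
    """A dimensionless preference score in [-1, 1]."""

    value: float
    kind: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"preference index {self.value} outside [-1, 1]")

    def __float__(self) -> float:
        return self.value


def _pair(counts) -> tuple[int, int]:
    """Extract (first-class, second-class) counts from QuadrantCounts or a pair."""
    if isinstance(counts, QuadrantCounts):
        return counts.n_csplus, counts.n_csminus
    a, b = counts
    return int(a), int(b)


def avoidance_index(counts: QuadrantCounts | tuple[int, int]) -> PreferenceIndex:
    """CS+ avoidance: (N_CS- - N_CS+) / total classified flies."""
    n_plus, n_minus = _pair(counts)
    if n_plus < 0 or n_minus < 0:
        raise ValueError("counts must be non-negative")
    total = n_plus + n_minus
    if total == 0:
        raise UndefinedIndexError("avoidance index undefined for zero flies")
    return PreferenceIndex(value=(n_minus - n_plus) / total, kind="avoidance")


def reciprocal_balance(
    index_a: PreferenceIndex | float, index_b: PreferenceIndex | float
) -> PreferenceIndex:
    """Average the indices of two reciprocally trained cohorts."""
    return PreferenceIndex(
        value=0.5 * (float(index_a) + float(index_b)), kind="balanced"
    )


def light_preference_index(
    configs: Sequence[QuadrantCounts | tuple[int, int]],
) -> PreferenceIndex:
    """Red-light preference averaged over illumination configurations.

    Each configuration contributes (N_light - N_dark) / total; the per-
    configuration values are averaged (the two alternating diagonal
    illumination patterns cancel place preference).  Counts are passed as
    ``(n_light, n_dark)`` pairs (or QuadrantCounts with n_csplus = n_light).
    """
    if len(configs) == 0:
        raise UndefinedIndexError("need at least one quadrant configuration")
    values = []
    for counts in configs:
        n_light, n_dark = _pair(counts)
        if n_light < 0 or n_dark < 0:
            raise ValueError("counts must be non-negative")
        total = n_light + n_dark
        if total == 0:
            raise UndefinedIndexError(
                "light preference undefined for a zero-fly configuration"
            )
        values.append((n_light - n_dark) / total)
    return PreferenceIndex(value=float(np.mean(values)), kind="light_preference")


def single_fly_preference(track: Sequence[str]) -> tuple[float, float]:
    """Percent of time one fly spent in CS+ versus CS- quadrants.

    ``track`` is a per-frame sequence of quadrant labels ("CSplus",
    "CSminus", or anything else for unclassified frames); frame counts proxy
    time at a fixed frame rate.  Returns ``(pct_csplus, pct_csminus)``; the
    two sum to 100 when every frame is labeled.
    """
    labels = pd.Series(list(track))
    if labels.empty:
        raise UndefinedIndexError("empty track")
    n = len(labels)
    pct_plus = 100.0 * float((labels == "CSplus").sum()) / n
    pct_minus = 100.0 * float((labels == "CSminus").sum()) / n
    return pct_plus, pct_minus
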