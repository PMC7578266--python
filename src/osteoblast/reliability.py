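"""Per-spot reliability scoring (SR 1-6).

Each spot's technical replicates yield two dimensionless quality
parameters: P1 = sd/mean (a coefficient of variation) and P2 =
mean/median (a skew indicator).  Each parameter is banded High /
Medium / Low and the pair is combined into the integer SR score via a
fixed symmetric lookup: the tighter the replicates, the higher the SR,
with 6 best and 1 worst.

Band boundaries (half-open choices documented in :func:`classify_p1`
and :func:`classify_p2`):

* P1: High below 0.20, Medium below 0.50, Low otherwise.
* P2: High inside (0.80, 1.20), Medium inside (0.70, 1.40) but outside
  the High band, Low otherwise.

A spot whose mean (for P1) or median (for P2) is zero has an undefined
ratio and is banded Low with a warning - an all-zero spot is maximally
unreliable, never an exception.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from osteoblast.chip_io import IntensityDataset

logger = logging.getLogger(__name__)


class Level(str, enum.Enum):
    HIGH = "High"
    MEDIUM = "Medium"
    LOW = "Low"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Symmetric (level_P1, level_P2) -> SR lookup.
SR_TABLE: dict[tuple[Level, Level], int] = {
    (Level.HIGH, Level.HIGH): 6,
    (Level.HIGH, Level.MEDIUM): 5,
    (Level.MEDIUM, Level.HIGH): 5,
    (Level.HIGH, Level.LOW): 4,
    (Level.LOW, Level.HIGH): 4,
    (Level.MEDIUM, Level.MEDIUM): 3,
    (Level.MEDIUM, Level.LOW): 2,
    (Level.LOW, Level.MEDIUM): 2,
    (Level.LOW, Level.LOW): 1,
}

SR_MIN = min(SR_TABLE.values())
SR_MAX = max(SR_TABLE.values())


@dataclass(frozen=True)
class SpotReliability:
    """Reliability summary of one spot within one group."""

    spot_id: str
    A: float
    M: float
    sd: float
    P1: float  # sd / A; NaN when A == 0
    P2: float  # A / M; NaN when M == 0
    level_P1: Level
    level_P2: Level
    SR: int


def spot_statistics(values: Sequence[float]) -> tuple[float, float, float]:
    """Return (mean, median, sample sd) of a replicate vector.

    The median of an even-length vector is the mean of the two central
    order statistics; the standard deviation uses the n-1 denominator.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"need >= 2 replicate values, got shape {arr.shape}")
    return float(arr.mean()), float(np.median(arr)), float(arr.std(ddof=1))


def classify_p1(p1: float) -> Level:
    """Band the CV parameter: High < 0.20 <= Medium < 0.50 <= Low."""
    if not np.isfinite(p1) or p1 < 0:
        raise ValueError(f"P1 must be finite and >= 0, got {p1}")
    if p1 < 0.20:
        return Level.HIGH
    if p1 < 0.50:
        return Level.MEDIUM
    return Level.LOW


def classify_p2(p2: float) -> Level:
    """Band the mean/median parameter.

    High strictly inside (0.80, 1.20); Medium strictly inside
    (0.70, 1.40) but outside the High band (the shared boundary points
    0.80 and 1.20 fall to Medium); Low everywhere else.
    """
    if not np.isfinite(p2):
        raise ValueError(f"P2 must be finite, got {p2}")
    if 0.80 < p2 < 1.20:
        return Level.HIGH
    if 0.70 < p2 < 1.40:
        return Level.MEDIUM
    return Level.LOW


def sr_score(level_p1: Level, level_p2: Level) -> int:
    """Combine the two band levels into the integer SR score (1-6)."""
    return SR_TABLE[(Level(level_p1), Level(level_p2))]


def score_spot(spot_id: str, values: Sequence[float]) -> SpotReliability:
    """Score one spot's replicate vector."""
    A, M, sd = spot_statistics(values)
    if A == 0.0:
        logger.warning("spot %s: mean is 0, P1 undefined -> Low", spot_id)
        p1, level_p1 = float("nan"), Level.LOW
    else:
        p1 = sd / A
        level_p1 = classify_p1(p1)
    if M == 0.0:
        logger.warning("spot %s: median is 0, P2 undefined -> Low", spot_id)
        p2, level_p2 = float("nan"), Level.LOW
    else:
        p2 = A / M
        level_p2 = classify_p2(p2)
    return SpotReliability(
        spot_id=spot_id,
        A=A,
        M=M,
        sd=sd,
        P1=p1,
        P2=p2,
        level_P1=level_p1,
        level_P2=level_p2,
        SR=sr_score(level_p1, level_p2),
    )


def score_dataset(dataset: IntensityDataset, group: str) -> list[SpotReliability]:
    """Score every spot of one group across its technical replicates."""
    matrix = dataset.group_matrix(group)
    return [
        score_spot(spot_id, matrix[i, :])
        for i, spot_id in enumerate(dataset.spot_ids)
    ]


def sr_histogram(scores: Sequence[SpotReliability]) -> dict[int, int]:
    """Count spots per SR value over the full 1..6 range."""
    counts = {sr: 0 for sr in range(SR_MIN, SR_MAX + 1)}
    for s in scores:
        counts[s.SR] += 1
    return counts


def select_common_spots(
    scores_a: Sequence[SpotReliability],
    scores_b: Sequence[SpotReliability],
    sr_level: int,
) -> list[str]:
    """Spot IDs scored at ``sr_level`` in BOTH groups, in A's (layout) order."""
    if sr_level not in range(SR_MIN, SR_MAX + 1):
        raise ValueError(f"sr_level must be in {SR_MIN}..{SR_MAX}, got {sr_level}")
    at_level_b = {s.spot_id for s in scores_b if s.SR == sr_level}
    return [s.spot_id for s in scores_a if s.SR == sr_level and s.spot_id in at_level_b]
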