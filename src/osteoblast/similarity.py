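"""Pairwise chi similarity between surfaces over common reliable spots.

For a pair of groups sharing N spots, with per-spot mean intensities
I0/It and standard deviations sigma0/sigmat (model and test group
respectively), the statistic is

    chi = sqrt( (1/N) * sum_i ((I0[i] - It[i]) / (1 - |sigma0[i] - sigmat[i]|))**2 )

i.e. the root of the equation's mean-square form; ``squared=True``
exposes the un-rooted value.  Identical profiles give chi = 0 and the
statistic is symmetric in its two arguments.

Profiles are built from jointly quantile-normalized replicate matrices
rescaled by the pair's global maximum, so all intensities lie in [0, 1]
and the denominator 1 - |sigma0 - sigmat| is always positive.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from osteoblast.chip_io import IntensityDataset
from osteoblast.diffphos import quantile_normalize
from osteoblast.reliability import SpotReliability, select_common_spots

logger = logging.getLogger(__name__)


class ChiScalingError(ValueError):
    """Denominator 1 - |sigma0 - sigmat| fell to zero or below."""


@dataclass(frozen=True)
class GroupProfile:
    """Per-spot mean and sd of one group's (normalized) intensities."""

    spot_ids: tuple[str, ...]
    I: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        I = np.asarray(self.I, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if I.shape != (len(self.spot_ids),) or sigma.shape != I.shape:
            raise ValueError("I and sigma must be 1-D with one entry per spot_id")
        if (sigma < 0).any():
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "spot_ids", tuple(self.spot_ids))
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "sigma", sigma)


@dataclass
class SimilarityMatrix:
    """Square chi matrix over groups at one SR level (NaN = no common spots)."""

    group_labels: list[str]
    sr_level: int
    chi: np.ndarray
    n_spots_used: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        """Heatmap-ready long format: one row per unordered group pair."""
        rows = []
        for i, j in itertools.combinations(range(len(self.group_labels)), 2):
            rows.append(
                {
                    "group_a": self.group_labels[i],
                    "group_b": self.group_labels[j],
                    "sr": self.sr_level,
                    "n_spots": int(self.n_spots_used[i, j]),
                    "chi": self.chi[i, j],
                }
            )
        return pd.DataFrame(rows, columns=["group_a", "group_b", "sr", "n_spots", "chi"])

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.chi, index=self.group_labels, columns=self.group_labels)


def compute_chi(
    model: GroupProfile, test: GroupProfile, squared: bool = False
) -> float:
    """Evaluate the chi similarity statistic between two aligned profiles.

    Raises
    ------
    ValueError
        If the profiles are empty or their spot orderings differ.
    ChiScalingError
        If any spot's denominator is <= 0 (sigma difference >= 1);
        rescale intensities before calling (see :func:`build_pair_profiles`).
    """
    if model.spot_ids != test.spot_ids:
        raise ValueError("profiles must share the same spot_ids in the same order")
    n = len(model.spot_ids)
    if n == 0:
        raise ValueError("cannot compute chi over zero spots")
    denom = 1.0 - np.abs(model.sigma - test.sigma)
    if (denom <= 0).any():
        offenders = [s for s, d in zip(model.spot_ids, denom) if d <= 0]
        raise ChiScalingError(
            f"sigma difference >= 1 for spots {offenders}; intensities must be "
            "rescaled so that |sigma0 - sigmat| < 1"
        )
    chi_sq = float(np.mean(((model.I - test.I) / denom) ** 2))
    return chi_sq if squared else float(np.sqrt(chi_sq))


def build_pair_profiles(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    spot_ids: list[str],
    normalize: bool = True,
) -> tuple[GroupProfile, GroupProfile]:
    """Quantile-normalize a pair of replicate matrices jointly, rescale by
    their global maximum, and summarize each as a :class:`GroupProfile`.

    Rescaling maps everything into [0, 1], which bounds every sample sd
    below 1 and keeps the chi denominator positive.  With
    ``normalize=False`` the matrices are only rescaled.
    """
    mat_a = np.asarray(mat_a, dtype=float)
    mat_b = np.asarray(mat_b, dtype=float)
    if mat_a.shape[0] != len(spot_ids) or mat_b.shape[0] != len(spot_ids):
        raise ValueError("matrix rows must match spot_ids")
    if normalize:
        joint = quantile_normalize(np.hstack([mat_a, mat_b]))
        mat_a, mat_b = joint[:, : mat_a.shape[1]], joint[:, mat_a.shape[1]:]
    peak = max(mat_a.max(initial=0.0), mat_b.max(initial=0.0))
    if peak > 0:
        logger.debug("rescaling pair by global maximum %.6g", peak)
        mat_a = mat_a / peak
        mat_b = mat_b / peak

    def _profile(mat: np.ndarray) -> GroupProfile:
        return GroupProfile(
            spot_ids=tuple(spot_ids),
            I=mat.mean(axis=1),
            sigma=mat.std(axis=1, ddof=1),
        )

    return _profile(mat_a), _profile(mat_b)


def pairwise_similarity(
    dataset: IntensityDataset,
    scores: dict[str, list[SpotReliability]],
    sr_level: int = 6,
    squared: bool = False,
) -> SimilarityMatrix:
    """Chi between every unordered group pair over pair-specific common spots.

    Each pair selects its own common SR-level spot set, normalizes it
    jointly, and evaluates chi.  Pairs with no common spot get NaN with
    a warning.
    """
    labels = sorted(dataset.groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for pairwise similarity")
    k = len(labels)
    chi = np.zeros((k, k))
    n_used = np.zeros((k, k), dtype=int)
    index = {s: i for i, s in enumerate(dataset.spot_ids)}
    for i, j in itertools.combinations(range(k), 2):
        a, b = labels[i], labels[j]
        common = select_common_spots(scores[a], scores[b], sr_level)
        if not common:
            logger.warning("no common SR-%d spots for pair (%s, %s)", sr_level, a, b)
            chi[i, j] = chi[j, i] = np.nan
            continue
        rows = [index[s] for s in common]
        prof_a, prof_b = build_pair_profiles(
            dataset.group_matrix(a)[rows, :],
            dataset.group_matrix(b)[rows, :],
            common,
        )
        value = compute_chi(prof_a, prof_b, squared=squared)
        chi[i, j] = chi[j, i] = value
        n_used[i, j] = n_used[j, i] = len(common)
    return SimilarityMatrix(
        group_labels=labels, sr_level=sr_level, chi=chi, n_spots_used=n_used
    )
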