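"""Synthetic peptide-array datasets with known ground truth.

Emulates the chip structure consumed by the pipeline: 144 spots
(one of them the internal positive control), 3 technical replicates per
group, occasional negative background-subtracted values.  Replicate
signals are drawn log-normally around per-spot baselines times
group-specific fold effects; the log-normal sigma is chosen so that
the draw's coefficient of variation equals the spot's quality-class CV
(at small CV the spot's P1 parameter therefore concentrates near that
CV, which makes SR class membership controllable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from osteoblast.chip_io import DEFAULT_CONTROL_ID, IntensityDataset, PeptideAnnotation

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVW"  # Y inserted explicitly
_SYMBOL_CHARS = "ABCDEFGHIKLMNPQRSTVWXYZ"

#: Quality-class name -> replicate CV used when a config gives no mix.
DEFAULT_QUALITY_CVS = {"sr6": 0.05, "sr5": 0.25, "sr1": 0.80}
DEFAULT_QUALITY_MIX = {"sr6": 0.6, "sr5": 0.25, "sr1": 0.15}


@dataclass(frozen=True)
class GroupSpec:
    """One surface group: a log-scale baseline and per-spot fold effects."""

    label: str
    baseline_log_mean: float = math.log(100.0)
    effects: dict[int, float] = field(default_factory=dict)  # spot index -> fold

    def fold(self, spot_index: int) -> float:
        return self.effects.get(spot_index, 1.0)


@dataclass
class SynthConfig:
    """Generator settings; see :func:`generate`."""

    n_spots: int = 144
    n_replicates: int = 3
    group_specs: list[GroupSpec] = field(
        default_factory=lambda: [GroupSpec("control"), GroupSpec("test")]
    )
    quality_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QUALITY_MIX)
    )
    noise_cv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QUALITY_CVS)
    )
    neg_background_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not self.group_specs:
            raise ValueError("need at least one group spec")
        total = sum(self.quality_mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"quality_mix proportions must sum to 1, got {total}")
        missing = set(self.quality_mix) - set(self.noise_cv)
        if missing:
            raise ValueError(f"quality classes without a CV: {sorted(missing)}")
        if any(cv < 0 for cv in self.noise_cv.values()):
            raise ValueError("all noise CVs must be >= 0")
        if not 0 <= self.neg_background_rate < 1:
            raise ValueError("neg_background_rate must be in [0, 1)")


def _random_sequence(rng: np.random.Generator) -> str:
    """Random 13-mer guaranteed to contain at least one tyrosine."""
    seq = list(rng.choice(list(_AMINO_ACIDS), size=13))
    seq[int(rng.integers(0, 13))] = "Y"
    return "".join(seq)


def make_layout(n_spots: int = 144, seed: int = 0) -> list[PeptideAnnotation]:
    """Synthetic layout: ``n_spots - 1`` analyte spots plus one control.

    Analyte IDs follow the ``SYMBOL_start_end`` convention over random
    13-mers containing a tyrosine; the last spot is the internal
    positive control.  Deterministic for a fixed seed.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    rng = np.random.default_rng(seed)
    annotations: list[PeptideAnnotation] = []
    used_ids: set[str] = set()
    while len(annotations) < n_spots - 1:
        symbol = "".join(rng.choice(list(_SYMBOL_CHARS), size=int(rng.integers(3, 7))))
        start = int(rng.integers(1, 1500))
        spot_id = f"{symbol}_{start}_{start + 12}"
        if spot_id in used_ids:
            continue
        used_ids.add(spot_id)
        seq = _random_sequence(rng)
        tyr_positions = tuple(
            sorted(start + i for i, aa in enumerate(seq) if aa == "Y")
        )
        annotations.append(
            PeptideAnnotation(
                spot_id=spot_id,
                sequence=seq,
                protein_name=f"Synthetic protein {symbol}",
                symbol=symbol,
                phospho_positions=tyr_positions,
                uniprot_accession=f"Q{rng.integers(10000, 99999)}",
            )
        )
    annotations.append(
        PeptideAnnotation(
            spot_id=DEFAULT_CONTROL_ID,
            sequence="EAIYAAPFAKKKXC",
            protein_name="Internal positive control",
            symbol="ART",
            phospho_positions=(4,),
            uniprot_accession="",
        )
    )
    return annotations


def generate(config: SynthConfig) -> tuple[IntensityDataset, pd.DataFrame]:
    """Draw a full dataset plus its ground-truth table.

    Per spot i and group g, replicate values are
    ``exp(baseline + log(spot_scale_i) + log(fold_g(i)))`` times
    log-normal noise with the spot's class CV (mean-one, so the
    expected value equals the intended mean).  A ``neg_background_rate``
    fraction of values is replaced by a small negative number to
    exercise the flooring rule downstream.

    Returns the (un-floored) dataset and a table with each spot's
    quality class, class CV and true fold effect per group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = make_layout(config.n_spots, seed=config.seed)
    n = config.n_spots

    # deterministic class counts (largest remainder), then shuffled
    classes = sorted(config.quality_mix)
    exact = {c: config.quality_mix[c] * n for c in classes}
    counts = {c: int(math.floor(exact[c])) for c in classes}
    short = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    assignment = np.array([c for c in classes for _ in range(counts[c])])
    rng.shuffle(assignment)

    spot_scale = rng.lognormal(mean=0.0, sigma=0.5, size=n)

    groups: dict[str, np.ndarray] = {}
    for spec in config.group_specs:
        mat = np.empty((n, config.n_replicates))
        for i in range(n):
            cv = config.noise_cv[assignment[i]]
            mean = math.exp(spec.baseline_log_mean) * spot_scale[i] * spec.fold(i)
            if cv == 0:
                mat[i, :] = mean
            else:
                sigma = math.sqrt(math.log1p(cv * cv))
                noise = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                                      size=config.n_replicates)
                mat[i, :] = mean * noise
        if config.neg_background_rate > 0:
            mask = rng.random(mat.shape) < config.neg_background_rate
            mat[mask] = -0.05 * np.abs(mat[mask])
        groups[spec.label] = mat

    truth_rows = []
    for i, ann in enumerate(layout):
        row = {
            "spot_id": ann.spot_id,
            "is_control": ann.spot_id == DEFAULT_CONTROL_ID,
            "quality_class": assignment[i],
            "class_cv": config.noise_cv[assignment[i]],
            "spot_scale": spot_scale[i],
        }
        for spec in config.group_specs:
            row[f"fold_{spec.label}"] = spec.fold(i)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    dataset = IntensityDataset(layout=layout, groups=groups, flooring_applied=False)
    return dataset, truth
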