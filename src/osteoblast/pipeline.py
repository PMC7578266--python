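"""End-to-end orchestration: ingest -> score -> select -> normalize ->
differential -> chi -> reports.

`run` executes the whole comparison for one control group against any
number of test groups, writing per-group SR histograms, per-contrast
common-spot lists, differential and volcano tables, the pairwise chi
matrix at the configured SR level, and a machine-readable manifest
(config, versions, input hashes, per-stage spot counts).  The analysis
path contains no randomness, so identical inputs and config produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import osteoblast
from osteoblast import chip_io, diffphos, reliability, similarity
from osteoblast.chip_io import DEFAULT_CONTROL_ID, IntensityDataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    control_group: str
    test_groups: list[str]
    sr_level: int = 6
    alpha: float = 0.05
    control_peptide_id: str = DEFAULT_CONTROL_ID
    output_dir: str | Path = "osteoblast_out"
    seed: int | None = None
    equal_var: bool = True
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.sr_level not in range(reliability.SR_MIN, reliability.SR_MAX + 1):
            raise ValueError(f"sr_level must be in 1..6, got {self.sr_level}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.control_group in self.test_groups:
            raise ValueError("control_group must not appear in test_groups")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run(
    config: RunConfig,
    layout: str | Path | list[chip_io.PeptideAnnotation],
    intensities: str | Path | dict[str, np.ndarray],
) -> dict:
    """Execute the full comparison and write all report tables.

    ``layout``/``intensities`` may be file paths (read via
    :mod:`osteoblast.chip_io`) or already-parsed objects.  Returns the
    manifest dictionary that is also written to ``manifest.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "osteoblast",
        "version": osteoblast.__version__,
        "python": platform.python_version(),
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {},
        "stages": {},
        "warnings": [],
    }

    # -- ingest --------------------------------------------------------
    if isinstance(layout, (str, Path)):
        manifest["inputs"]["layout"] = {"path": str(layout), "sha256": _sha256(layout)}
        layout = chip_io.read_layout(layout)
    if isinstance(intensities, (str, Path)):
        manifest["inputs"]["intensities"] = {
            "path": str(intensities),
            "sha256": _sha256(intensities),
        }
        dataset = chip_io.read_intensities(intensities, layout)
    else:
        dataset = IntensityDataset(layout=list(layout), groups=dict(intensities))

    for label in [config.control_group, *config.test_groups]:
        if label not in dataset.groups:
            raise KeyError(f"group {label!r} not present in intensity data")

    n_raw = dataset.n_spots
    dataset = chip_io.exclude_control(dataset, config.control_peptide_id)
    dataset = chip_io.floor_negatives(dataset)
    manifest["stages"]["ingest"] = {
        "n_spots_raw": n_raw,
        "n_spots_analyzed": dataset.n_spots,
        "control_excluded": dataset.n_spots < n_raw,
        "groups": sorted(dataset.groups),
    }

    # -- reliability scoring ------------------------------------------
    scores = {g: reliability.score_dataset(dataset, g) for g in dataset.groups}
    hist_rows = []
    for g in sorted(scores):
        hist = reliability.sr_histogram(scores[g])
        for sr, count in hist.items():
            hist_rows.append({"group": g, "SR": sr, "n_spots": count})
    pd.DataFrame(hist_rows).to_csv(outdir / "sr_histogram.tsv", sep="\t", index=False)
    score_rows = []
    for g in sorted(scores):
        for s in scores[g]:
            score_rows.append(
                {
                    "group": g, "spot_id": s.spot_id, "A": s.A, "M": s.M,
                    "sd": s.sd, "P1": s.P1, "P2": s.P2,
                    "level_P1": str(s.level_P1), "level_P2": str(s.level_P2),
                    "SR": s.SR,
                }
            )
    pd.DataFrame(score_rows).to_csv(outdir / "scores.tsv", sep="\t", index=False)
    manifest["stages"]["score"] = {
        g: {str(k): v for k, v in reliability.sr_histogram(scores[g]).items()}
        for g in sorted(scores)
    }

    # -- per-contrast differential analysis ---------------------------
    manifest["stages"]["differential"] = {}
    for test_group in config.test_groups:
        common = reliability.select_common_spots(
            scores[test_group], scores[config.control_group], config.sr_level
        )
        (outdir / f"common_spots_{test_group}.txt").write_text(
            "\n".join(common) + ("\n" if common else "")
        )
        records = diffphos.differential_table(
            dataset,
            scores,
            test_group=test_group,
            control_group=config.control_group,
            sr_level=config.sr_level,
            alpha=config.alpha,
            equal_var=config.equal_var,
            bh_correct=config.bh_correct,
        )
        diffphos.records_to_frame(records).to_csv(
            outdir / f"differential_{test_group}.tsv", sep="\t", index=False
        )
        volcano, n_up, n_down = diffphos.volcano_table(records, config.alpha)
        volcano.to_csv(outdir / f"volcano_{test_group}.tsv", sep="\t", index=False)
        manifest["stages"]["differential"][test_group] = {
            "n_common_spots": len(common),
            "n_tested": len(records),
            "n_up": n_up,
            "n_down": n_down,
        }
        if not common:
            manifest["warnings"].append(
                f"no common SR-{config.sr_level} spots for contrast "
                f"{test_group} vs {config.control_group}"
            )

    # -- pairwise chi --------------------------------------------------
    sim = similarity.pairwise_similarity(dataset, scores, sr_level=config.sr_level)
    sim.to_long_frame().to_csv(outdir / "chi_pairwise.tsv", sep="\t", index=False)
    sim.to_square_frame().to_csv(outdir / "chi_matrix.csv")
    chi_entries = sim.to_long_frame().to_dict(orient="records")
    for entry in chi_entries:
        if entry["n_spots"] == 0:
            manifest["warnings"].append(
                f"no common SR-{config.sr_level} spots for chi pair "
                f"({entry['group_a']}, {entry['group_b']})"
            )
        if isinstance(entry["chi"], float) and np.isnan(entry["chi"]):
            entry["chi"] = None
    manifest["stages"]["similarity"] = {
        "sr_level": config.sr_level,
        "pairs": chi_entries,
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete: %s", outdir)
    return manifest
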