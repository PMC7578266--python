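"""Chip layout / intensity table I/O and raw-signal preprocessing.

Layout tables mirror the array annotation style: one row per spot with
spot ID, protein name, HGNC-style symbol, phospho-site positions,
UniProt accession and the 13-mer substrate sequence.  Intensity tables
carry one row per spot and one column per ``<group>_rep<k>`` technical
replicate.  Both are plain CSV/TSV with a header.

Preprocessing here is limited to two rules applied before any
statistics: the internal positive-control spot is dropped, and
negative (background over-subtracted) signals are floored to zero.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Spot ID of the internal positive-control peptide, excluded from analysis.
DEFAULT_CONTROL_ID = "ART_003_EAI(pY)AAPFAKKKXC"

_AA_CODES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Default layout header names; override via the ``columns`` mapping.
LAYOUT_COLUMNS = {
    "spot_id": "Spot",
    "protein_name": "Protein",
    "symbol": "Symbol",
    "phospho_positions": "p",
    "uniprot_accession": "Uniprot accession",
    "sequence": "Sequence",
}

_REP_COLUMN = re.compile(r"^(?P<group>.+)_rep(?P<rep>\d+)$")


class ChipFormatError(ValueError):
    """Malformed layout or intensity table."""


class ChipValidationError(ValueError):
    """Table parsed but violates a dataset invariant."""


@dataclass(frozen=True)
class PeptideAnnotation:
    """Identity of one array spot.

    Parameters
    ----------
    spot_id
        Unique spot identifier.  The ``SYMBOL_start_end`` convention is
        common but never required; IDs are opaque strings.
    phospho_positions
        1-based phosphorylatable positions in the source protein,
        sorted ascending.
    sequence
        Substrate peptide in one-letter amino-acid codes (plus X).
    """

    spot_id: str
    sequence: str
    protein_name: str = ""
    symbol: str = ""
    phospho_positions: tuple[int, ...] = ()
    uniprot_accession: str = ""

    def __post_init__(self) -> None:
        if not self.spot_id:
            raise ChipValidationError("spot_id must be non-empty")
        if len(self.sequence) < 1:
            raise ChipValidationError(f"{self.spot_id}: empty sequence")
        bad = set(self.sequence.upper()) - _AA_CODES
        if bad:
            raise ChipValidationError(
                f"{self.spot_id}: non-amino-acid characters {sorted(bad)} in sequence"
            )
        positions = tuple(self.phospho_positions)
        if any(p < 1 for p in positions):
            raise ChipValidationError(f"{self.spot_id}: phospho positions must be >= 1")
        if list(positions) != sorted(positions):
            raise ChipValidationError(f"{self.spot_id}: phospho positions not sorted")
        object.__setattr__(self, "phospho_positions", positions)

    def to_dict(self) -> dict:
        return {
            "spot_id": self.spot_id,
            "protein_name": self.protein_name,
            "symbol": self.symbol,
            "phospho_positions": list(self.phospho_positions),
            "uniprot_accession": self.uniprot_accession,
            "sequence": self.sequence,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PeptideAnnotation":
        return cls(
            spot_id=d["spot_id"],
            sequence=d["sequence"],
            protein_name=d.get("protein_name", ""),
            symbol=d.get("symbol", ""),
            phospho_positions=tuple(d.get("phospho_positions", ())),
            uniprot_accession=d.get("uniprot_accession", ""),
        )


@dataclass
class IntensityDataset:
    """Replicate signal matrices for every surface group, plus the layout.

    ``groups`` maps a group label to an ``(n_spots, n_replicates)``
    float array whose row order matches ``layout``.
    """

    layout: list[PeptideAnnotation]
    groups: dict[str, np.ndarray]
    flooring_applied: bool = False

    def __post_init__(self) -> None:
        ids = [a.spot_id for a in self.layout]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ChipValidationError(f"duplicate spot_ids in layout: {dupes}")
        n = len(self.layout)
        converted = {}
        for label, mat in self.groups.items():
            arr = np.asarray(mat, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != n:
                raise ChipValidationError(
                    f"group {label!r}: matrix shape {arr.shape} does not match "
                    f"{n} layout spots"
                )
            if arr.shape[1] < 2:
                raise ChipValidationError(
                    f"group {label!r}: need >= 2 replicates, got {arr.shape[1]}"
                )
            if not np.all(np.isfinite(arr)):
                raise ChipValidationError(
                    f"group {label!r}: missing or non-numeric replicate values"
                )
            converted[label] = arr
        self.groups = converted
        if self.flooring_applied and any(
            (m < 0).any() for m in self.groups.values()
        ):
            raise ChipValidationError("flooring_applied but negative values present")

    @property
    def spot_ids(self) -> list[str]:
        return [a.spot_id for a in self.layout]

    @property
    def n_spots(self) -> int:
        return len(self.layout)

    def group_matrix(self, label: str) -> np.ndarray:
        try:
            return self.groups[label]
        except KeyError:
            raise KeyError(
                f"unknown group {label!r}; available: {sorted(self.groups)}"
            ) from None

    def annotation(self, spot_id: str) -> PeptideAnnotation:
        for a in self.layout:
            if a.spot_id == spot_id:
                return a
        raise KeyError(spot_id)

    # -- JSON round trip (used by the CLI `ingest` stage) --------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "layout": [a.to_dict() for a in self.layout],
            "groups": {k: v.tolist() for k, v in self.groups.items()},
            "flooring_applied": self.flooring_applied,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "IntensityDataset":
        payload = json.loads(Path(path).read_text())
        return cls(
            layout=[PeptideAnnotation.from_dict(d) for d in payload["layout"]],
            groups={k: np.asarray(v, float) for k, v in payload["groups"].items()},
            flooring_applied=payload.get("flooring_applied", False),
        )


def _parse_positions(cell) -> tuple[int, ...]:
    """Parse a bracketed position list like ``[573, 579, 580]``."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    if isinstance(cell, (int, np.integer)):
        return (int(cell),)
    text = str(cell).strip().strip("[]")
    if not text:
        return ()
    return tuple(int(tok) for tok in text.replace(";", ",").split(",") if tok.strip())


def _format_positions(positions: Sequence[int]) -> str:
    return "[" + ", ".join(str(p) for p in positions) + "]"


def _detect_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    suffix = Path(path).suffix.lower()
    if suffix in {".tsv", ".tab", ".txt"}:
        return "\t"
    if suffix == ".csv":
        return ","
    # sniff the header line
    head = Path(path).open().readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_layout(
    path: str | Path,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[PeptideAnnotation]:
    """Read a chip layout table into a list of :class:`PeptideAnnotation`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    sep
        Field separator; inferred from the extension when omitted.
    columns
        Overrides for :data:`LAYOUT_COLUMNS` (logical name -> header name).

    Raises
    ------
    ChipFormatError
        If a required column (spot ID, sequence) is missing.
    ChipValidationError
        On duplicate spot IDs or invalid field values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(LAYOUT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str, keep_default_na=False)
    for logical in ("spot_id", "sequence"):
        if colmap[logical] not in df.columns:
            raise ChipFormatError(
                f"{path}: required column {colmap[logical]!r} ({logical}) missing; "
                f"found {list(df.columns)}"
            )
    annotations = []
    for _, row in df.iterrows():
        annotations.append(
            PeptideAnnotation(
                spot_id=row[colmap["spot_id"]],
                sequence=row[colmap["sequence"]],
                protein_name=row.get(colmap["protein_name"], ""),
                symbol=row.get(colmap["symbol"], ""),
                phospho_positions=_parse_positions(row.get(colmap["phospho_positions"])),
                uniprot_accession=row.get(colmap["uniprot_accession"], ""),
            )
        )
    ids = [a.spot_id for a in annotations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ChipValidationError(f"{path}: duplicate spot_ids {dupes}")
    return annotations


def write_layout(
    annotations: Iterable[PeptideAnnotation],
    path: str | Path,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write a layout table; inverse of :func:`read_layout`."""
    colmap = dict(LAYOUT_COLUMNS)
    if columns:
        colmap.update(columns)
    rows = []
    for a in annotations:
        rows.append(
            {
                colmap["spot_id"]: a.spot_id,
                colmap["protein_name"]: a.protein_name,
                colmap["symbol"]: a.symbol,
                colmap["phospho_positions"]: _format_positions(a.phospho_positions),
                colmap["uniprot_accession"]: a.uniprot_accession,
                colmap["sequence"]: a.sequence,
            }
        )
    df = pd.DataFrame(rows, columns=list(colmap.values()))
    df.to_csv(path, sep=_detect_sep(path, sep), index=False)


def read_intensities(
    path: str | Path,
    layout: Sequence[PeptideAnnotation],
    sep: str | None = None,
    spot_column: str = "Spot",
) -> IntensityDataset:
    """Read a replicate intensity table keyed by ``<group>_rep<k>`` columns.

    Rows are matched to ``layout`` by spot ID; every layout spot must be
    present exactly once and every replicate cell must be numeric.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    if spot_column not in df.columns:
        raise ChipFormatError(f"{path}: spot column {spot_column!r} missing")
    rep_cols: dict[str, list[tuple[int, str]]] = {}
    for col in df.columns:
        m = _REP_COLUMN.match(col)
        if m:
            rep_cols.setdefault(m["group"], []).append((int(m["rep"]), col))
    if not rep_cols:
        raise ChipFormatError(f"{path}: no '<group>_rep<k>' intensity columns found")
    df = df.set_index(spot_column)
    wanted = [a.spot_id for a in layout]
    missing = [s for s in wanted if s not in df.index]
    if missing:
        raise ChipValidationError(f"{path}: layout spots absent from table: {missing[:5]}")
    df = df.loc[wanted]
    groups = {}
    for group, cols in rep_cols.items():
        ordered = [c for _, c in sorted(cols)]
        mat = df[ordered].to_numpy(dtype=float)
        if np.isnan(mat).any():
            bad = [wanted[i] for i in np.where(np.isnan(mat).any(axis=1))[0][:5]]
            raise ChipValidationError(
                f"{path}: missing replicate values for group {group!r} (spots {bad})"
            )
        groups[group] = mat
    return IntensityDataset(layout=list(layout), groups=groups)


def write_intensities(
    dataset: IntensityDataset, path: str | Path, sep: str | None = None
) -> None:
    """Write the dataset's group matrices as a ``<group>_rep<k>`` table."""
    data: dict[str, object] = {"Spot": dataset.spot_ids}
    for group, mat in dataset.groups.items():
        for k in range(mat.shape[1]):
            data[f"{group}_rep{k + 1}"] = mat[:, k]
    pd.DataFrame(data).to_csv(path, sep=_detect_sep(path, sep), index=False)


def exclude_control(
    dataset: IntensityDataset, control_id: str = DEFAULT_CONTROL_ID
) -> IntensityDataset:
    """Drop the internal positive-control spot from layout and all matrices.

    A dataset without the control spot is returned unchanged (with a
    logged warning); all other rows keep their relative order.
    """
    ids = dataset.spot_ids
    if control_id not in ids:
        logger.warning("control spot %r not present; nothing excluded", control_id)
        return dataset
    keep = [i for i, s in enumerate(ids) if s != control_id]
    return IntensityDataset(
        layout=[dataset.layout[i] for i in keep],
        groups={g: m[keep, :] for g, m in dataset.groups.items()},
        flooring_applied=dataset.flooring_applied,
    )


def floor_negatives(dataset: IntensityDataset) -> IntensityDataset:
    """Replace every negative signal with zero (idempotent)."""
    return replace(
        dataset,
        groups={g: np.maximum(m, 0.0) for g, m in dataset.groups.items()},
        flooring_applied=True,
    )
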