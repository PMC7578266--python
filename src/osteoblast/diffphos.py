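"""Quantile normalization and differential phosphorylation calls.

The selected common-SR spots of the two groups under comparison are
quantile-normalized jointly (all ``2 x n_replicates`` columns share one
target distribution), then each spot is tested with a two-sided
two-sample Student's t-test (pooled variance by default; Welch behind a
flag).  Fold change is the ratio of normalized test and control means.
No multiple-testing correction is applied by default; Benjamini-
Hochberg is available as an option.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from osteoblast.chip_io import IntensityDataset, PeptideAnnotation
from osteoblast.reliability import SpotReliability, select_common_spots

logger = logging.getLogger(__name__)


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    NS = "ns"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DifferentialRecord:
    """Outcome of one spot's test-vs-control comparison."""

    spot_id: str
    p_value: float
    fold_change: float
    direction: Direction
    annotation: PeptideAnnotation | None = None

    @property
    def log2_fold_change(self) -> float:
        return float(np.log2(self.fold_change))


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column onto the common mean-of-sorted-columns distribution.

    The k-th smallest value of each column becomes the mean over columns
    of their k-th smallest values.  Tied values within a column all
    receive the mean of the reference values spanned by the tie block
    (preprocessCore-compatible).  Shape is preserved; the operation is
    idempotent.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        normalized_sorted = reference.copy()
        # average the reference over each tie block
        start = 0
        for end in range(1, len(sorted_col) + 1):
            if end == len(sorted_col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    normalized_sorted[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = normalized_sorted
    return out.reshape(np.asarray(matrix, dtype=float).shape)


def differential_test(
    test: np.ndarray,
    control: np.ndarray,
    alpha: float = 0.05,
    spot_id: str = "",
    annotation: PeptideAnnotation | None = None,
    equal_var: bool = True,
) -> DifferentialRecord:
    """Two-sided two-sample t-test plus fold change for one spot.

    Fold change is mean(test)/mean(control) on the normalized scale.
    Degenerate cases: two identical constant vectors give p = 1; a zero
    control mean makes the fold change undefined (NaN) and the record is
    flagged ``ns`` - callers drop such spots with a warning.
    """
    test = np.asarray(test, dtype=float)
    control = np.asarray(control, dtype=float)
    if test.size < 2 or control.size < 2:
        raise ValueError("need >= 2 replicates on each side")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    if test.std() == 0 and control.std() == 0:
        p_value = 1.0 if test.mean() == control.mean() else 0.0
    else:
        with warnings.catch_warnings():
            # scipy warns on near-identical replicate vectors; the
            # degenerate exactly-constant case is handled above
            warnings.simplefilter("ignore", RuntimeWarning)
            p_value = float(stats.ttest_ind(test, control, equal_var=equal_var).pvalue)

    control_mean = control.mean()
    if control_mean == 0:
        logger.warning("spot %s: control mean is 0, fold change undefined", spot_id)
        return DifferentialRecord(spot_id, p_value, float("nan"), Direction.NS, annotation)
    fold_change = float(test.mean() / control_mean)

    if p_value < alpha and fold_change > 1:
        direction = Direction.UP
    elif p_value < alpha and fold_change < 1:
        direction = Direction.DOWN
    else:
        direction = Direction.NS
    return DifferentialRecord(spot_id, p_value, fold_change, direction, annotation)


def differential_table(
    dataset: IntensityDataset,
    scores: dict[str, list[SpotReliability]],
    test_group: str,
    control_group: str,
    sr_level: int = 6,
    alpha: float = 0.05,
    equal_var: bool = True,
    bh_correct: bool = False,
) -> list[DifferentialRecord]:
    """Full differential pipeline for one test-vs-control contrast.

    Selects the common spots at ``sr_level``, quantile-normalizes the
    joint test+control replicate matrix restricted to those spots, and
    tests each spot.  Spots with an undefined fold change are dropped.
    With ``bh_correct`` the p-values are Benjamini-Hochberg adjusted
    before directions are assigned.
    """
    common = select_common_spots(
        scores[test_group], scores[control_group], sr_level
    )
    if not common:
        logger.warning(
            "no common SR-%d spots between %s and %s", sr_level, test_group, control_group
        )
        return []
    index = {s: i for i, s in enumerate(dataset.spot_ids)}
    rows = [index[s] for s in common]
    test_mat = dataset.group_matrix(test_group)[rows, :]
    ctrl_mat = dataset.group_matrix(control_group)[rows, :]
    n_test = test_mat.shape[1]
    joint = quantile_normalize(np.hstack([test_mat, ctrl_mat]))
    test_norm, ctrl_norm = joint[:, :n_test], joint[:, n_test:]

    records = []
    for i, spot_id in enumerate(common):
        rec = differential_test(
            test_norm[i],
            ctrl_norm[i],
            alpha=alpha,
            spot_id=spot_id,
            annotation=dataset.annotation(spot_id),
            equal_var=equal_var,
        )
        if np.isnan(rec.fold_change):
            logger.warning("spot %s excluded (undefined fold change)", spot_id)
            continue
        records.append(rec)
    if bh_correct:
        records = _bh_adjust(records, alpha)
    return records


def _bh_adjust(records: list[DifferentialRecord], alpha: float) -> list[DifferentialRecord]:
    """Benjamini-Hochberg step-up adjustment, re-deriving directions."""
    m = len(records)
    order = np.argsort([r.p_value for r in records])
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running_min = min(running_min, records[idx].p_value * m / (rank_from_top + 1))
        adjusted[idx] = running_min
    out = []
    for rec, q in zip(records, adjusted):
        if q < alpha and rec.fold_change > 1:
            direction = Direction.UP
        elif q < alpha and rec.fold_change < 1:
            direction = Direction.DOWN
        else:
            direction = Direction.NS
        out.append(
            DifferentialRecord(rec.spot_id, float(q), rec.fold_change, direction, rec.annotation)
        )
    return out


def volcano_table(
    records: list[DifferentialRecord], alpha: float = 0.05
) -> tuple[pd.DataFrame, int, int]:
    """Volcano-plot data plus (n_up, n_down) significant counts."""
    rows = []
    for r in records:
        rows.append(
            {
                "spot_id": r.spot_id,
                "log2_fc": r.log2_fold_change,
                "neg_log10_p": float(-np.log10(r.p_value)) if r.p_value > 0 else np.inf,
                "direction": str(r.direction),
            }
        )
    df = pd.DataFrame(rows, columns=["spot_id", "log2_fc", "neg_log10_p", "direction"])
    n_up = sum(1 for r in records if r.direction is Direction.UP)
    n_down = sum(1 for r in records if r.direction is Direction.DOWN)
    return df, n_up, n_down


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Render records in the published differential-table column layout."""
    rows = []
    for r in records:
        a = r.annotation
        rows.append(
            {
                "Spot": r.spot_id,
                "Protein": a.protein_name if a else "",
                "Symbol": a.symbol if a else "",
                "p": "[" + ", ".join(map(str, a.phospho_positions)) + "]" if a else "",
                "Uniprot accession": a.uniprot_accession if a else "",
                "Sequence": a.sequence if a else "",
                "p-value": r.p_value,
                "FC": r.fold_change,
                "direction": str(r.direction),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Spot", "Protein", "Symbol", "p", "Uniprot accession",
            "Sequence", "p-value", "FC", "direction",
        ],
    )
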