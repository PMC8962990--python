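"""Overlap evaluation between binary masks: Jaccard and Dice indices.

JC = |X ∩ Y| / |X ∪ Y| and DC = 2|X ∩ Y| / (|X| + |Y|), both in [0, 1],
related exactly by DC = 2·JC / (1 + JC). Masks are binarized as value > 0 on
load, so multi-label ground truths count every labelled voxel as foreground
(an explicit label set can restrict this).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OverlapReport", "overlap", "evaluate_batch", "load_mask"]


@dataclass(frozen=True)
class OverlapReport:
    jaccard: float
    dice: float
    size_x: int
    size_y: int
    intersection: int
    union: int


def _binarize(m, labels=None) -> np.ndarray:
    arr = np.asarray(m)
    if labels is not None:
        return np.isin(arr, list(labels))
    return arr > 0


def overlap(x, y, labels=None) -> OverlapReport:
    """Jaccard/Dice overlap of two same-shape binary masks (value > 0).

    Raises on shape mismatch and when both masks are empty (0/0 is
    undefined — the indices presume non-empty objects).
    """
    bx = _binarize(x, labels)
    by = _binarize(y, labels)
    if bx.shape != by.shape:
        raise ValueError(f"mask shapes differ: {bx.shape} vs {by.shape}")
    nx = int(bx.sum())
    ny = int(by.sum())
    if nx == 0 and ny == 0:
        raise ValueError("both masks are empty; overlap is undefined")
    inter = int(np.count_nonzero(bx & by))
    union = nx + ny - inter
    return OverlapReport(
        jaccard=inter / union,
        dice=2 * inter / (nx + ny),
        size_x=nx,
        size_y=ny,
        intersection=inter,
        union=union,
    )


def load_mask(path) -> np.ndarray:
    """Read a mask volume/image from NIfTI/Analyze or PNG/PGM."""
    from .pipelines import load_volume

    arr, _ = load_volume(path, quantize=False)
    return arr


def evaluate_batch(pairs, csv_out=None, labels=None) -> pd.DataFrame:
    """Evaluate (prediction, truth) pairs; one row per pair plus a mean row.

    Entries may be file paths or in-memory arrays. Per-pair failures are
    recorded in an ``error`` column and the batch continues. An empty input
    yields an empty table without a mean row.
    """
    rows = []
    for pred, truth in pairs:
        name_p = str(pred) if isinstance(pred, (str, Path)) else "<array>"
        name_t = str(truth) if isinstance(truth, (str, Path)) else "<array>"
        row = {"prediction": name_p, "truth": name_t}
        try:
            p = load_mask(pred) if isinstance(pred, (str, Path)) else pred
            t = load_mask(truth) if isinstance(truth, (str, Path)) else truth
            row.update(asdict(overlap(p, t, labels=labels)))
        except Exception as exc:  # noqa: BLE001 — recorded, batch continues
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(rows) and "jaccard" in table:
        mean = {"prediction": "mean", "truth": "",
                "jaccard": table["jaccard"].mean(),
                "dice": table["dice"].mean()}
        table = pd.concat([table, pd.DataFrame([mean])], ignore_index=True)
    if csv_out is not None:
        table.to_csv(csv_out, index=False)
    return table
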