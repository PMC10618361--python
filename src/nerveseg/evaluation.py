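"""Voxel-overlap evaluation: confusion counts, DSC / precision / sensitivity,
and per-case + aggregate reporting.

Foreground (nerve) voxels are the positive class.  With heavy class
imbalance, accuracy and specificity mostly score the background, so the
reported metrics are the Dice similarity coefficient (equivalently the F1
score), precision and sensitivity (recall).

Edge conventions, documented because segmentation benchmarks differ: when
both masks are empty DSC is reported as 1.0; a metric whose denominator is
zero is otherwise *undefined* (``None``) and excluded from aggregates with
the exclusion counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_io import Mask

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "confusion_counts",
    "dsc",
    "precision",
    "sensitivity",
    "evaluate_case",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsRecord:
    case_id: str
    dsc: Optional[float]
    precision: Optional[float]
    sensitivity: Optional[float]
    counts: ConfusionCounts


def _data(mask: Union[Mask, np.ndarray]) -> np.ndarray:
    return (mask.data if isinstance(mask, Mask) else np.asarray(mask)).astype(bool)


def confusion_counts(pred: Union[Mask, np.ndarray], truth: Union[Mask, np.ndarray]) -> ConfusionCounts:
    """Voxelwise TP/FP/FN/TN between aligned binary masks."""
    p, t = _data(pred), _data(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(counts: ConfusionCounts) -> Optional[float]:
    """2TP / (2TP + FP + FN); 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0  # both masks empty: perfect (vacuous) agreement
    return 2 * counts.tp / denom


def precision(counts: ConfusionCounts) -> Optional[float]:
    """TP / (TP + FP); undefined (None) for an empty prediction."""
    denom = counts.tp + counts.fp
    return None if denom == 0 else counts.tp / denom


def sensitivity(counts: ConfusionCounts) -> Optional[float]:
    """TP / (TP + FN); undefined (None) for an empty ground truth."""
    denom = counts.tp + counts.fn
    return None if denom == 0 else counts.tp / denom


def evaluate_case(case_id: str, pred, truth) -> MetricsRecord:
    c = confusion_counts(pred, truth)
    return MetricsRecord(case_id, dsc(c), precision(c), sensitivity(c), c)


def aggregate(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    """Mean, sample SD, min and max per metric over defined entries.

    Returns a dataframe indexed by metric with columns
    (mean, sd, min, max, n, n_undefined); single-record aggregates use the
    sd=0 convention.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    rows = {}
    for metric in ("dsc", "precision", "sensitivity"):
        vals = [getattr(r, metric) for r in records]
        defined = np.array([v for v in vals if v is not None], dtype=float)
        n_undef = len(vals) - defined.size
        if defined.size == 0:
            rows[metric] = dict(mean=np.nan, sd=np.nan, min=np.nan, max=np.nan,
                                n=0, n_undefined=n_undef)
            continue
        sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
        rows[metric] = dict(
            mean=float(defined.mean()),
            sd=sd,
            min=float(defined.min()),
            max=float(defined.max()),
            n=int(defined.size),
            n_undefined=n_undef,
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def records_to_frame(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    """One row per case (metrics + raw counts), for CSV export."""
    return pd.DataFrame(
        [
            dict(
                case_id=r.case_id,
                dsc=r.dsc,
                precision=r.precision,
                sensitivity=r.sensitivity,
                tp=r.counts.tp,
                fp=r.counts.fp,
                fn=r.counts.fn,
                tn=r.counts.tn,
            )
            for r in records
        ]
    )
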