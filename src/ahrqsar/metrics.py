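"""Classification performance panel on the active/inactive collapse.

All headline statistics are computed on the binary division into active
and inactive compounds, collapsing any multi-category confusion grid
first.  With TA/TI/FA/FI the true-active, true-inactive, false-active and
false-inactive counts:

    OA          = (TA + TI) / (TA + TI + FA + FI)
    WOA         = (sensitivity + specificity) / 2
    sensitivity = TA / (TA + FI)
    specificity = TI / (TI + FA)
    precision   = TA / (TA + FA)
    NPV         = TI / (TI + FI)
    MCC         = (TA*TI - FA*FI) / sqrt((TA+FA)(TA+FI)(TI+FA)(TI+FI))

WOA weights both classes equally regardless of prevalence, which is why
it is the tuning objective on a ~10:1 imbalanced set.  Degenerate
denominators yield NaN (flagged absent), never a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_grid",
    "collapse_to_binary",
    "compute_metrics",
    "macro_recall",
    "binary_agreement",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts: true/false active, true/false inactive."""

    ta: float
    ti: float
    fa: float
    fi: float

    def __post_init__(self) -> None:
        for name in ("ta", "ti", "fa", "fi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.ta + self.ti + self.fa + self.fi


@dataclass
class MetricsReport:
    oa: float
    woa: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    mcc: float  # NaN when a marginal is zero
    mcc_defined: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "OA": self.oa,
            "WOA": self.woa,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "NPV": self.npv,
            "MCC": self.mcc,
        }


def confusion_grid(
    true_labels, predicted_labels, categories: list | None = None
) -> pd.DataFrame:
    """Multiclass confusion grid, rows = true, columns = predicted."""
    true_s = pd.Series(list(true_labels))
    pred_s = pd.Series(list(predicted_labels))
    if len(true_s) != len(pred_s):
        raise ValueError("label vectors differ in length")
    if categories is None:
        categories = sorted(set(true_s) | set(pred_s), key=str)
    grid = pd.DataFrame(0, index=categories, columns=categories, dtype=int)
    for t, p in zip(true_s, pred_s):
        grid.loc[t, p] += 1
    return grid


def collapse_to_binary(grid: pd.DataFrame, active_categories: set) -> ConfusionCounts:
    """Sum a multiclass grid into the 2x2 active/inactive layout.

    A Medium compound predicted High is a true active after collapse: the
    binary view only asks whether activity itself was recognised.
    ``active_categories`` must partition the grid's labels together with
    its complement (no overlap, no omission of an active label that does
    not appear in the grid).
    """
    labels = set(grid.index) | set(grid.columns)
    unknown = set(active_categories) - labels
    if unknown:
        raise ValueError(f"active categories not present in grid: {sorted(unknown, key=str)}")
    inactive = labels - set(active_categories)
    if not inactive:
        raise ValueError("active categories cover the whole grid; nothing inactive")

    def _mass(rows, cols) -> float:
        rows = [r for r in rows if r in grid.index]
        cols = [c for c in cols if c in grid.columns]
        return float(grid.loc[rows, cols].to_numpy().sum())

    act, inact = sorted(active_categories, key=str), sorted(inactive, key=str)
    return ConfusionCounts(
        ta=_mass(act, act),
        ti=_mass(inact, inact),
        fa=_mass(inact, act),
        fi=_mass(act, inact),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Full panel from binary counts; see module docstring for formulas."""
    if cc.total <= 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cc.ta, cc.ta + cc.fi)
    spec = _ratio(cc.ti, cc.ti + cc.fa)
    mcc_den = (
        (cc.ta + cc.fa) * (cc.ta + cc.fi) * (cc.ti + cc.fa) * (cc.ti + cc.fi)
    )
    mcc_defined = mcc_den > 0
    mcc = (
        (cc.ta * cc.ti - cc.fa * cc.fi) / math.sqrt(mcc_den)
        if mcc_defined
        else math.nan
    )
    return MetricsReport(
        oa=_ratio(cc.ta + cc.ti, cc.total),
        woa=(sens + spec) / 2,
        sensitivity=sens,
        specificity=spec,
        precision=_ratio(cc.ta, cc.ta + cc.fa),
        npv=_ratio(cc.ti, cc.ti + cc.fi),
        mcc=mcc,
        mcc_defined=mcc_defined,
    )


def macro_recall(grid: pd.DataFrame) -> float:
    """Secondary multiclass statistic: unweighted mean of per-category
    recall.  Not the headline WOA, which is binary by definition."""
    recalls = []
    for cat in grid.index:
        row_total = float(grid.loc[cat].sum())
        if row_total > 0:
            recalls.append(float(grid.loc[cat, cat]) / row_total)
    if not recalls:
        raise ValueError("grid has no populated true categories")
    return float(np.mean(recalls))


def binary_agreement(
    predictions, reference, ids=None
) -> tuple[float, list]:
    """Fraction of concordant binary calls plus the discordant ids.

    Unreliable (NR) predictions must be filtered out by the caller before
    comparison; this mirrors how external-set agreement is evaluated on
    reliable predictions only.
    """
    pred = list(predictions)
    ref = list(reference)
    if len(pred) != len(ref):
        raise ValueError(
            f"length mismatch: {len(pred)} predictions vs {len(ref)} references"
        )
    if not pred:
        raise ValueError("nothing to compare")
    if ids is None:
        ids = list(range(len(pred)))
    discordant = [i for i, p, r in zip(ids, pred, ref) if p != r]
    return 1 - len(discordant) / len(pred), discordant
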