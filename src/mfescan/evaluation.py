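"""Confusion-matrix bookkeeping and the four reported performance metrics.

Specificity   SP  = TN / (TN + FP)
Sensitivity   SE  = TP / (TP + FN)
Pos. pred. v. PPV = TP / (TP + FP)
Accuracy      Q   = (TP + TN) / (TP + FN + TN + FP)

Metrics are kept as raw ratios; reports present them as percentages rounded
half-up to one decimal. A zero denominator yields NaN with a warning, never
a silent zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative tallies of a binary classification."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """SP, SE, PPV and overall accuracy Q as raw ratios in [0, 1]."""

    sp: float
    se: float
    ppv: float
    q: float

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        """Percentages rounded half-up (report convention)."""
        return {
            name: round_half_up(100.0 * v, decimals) if not math.isnan(v) else math.nan
            for name, v in (
                ("sp", self.sp), ("se", self.se), ("ppv", self.ppv), ("q", self.q)
            )
        }


def round_half_up(x: float, decimals: int = 1) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return math.nan
    return num / den


def compute_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """SP, SE, PPV and Q from confusion counts (NaN where undefined)."""
    if counts.total == 0:
        raise ValueError("all four counts are zero")
    return ConfusionMetrics(
        sp=_ratio(counts.tn, counts.tn + counts.fp, "SP"),
        se=_ratio(counts.tp, counts.tp + counts.fn, "SE"),
        ppv=_ratio(counts.tp, counts.tp + counts.fp, "PPV"),
        q=_ratio(counts.tp + counts.tn, counts.total, "Q"),
    )


def confusion_from_predictions(
    results: Sequence, truth: Mapping[str, bool]
) -> ConfusionCounts:
    """Tally boolean calls (``result.call``) against a truth mapping by id."""
    tp = fp = tn = fn = 0
    for res in results:
        if res.id not in truth:
            raise KeyError(f"no truth label for prediction id {res.id!r}")
        actual = bool(truth[res.id])
        if res.call and actual:
            tp += 1
        elif res.call and not actual:
            fp += 1
        elif not res.call and not actual:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_table(rows: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """One report row per model: counts plus SP/SE/PPV/Q in percent."""
    out = []
    for name, counts in rows.items():
        pct = compute_metrics(counts).as_percent()
        out.append(
            {
                "model": name,
                "positives": counts.positives,
                "negatives": counts.negatives,
                "TP": counts.tp,
                "FP": counts.fp,
                "TN": counts.tn,
                "FN": counts.fn,
                "SP": pct["sp"],
                "SE": pct["se"],
                "PPV": pct["ppv"],
                "Q": pct["q"],
            }
        )
    return pd.DataFrame(out)
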