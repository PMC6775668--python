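"""Robust summaries of cross-validation accuracy.

Role predictability is summarised by Tukey's trimean of the per-fold
accuracies (a robust location estimate) and their interquartile range (a
robust dispersion estimate).  Quartiles use linear interpolation between
order statistics (the "type 7" convention, the default in mainstream
numerical software).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["tukey_trimean", "AccuracyStats"]


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty list of values")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(q1), float(q2), float(q3)


def tukey_trimean(values: Sequence[float]) -> float:
    """Tukey's trimean (Q1 + 2*Q2 + Q3) / 4 of ``values``."""
    q1, q2, q3 = _quartiles(values)
    return (q1 + 2.0 * q2 + q3) / 4.0


@dataclass(frozen=True)
class AccuracyStats:
    """Per-fold accuracies with their robust location/dispersion summary."""

    per_fold_accuracy: tuple[float, ...]
    q1: float
    q2: float
    q3: float
    trimean: float
    iqr: float

    @classmethod
    def from_fold_accuracies(cls, accuracies: Sequence[float]) -> "AccuracyStats":
        q1, q2, q3 = _quartiles(accuracies)
        return cls(
            per_fold_accuracy=tuple(float(a) for a in accuracies),
            q1=q1,
            q2=q2,
            q3=q3,
            trimean=(q1 + 2.0 * q2 + q3) / 4.0,
            iqr=q3 - q1,
        )

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": list(self.per_fold_accuracy),
            "q1": self.q1,
            "q2": self.q2,
            "q3": self.q3,
            "trimean": self.trimean,
            "iqr": self.iqr,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AccuracyStats":
        return cls(
            per_fold_accuracy=tuple(doc["per_fold_accuracy"]),
            q1=doc["q1"],
            q2=doc["q2"],
            q3=doc["q3"],
            trimean=doc["trimean"],
            iqr=doc["iqr"],
        )
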