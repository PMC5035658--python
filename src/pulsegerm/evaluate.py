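"""Validation and monitoring outputs.

Contingency tables and error rates against ground truth (manual photo
annotation or simulator labels), the FCM-vs-CFU correlation that ties
FDA-positive counts to plate viability, per-time feature distributions,
and germination time courses.

.. note::
   The contingency cell names follow the originating method's
   (non-standard) convention: the positive class is *germinated*,
   ``fp`` counts germinated spores **not** categorised as germinated
   (a miss in common usage) and ``fn`` counts non-germinated spores
   categorised as germinated (a false alarm).  The accessors ``miss``
   and ``false_alarm`` are provided to avoid confusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "TimeCoursePoint",
    "cfu_correlation",
    "contingency",
    "distributions",
    "error_rate",
    "timecourse",
]

INTERMEDIATE_POLICIES = (
    "as_germinated",
    "as_non_germinated",
    "excluded",
    "best_case",
)


@dataclass(frozen=True)
class ContingencyTable:
    """Classification counts (see module note on the fp/fn convention)."""

    tp: int  # germinated, classified germinated
    fp: int  # germinated, NOT classified germinated (a miss)
    tn: int  # non-germinated, classified non-germinated
    fn: int  # non-germinated, classified germinated (a false alarm)
    intermediate_excluded: int = 0
    policy: str = "excluded"

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def miss(self) -> int:
        """Germinated spores the classifier missed (the table's fp)."""
        return self.fp

    @property
    def false_alarm(self) -> int:
        """Non-germinated spores flagged germinated (the table's fn)."""
        return self.fn

    @property
    def error_raw(self) -> float:
        """Unrounded error percentage."""
        if self.total == 0:
            raise ZeroDivisionError("error rate undefined for an empty table")
        return 100.0 * (self.fp + self.fn) / self.total


def contingency(
    predicted: Sequence[str],
    truth: Sequence[str],
    intermediate_policy: str = "excluded",
) -> ContingencyTable:
    """Tabulate predictions against truth.

    ``truth`` may contain the intermediate label ``germinating``;
    ``intermediate_policy`` decides its fate:

    * ``as_germinated`` / ``as_non_germinated`` — force the class;
    * ``excluded`` — drop intermediates from the table (the default,
      matching how the method's error rates are reported);
    * ``best_case`` — credit each intermediate to whatever class the
      prediction assigned (dual allocation: never an error).
    """
    if intermediate_policy not in INTERMEDIATE_POLICIES:
        raise ValueError(
            f"unknown policy {intermediate_policy!r}; "
            f"choose from {INTERMEDIATE_POLICIES}"
        )
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions "
            f"vs {len(truth)} truth labels"
        )
    tp = fp = tn = fn = excluded = 0
    for pred, true in zip(predicted, truth):
        if pred not in ("germinated", "non_germinated"):
            raise ValueError(f"prediction must be binary, got {pred!r}")
        if true == "germinating":
            if intermediate_policy == "excluded":
                excluded += 1
                continue
            if intermediate_policy == "best_case":
                true = pred
            elif intermediate_policy == "as_germinated":
                true = "germinated"
            else:
                true = "non_germinated"
        if true == "germinated":
            if pred == "germinated":
                tp += 1
            else:
                fp += 1
        elif true == "non_germinated":
            if pred == "non_germinated":
                tn += 1
            else:
                fn += 1
        else:
            raise ValueError(f"unknown truth label {true!r}")
    return ContingencyTable(
        tp=tp, fp=fp, tn=tn, fn=fn,
        intermediate_excluded=excluded,
        policy=intermediate_policy,
    )


def error_rate(table: ContingencyTable) -> float:
    """Method error in percent: ``100 (fp + fn) / total``, rounded to one
    decimal as reported; the unrounded value is
    :attr:`ContingencyTable.error_raw`."""
    return round(table.error_raw, 1)


def cfu_correlation(fcm_counts, cfu_counts) -> dict:
    """Ordinary least squares of CFU on FCM counts.

    An at-line viability count is trusted when this regression has a
    slope near 1 and a high R².  Returns ``{"slope", "intercept",
    "r_squared"}``; needs at least three pairs and non-degenerate FCM
    values.
    """
    x = np.asarray(fcm_counts, dtype=float)
    y = np.asarray(cfu_counts, dtype=float)
    if x.size != y.size:
        raise ValueError("paired sequences must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("counts must be positive")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in the paired counts")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
    }


@dataclass(frozen=True)
class TimeCoursePoint:
    """Germinated share of FDA-positive spores at one sampling time."""

    time_h: float
    percent_germinated: float  # NaN when no FDA-positive event was seen
    n_fda_positive: int


def timecourse(classified_batches) -> list[TimeCoursePoint]:
    """Germination time course over classified, gated batches.

    ``classified_batches`` is an iterable of ``(time_h, predicted_labels)``
    where the labels are the binary classes of the FDA-positive particles
    of that sample.  Batches with zero FDA-positive events yield a point
    with NaN percent and a warning.  Points are returned ordered by time.
    """
    points = []
    for time_h, labels in classified_batches:
        labels = list(labels)
        n = len(labels)
        if n == 0:
            warnings.warn(
                f"no FDA-positive events at t={time_h} h; "
                "percent germinated undefined",
                stacklevel=2,
            )
            percent = float("nan")
        else:
            germ = sum(1 for lab in labels if lab == "germinated")
            percent = 100.0 * germ / n
        points.append(TimeCoursePoint(float(time_h), percent, n))
    return sorted(points, key=lambda p: p.time_h)


def distributions(
    batches,
    feature_name: str,
    bin_edges,
) -> dict[float, pd.DataFrame]:
    """Per-time, class-split feature histograms normalised to 100 %.

    ``batches`` is an iterable of ``(time_h, table)`` where the table
    holds ``feature_name`` and ``predicted_class`` columns.  For each
    sampling point the histogram over all classes and bins sums to
    100 %.  Empty batches are skipped with a warning.
    """
    edges = np.asarray(bin_edges, dtype=float)
    out: dict[float, pd.DataFrame] = {}
    for time_h, table in batches:
        if feature_name not in table.columns:
            raise KeyError(f"no feature column {feature_name!r}")
        if len(table) == 0:
            warnings.warn(f"empty batch at t={time_h} h skipped", stacklevel=2)
            continue
        raw = {}
        for cls, group in table.groupby("predicted_class"):
            counts, _ = np.histogram(group[feature_name].to_numpy(), bins=edges)
            raw[cls] = counts
        binned = sum(int(c.sum()) for c in raw.values())
        if binned == 0:
            warnings.warn(
                f"no events of t={time_h} h fall inside the bins; skipped",
                stacklevel=2,
            )
            continue
        rows = {cls: 100.0 * counts / binned for cls, counts in raw.items()}
        hist = pd.DataFrame(
            rows,
            index=pd.IntervalIndex.from_breaks(edges, closed="left"),
        ).T
        out[float(time_h)] = hist
    return out
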