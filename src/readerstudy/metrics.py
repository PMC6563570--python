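"""Per-examination accuracy metrics and Wilson score intervals.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/all.  The microaverage pools confusion counts across readers
before forming the ratio, so the pooled metric is the count-weighted one
(920 = 8 readers x 115 cases in the default design).  Interval estimates
use the 95% Wilson score interval, which inverts the score test and keeps
sensible coverage near 0 and 1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .exceptions import AlignmentError, UndefinedMetricError
from .records import CaseRecord

METRICS = ("sensitivity", "specificity", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies for one reader or pooled across readers."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its Wilson score confidence interval."""

    estimate: float
    lower: float
    upper: float
    n: int
    confidence: float = 0.95
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.estimate <= self.upper <= 1.0:
            raise ValueError(
                f"interval ordering violated: {self.lower}, {self.estimate}, {self.upper}"
            )


def binarize_prediction(volume: np.ndarray, threshold: float = 0.5) -> int:
    """Case-level call from a voxelwise probability volume.

    Positive iff at least one voxel probability strictly exceeds
    ``threshold`` — the strict ">" matters at the 0.5 boundary.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.size == 0:
        raise ValueError("empty volume")
    if not np.isfinite(volume).all():
        raise ValueError("volume contains non-finite values")
    if volume.min() < 0.0 or volume.max() > 1.0:
        raise ValueError("voxel probabilities must lie in [0, 1]")
    return int((volume > threshold).any())


def confusion(
    labels: Mapping[str, int], cases: Sequence[CaseRecord]
) -> ConfusionCounts:
    """Tally one reader's labels against case truth, aligned on case_id."""
    if len(cases) == 0:
        raise AlignmentError("empty case list")
    case_ids = {c.case_id for c in cases}
    if len(case_ids) != len(cases):
        raise AlignmentError("duplicate case_id in truth")
    missing = case_ids - set(labels)
    extra = set(labels) - case_ids
    if missing or extra:
        raise AlignmentError(
            f"labels and truth misaligned; missing={sorted(missing)[:5]}, "
            f"unmatched={sorted(extra)[:5]}"
        )
    tp = fp = tn = fn = 0
    for case in cases:
        call = labels[case.case_id]
        if call not in (0, 1):
            raise ValueError(f"label for case {case.case_id} is not binary: {call!r}")
        if case.truth == 1:
            tp += call
            fn += 1 - call
        else:
            fp += call
            tn += 1 - call
    return ConfusionCounts(tp, fp, tn, fn)


def metric(counts: ConfusionCounts, which: str) -> float:
    """sensitivity, specificity or accuracy from a confusion tally.

    Raises :class:`UndefinedMetricError` on a zero denominator rather than
    returning NaN, because silent NaNs would propagate into the t-tests.
    """
    if which == "sensitivity":
        num, den = counts.tp, counts.n_positive
    elif which == "specificity":
        num, den = counts.tn, counts.n_negative
    elif which == "accuracy":
        num, den = counts.tp + counts.tn, counts.total
    else:
        raise ValueError(f"unknown metric {which!r}; expected one of {METRICS}")
    if den == 0:
        raise UndefinedMetricError(f"{which} undefined: denominator is zero")
    return num / den


def metric_numerator_denominator(counts: ConfusionCounts, which: str) -> tuple[int, int]:
    """The integer (successes, trials) pair behind ``metric`` — the input
    the Wilson interval needs."""
    if which == "sensitivity":
        return counts.tp, counts.n_positive
    if which == "specificity":
        return counts.tn, counts.n_negative
    if which == "accuracy":
        return counts.tp + counts.tn, counts.total
    raise ValueError(f"unknown metric {which!r}; expected one of {METRICS}")


def microaverage(per_reader: Iterable[ConfusionCounts]) -> ConfusionCounts:
    """Pool confusion counts across readers (elementwise sum).

    metric(microaverage(counts)) is the pooled metric:
    sum of numerators over sum of denominators.
    """
    per_reader = list(per_reader)
    if not per_reader:
        raise ValueError("microaverage of an empty collection")
    total = per_reader[0]
    for c in per_reader[1:]:
        total = total + c
    return total


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    center = (p + z^2/2n) / (1 + z^2/n),
    half-width = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n),
    with z the exact standard-normal quantile at (1+confidence)/2
    (1.959964... at 95%, not the rounded 1.96).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, n]; got {successes}/{n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    lower, upper = proportion_confint(
        successes, n, alpha=1.0 - confidence, method="wilson"
    )
    estimate = successes / n
    # clip to [0,1] and absorb ~1e-16 rounding at the p-hat = 0/1 boundaries
    return ProportionCI(
        estimate=estimate,
        lower=min(float(np.clip(lower, 0.0, 1.0)), estimate),
        upper=max(float(np.clip(upper, 0.0, 1.0)), estimate),
        n=n,
        confidence=confidence,
    )


def metric_with_ci(
    counts: ConfusionCounts, which: str, confidence: float = 0.95
) -> ProportionCI:
    """Metric point estimate with its Wilson interval at the metric's own n."""
    successes, n = metric_numerator_denominator(counts, which)
    if n == 0:
        raise UndefinedMetricError(f"{which} undefined: denominator is zero")
    return wilson_ci(successes, n, confidence)


def normal_quantile(confidence: float = 0.95) -> float:
    """z used by the Wilson interval, exposed for documentation/tests."""
    return float(norm.ppf((1.0 + confidence) / 2.0))
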