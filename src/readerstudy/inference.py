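"""Paired cross-reader inference, time-to-diagnosis analysis, BH correction.

With n = 8 readers each measured under both sessions, the unit of inference
is the reader: per-reader metric differences feed a one-tailed paired t test
(df = n - 1), always on the exact Student t distribution, with a two-sided
95% t interval reported alongside.  Reading times are the consecutive
differences of logged entry times; the 5 longest and 5 shortest per
reader-session are excluded before averaging to absorb interruptions and
logging glitches.  A Benjamini-Hochberg step-up correction is applied across
the registered hypothesis family.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateVarianceError, SchemaError
from .records import Annotation, Session


@dataclass(frozen=True)
class PairedTestResult:
    """One-tailed paired t test on per-reader differences (b - a)."""

    mean_diff: float
    ci_lower: float
    ci_upper: float
    t_stat: float
    df: int
    p_one_tailed: float
    direction: str
    n: int

    def __post_init__(self) -> None:
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")
        if not self.ci_lower <= self.mean_diff <= self.ci_upper:
            raise ValueError("CI must bracket the mean difference")


@dataclass(frozen=True)
class HypothesisRecord:
    """One member of the multiplicity family, before/after BH adjustment."""

    id: str
    p_unadjusted: float
    p_adjusted: float
    family_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_unadjusted <= 1.0:
            raise ValueError(f"{self.id}: p_unadjusted outside [0, 1]")
        if self.p_adjusted < self.p_unadjusted - 1e-12 or self.p_adjusted > 1.0:
            raise ValueError(f"{self.id}: invalid adjusted p")


@dataclass(frozen=True)
class TimingSummary:
    """Trimmed mean time-to-diagnosis for one reader-session (or pooled)."""

    reader_id: str
    session: Session
    n_raw: int
    n_used: int
    mean_s: float
    ci_lower_s: float
    ci_upper_s: float


def paired_one_tailed_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    direction: str = "greater",
    confidence: float = 0.95,
) -> PairedTestResult:
    """Paired t test on differences d = b - a across readers.

    ``direction="greater"`` tests mean(d) > 0 (improvement means b exceeds
    a, as for sensitivity/specificity/accuracy/kappa); ``"less"`` tests
    mean(d) < 0 (as for reading time).  The reported interval is the
    conventional two-sided t CI for the mean difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemaError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise SchemaError("paired t test requires at least 2 pairs")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError(
            "paired differences are constant; t statistic undefined"
        )
    res = stats.ttest_rel(b, a, alternative=direction)
    mean = float(d.mean())
    sem = sd / np.sqrt(n)
    half = stats.t.ppf((1.0 + confidence) / 2.0, df=n - 1) * sem
    return PairedTestResult(
        mean_diff=mean,
        ci_lower=mean - half,
        ci_upper=mean + half,
        t_stat=float(res.statistic),
        df=n - 1,
        p_one_tailed=float(res.pvalue),
        direction=direction,
        n=n,
    )


def diagnosis_durations(annotations: Iterable[Annotation]) -> np.ndarray:
    """Per-case reading durations for one reader-session.

    Durations are the consecutive differences of spreadsheet entry times in
    reading order (restored by sorting on entry time), so 115 cases yield
    114 durations — the first case has no predecessor.
    """
    anns = list(annotations)
    if len(anns) < 2:
        raise SchemaError("need at least 2 entries to form a duration")
    readers = {a.reader_id for a in anns}
    sessions = {a.session for a in anns}
    if len(readers) > 1 or len(sessions) > 1:
        raise SchemaError(
            "durations are defined per reader-session; got "
            f"readers={sorted(readers)}, sessions={sorted(s.value for s in sessions)}"
        )
    if any(a.entry_time_s is None for a in anns):
        raise SchemaError("entry_time_s missing for some annotations")
    times = np.sort(np.array([a.entry_time_s for a in anns], dtype=float))
    diffs = np.diff(times)
    if (diffs <= 0).any():
        raise ValueError("entry times must be strictly increasing")
    return diffs


def trim_durations(durations: Sequence[float], k: int = 5) -> np.ndarray:
    """Drop the k largest and k smallest durations (stable on ties).

    Remaining values keep their original order; length shrinks by exactly 2k.
    """
    d = np.asarray(durations, dtype=float)
    if k < 0:
        raise ValueError("k must be >= 0")
    if d.ndim != 1 or d.size <= 2 * k:
        raise ValueError(
            f"need more than {2 * k} durations to trim {k} from each tail; got {d.size}"
        )
    if k == 0:
        return d.copy()
    order = np.argsort(d, kind="stable")
    drop = np.concatenate([order[:k], order[-k:]])
    keep = np.ones(d.size, dtype=bool)
    keep[drop] = False
    return d[keep]


def mean_time_ci(
    durations: Sequence[float],
    confidence: float = 0.95,
    reader_id: str = "pooled",
    session: Session | str = Session.UNAUGMENTED,
    n_raw: int | None = None,
) -> TimingSummary:
    """Mean duration with a two-sided Student-t interval."""
    d = np.asarray(durations, dtype=float)
    if d.size < 2:
        raise SchemaError("mean_time_ci requires at least 2 durations")
    mean = float(d.mean())
    sem = d.std(ddof=1) / np.sqrt(d.size)
    half = float(stats.t.ppf((1.0 + confidence) / 2.0, df=d.size - 1) * sem)
    return TimingSummary(
        reader_id=reader_id,
        session=Session.coerce(session),
        n_raw=d.size if n_raw is None else n_raw,
        n_used=d.size,
        mean_s=mean,
        ci_lower_s=mean - half,
        ci_upper_s=mean + half,
    )


def bh_adjust(
    p_values: Sequence[float], ids: Sequence[str] | None = None
) -> list[HypothesisRecord]:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept.

    p_adj(i) = min_{j >= i} (m * p_(j) / j) capped at 1, where p_(1) <= ...
    <= p_(m) are the sorted unadjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise SchemaError("bh_adjust requires a non-empty 1-D p-value vector")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if ids is None:
        ids = [f"h{i + 1}" for i in range(p.size)]
    if len(ids) != p.size:
        raise SchemaError("ids and p_values must have equal length")
    adjusted = multipletests(p, method="fdr_bh")[1]
    m = p.size
    return [
        HypothesisRecord(id=i, p_unadjusted=float(pu), p_adjusted=float(pa), family_size=m)
        for i, pu, pa in zip(ids, p, adjusted)
    ]


def subgroup_paired_test(
    per_reader_a: dict[str, float],
    per_reader_b: dict[str, float],
    reader_ids: Sequence[str],
    direction: str = "greater",
) -> PairedTestResult:
    """Paired test restricted to a reader subset (e.g. radiologists only).

    Same machinery as :func:`paired_one_tailed_t`; the subset must contain at
    least 2 readers present in both sessions.
    """
    if len(reader_ids) < 2:
        raise SchemaError("subgroup analysis requires at least 2 readers")
    missing = [r for r in reader_ids if r not in per_reader_a or r not in per_reader_b]
    if missing:
        raise SchemaError(f"readers missing metric values: {missing}")
    a = [per_reader_a[r] for r in reader_ids]
    b = [per_reader_b[r] for r in reader_ids]
    return paired_one_tailed_t(a, b, direction=direction)
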