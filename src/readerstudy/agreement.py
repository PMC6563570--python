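"""Interrater agreement: exact Fleiss kappa and the session-swap permutation test.

"Exact" Fleiss kappa here is Conger's multi-rater generalisation of Cohen's
kappa: observed agreement is the average over rater pairs of their percent
agreement, and expected agreement uses rater-specific marginal rates

    P_o = (1 / (N R (R-1))) * sum_cases sum_categories n_cj (n_cj - 1)
    P_e = (2 / (R (R-1))) * sum_{r<r'} sum_categories p_rj p_r'j

so for R = 2 the statistic reduces to Cohen's kappa.  The classic Fleiss
statistic (pooled marginals, P_e = sum_j pbar_j^2) is available behind
``variant="fleiss"`` for comparison.

The permutation test for the augmented-minus-unaugmented kappa difference
swaps, independently per case with probability 1/2, that case's full row of
reader labels between the two session matrices (preserving within-case
inter-rater correlation), recomputes the kappa difference each time, and
reports the proportion of null differences strictly greater than the
observed one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateAgreementError,
    DegenerateNullWarning,
    SchemaError,
)
from .records import AnnotationMatrix


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected multi-rater agreement on one session."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_cases: int
    n_raters: int
    variant: str = "conger"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12:
            raise ValueError(f"kappa out of range: {self.kappa}")


@dataclass(frozen=True)
class PermutationResult:
    """Observed kappa difference and its case-swap permutation null."""

    observed_diff: float
    n_permutations: int
    null_exceed_count: int
    p_value: float
    seed: int
    kappa_augmented: float
    kappa_unaugmented: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.null_exceed_count <= self.n_permutations:
            raise ValueError("null_exceed_count must lie in [0, B]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _category_counts(labels: np.ndarray) -> np.ndarray:
    """cases x 2 matrix of per-case counts for categories (0, 1)."""
    n1 = labels.sum(axis=1)
    return np.stack([labels.shape[1] - n1, n1], axis=1)


def _agreement_components(labels: np.ndarray, variant: str) -> tuple[float, float]:
    n_cases, n_raters = labels.shape
    counts = _category_counts(labels)
    p_o = float((counts * (counts - 1)).sum() / (n_cases * n_raters * (n_raters - 1)))
    if variant == "conger":
        # rater marginals per category; pairwise products via the
        # (sum^2 - sum of squares)/2 identity
        p_r = np.stack([1.0 - labels.mean(axis=0), labels.mean(axis=0)], axis=0)
        pair_sum = (p_r.sum(axis=1) ** 2 - (p_r**2).sum(axis=1)).sum()
        p_e = float(pair_sum / (n_raters * (n_raters - 1)))
    elif variant == "fleiss":
        pbar = counts.sum(axis=0) / (n_cases * n_raters)
        p_e = float((pbar**2).sum())
    else:
        raise ValueError(f"unknown kappa variant {variant!r}")
    return p_o, p_e


def fleiss_exact_kappa(
    matrix: AnnotationMatrix | np.ndarray, variant: str = "conger"
) -> KappaResult:
    """Multi-rater chance-corrected agreement on a cases x raters label grid.

    Parameters
    ----------
    matrix
        An :class:`AnnotationMatrix` or a binary cases x raters array.
    variant
        ``"conger"`` (default; rater-specific marginals — the exact form)
        or ``"fleiss"`` (classic pooled marginals).
    """
    labels = matrix.labels if isinstance(matrix, AnnotationMatrix) else np.asarray(matrix)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim != 2:
        raise SchemaError("kappa requires a 2-D cases x raters matrix")
    n_cases, n_raters = labels.shape
    if n_raters < 2:
        raise SchemaError("kappa requires at least 2 raters")
    if n_cases < 1:
        raise SchemaError("kappa requires at least 1 case")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    p_o, p_e = _agreement_components(labels, variant)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateAgreementError(
            "expected agreement is 1 (all raters label every case identically "
            "in a single category); kappa is undefined"
        )
    return KappaResult(
        kappa=(p_o - p_e) / (1.0 - p_e),
        observed_agreement=p_o,
        expected_agreement=p_e,
        n_cases=n_cases,
        n_raters=n_raters,
        variant=variant,
    )


def _row_agreement(labels: np.ndarray) -> np.ndarray:
    """Per-case fraction of agreeing rater pairs."""
    n_raters = labels.shape[1]
    n1 = labels.sum(axis=1)
    n0 = n_raters - n1
    return (n1 * (n1 - 1) + n0 * (n0 - 1)) / (n_raters * (n_raters - 1))


def _kappa_from_parts(p_o: np.ndarray, marg1: np.ndarray, variant: str) -> np.ndarray:
    """Vectorised kappa for B permutations.

    p_o: (B,) observed agreement; marg1: (B, R) per-rater category-1 rates.
    """
    n_raters = marg1.shape[1]
    if variant == "conger":
        marg0 = 1.0 - marg1
        pair = (
            marg1.sum(axis=1) ** 2 - (marg1**2).sum(axis=1)
            + marg0.sum(axis=1) ** 2 - (marg0**2).sum(axis=1)
        )
        p_e = pair / (n_raters * (n_raters - 1))
    else:
        pbar = marg1.mean(axis=1)
        p_e = pbar**2 + (1.0 - pbar) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        return (p_o - p_e) / (1.0 - p_e)


def kappa_difference_permutation(
    augmented: AnnotationMatrix,
    unaugmented: AnnotationMatrix,
    n_permutations: int = 10_000,
    seed: int = 0,
    variant: str = "conger",
    unit: str = "case",
    smoothed: bool = False,
    chunk_size: int = 2_000,
) -> PermutationResult:
    """One-tailed permutation test for kappa(augmented) - kappa(unaugmented).

    Under the null hypothesis that augmentation does not change agreement,
    the session assignment of each case's pair of label rows is exchangeable,
    so each permutation swaps rows between the two matrices independently per
    case with probability 1/2 (``unit="case"``).  ``unit="cell"`` instead
    swaps each (case, reader) cell independently — a stricter null that
    breaks within-case correlation; case-level swapping is the default
    because the test set, not individual reads, was relabelled.

    p = #{null diffs > observed} / B (strict inequality); with
    ``smoothed=True`` the (count+1)/(B+1) estimate is reported instead.
    """
    if augmented.case_ids != unaugmented.case_ids:
        raise SchemaError("matrices must share an identical case ordering")
    if augmented.reader_ids != unaugmented.reader_ids:
        raise SchemaError("matrices must share an identical rater ordering")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if unit not in ("case", "cell"):
        raise ValueError("unit must be 'case' or 'cell'")

    aug = augmented.labels.astype(np.float64)
    una = unaugmented.labels.astype(np.float64)
    n_cases, n_raters = aug.shape

    k_aug = fleiss_exact_kappa(augmented, variant=variant)
    k_una = fleiss_exact_kappa(unaugmented, variant=variant)
    observed = k_aug.kappa - k_una.kappa

    rng = np.random.default_rng(seed)
    agree_aug = _row_agreement(aug)
    agree_una = _row_agreement(una)

    exceed = 0
    all_equal_observed = True
    done = 0
    while done < n_permutations:
        b = min(chunk_size, n_permutations - done)
        if unit == "case":
            swap = rng.random((b, n_cases)) < 0.5  # True: take the other session's row
            keep = ~swap
            p_o_aug = (swap @ agree_una + keep @ agree_aug) / n_cases
            p_o_una = (swap @ agree_aug + keep @ agree_una) / n_cases
            m_aug = (swap @ una + keep @ aug) / n_cases
            m_una = (swap @ aug + keep @ una) / n_cases
        else:
            swap = rng.random((b, n_cases, n_raters)) < 0.5
            lab_aug = np.where(swap, una[None], aug[None])
            lab_una = np.where(swap, aug[None], una[None])
            n1a = lab_aug.sum(axis=2)
            n1u = lab_una.sum(axis=2)
            denom = n_raters * (n_raters - 1)
            p_o_aug = (
                n1a * (n1a - 1) + (n_raters - n1a) * (n_raters - n1a - 1)
            ).sum(axis=1) / (n_cases * denom)
            p_o_una = (
                n1u * (n1u - 1) + (n_raters - n1u) * (n_raters - n1u - 1)
            ).sum(axis=1) / (n_cases * denom)
            m_aug = lab_aug.mean(axis=1)
            m_una = lab_una.mean(axis=1)
        diffs = _kappa_from_parts(p_o_aug, m_aug, variant) - _kappa_from_parts(
            p_o_una, m_una, variant
        )
        if not np.isfinite(diffs).all():
            raise DegenerateAgreementError(
                "a permuted split had expected agreement 1; kappa difference "
                "undefined under permutation"
            )
        exceed += int((diffs > observed).sum())
        if all_equal_observed and not np.allclose(diffs, observed, atol=1e-15):
            all_equal_observed = False
        done += b

    if all_equal_observed:
        warnings.warn(
            "permutation null is a point mass at the observed difference; "
            "the p-value is uninformative",
            DegenerateNullWarning,
            stacklevel=2,
        )
    if smoothed:
        p_value = (exceed + 1) / (n_permutations + 1)
    else:
        p_value = exceed / n_permutations
    return PermutationResult(
        observed_diff=observed,
        n_permutations=n_permutations,
        null_exceed_count=exceed,
        p_value=p_value,
        seed=seed,
        kappa_augmented=k_aug.kappa,
        kappa_unaugmented=k_una.kappa,
        smoothed=smoothed,
    )
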