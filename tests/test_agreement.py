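"""Exact (Conger) Fleiss kappa and the session-swap permutation test."""
import warnings

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

from readerstudy import (
    AnnotationMatrix,
    Session,
    fleiss_exact_kappa,
    kappa_difference_permutation,
)
from readerstudy.exceptions import (
    DegenerateAgreementError,
    DegenerateNullWarning,
    SchemaError,
)


def pairwise_conger_oracle(labels: np.ndarray) -> float:
    """Brute force: average observed and chance agreement over rater pairs,
    then chance-correct once."""
    n_cases, n_raters = labels.shape
    po, pe = [], []
    for r in range(n_raters):
        for s in range(r + 1, n_raters):
            po.append(np.mean(labels[:, r] == labels[:, s]))
            pe.append(
                sum(
                    np.mean(labels[:, r] == c) * np.mean(labels[:, s] == c)
                    for c in (0, 1)
                )
            )
    po_bar, pe_bar = np.mean(po), np.mean(pe)
    return (po_bar - pe_bar) / (1 - pe_bar)


def random_matrix(rng, n_cases=None, n_raters=None):
    n_cases = n_cases or rng.integers(3, 21)
    n_raters = n_raters or rng.integers(2, 7)
    while True:
        labels = (rng.random((n_cases, n_raters)) < rng.uniform(0.2, 0.8)).astype(int)
        if 0 < labels.sum() < labels.size:  # both categories in use
            return labels


def as_matrix(labels, session=Session.UNAUGMENTED):
    n_cases, n_raters = labels.shape
    return AnnotationMatrix(
        labels,
        tuple(f"c{i}" for i in range(n_cases)),
        tuple(f"r{j}" for j in range(n_raters)),
        session,
    )


class TestExactKappa:
    def test_perfect_agreement_is_one(self):
        labels = np.repeat([[1], [0], [1], [0], [0]], 4, axis=1)
        assert fleiss_exact_kappa(labels).kappa == pytest.approx(1.0)

    def test_two_opposed_raters_with_balanced_marginals(self):
        """P_o = 0 and P_e = 0.5, so kappa = -1 in closed form."""
        labels = np.array([[0, 1], [1, 0], [0, 1], [1, 0]])
        res = fleiss_exact_kappa(labels)
        assert res.observed_agreement == pytest.approx(0.0)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(-1.0)

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(100):
            labels = random_matrix(rng)
            assert fleiss_exact_kappa(labels).kappa == pytest.approx(
                pairwise_conger_oracle(labels), abs=1e-12
            )

    def test_two_raters_reduce_to_cohen(self, rng):
        for _ in range(100):
            labels = random_matrix(rng, n_raters=2)
            expected = cohen_kappa_score(labels[:, 0], labels[:, 1])
            assert fleiss_exact_kappa(labels).kappa == pytest.approx(expected, abs=1e-12)

    def test_classic_variant_matches_statsmodels(self, rng):
        for _ in range(50):
            labels = random_matrix(rng)
            table = aggregate_raters(labels, n_cat=2)[0]
            expected = fleiss_kappa(table, method="fleiss")
            ours = fleiss_exact_kappa(labels, variant="fleiss").kappa
            assert ours == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_case_and_rater_permutation(self, rng):
        labels = random_matrix(rng, n_cases=15, n_raters=5)
        base = fleiss_exact_kappa(labels).kappa
        shuffled = labels[rng.permutation(15)][:, rng.permutation(5)]
        assert fleiss_exact_kappa(shuffled).kappa == pytest.approx(base, abs=1e-12)

    def test_label_noise_degrades_agreement(self, rng):
        """Flipping an increasing share of cells pulls kappa down from 1."""
        base = np.repeat((rng.random((40, 1)) < 0.5).astype(int), 6, axis=1)
        means = []
        for rate in (0.0, 0.1, 0.3):
            ks = []
            for _ in range(30):
                noisy = base ^ (rng.random(base.shape) < rate).astype(int)
                if 0 < noisy.sum() < noisy.size:
                    ks.append(fleiss_exact_kappa(noisy).kappa)
            means.append(np.mean(ks))
        assert means[0] == pytest.approx(1.0)
        assert means[0] > means[1] > means[2]

    def test_single_rater_rejected(self):
        with pytest.raises(SchemaError):
            fleiss_exact_kappa(np.array([[1], [0]]))

    def test_unanimous_single_category_is_degenerate(self):
        with pytest.raises(DegenerateAgreementError):
            fleiss_exact_kappa(np.zeros((5, 3), dtype=int))


class TestPermutationTest:
    def test_identical_matrices_give_zero_diff_and_warn(self, rng):
        m = as_matrix(random_matrix(rng, 12, 4))
        same = as_matrix(m.labels, Session.AUGMENTED)
        with pytest.warns(DegenerateNullWarning):
            res = kappa_difference_permutation(same, m, n_permutations=100, seed=3)
        assert res.observed_diff == 0.0
        assert res.p_value == 0.0  # strict-inequality rule

    def test_deterministic_given_seed(self, rng):
        a = as_matrix(random_matrix(rng, 20, 5), Session.AUGMENTED)
        u = as_matrix(random_matrix(rng, 20, 5))
        r1 = kappa_difference_permutation(a, u, n_permutations=500, seed=42)
        r2 = kappa_difference_permutation(a, u, n_permutations=500, seed=42)
        assert r1 == r2

    def test_chunking_does_not_change_the_stream(self, rng):
        a = as_matrix(random_matrix(rng, 20, 5), Session.AUGMENTED)
        u = as_matrix(random_matrix(rng, 20, 5))
        r1 = kappa_difference_permutation(a, u, n_permutations=500, seed=9, chunk_size=7)
        r2 = kappa_difference_permutation(a, u, n_permutations=500, seed=9, chunk_size=500)
        # same total draws per permutation row, so identical mask stream
        assert r1.null_exceed_count == r2.null_exceed_count

    def test_shape_mismatch_rejected(self, rng):
        a = as_matrix(random_matrix(rng, 10, 4), Session.AUGMENTED)
        u = as_matrix(random_matrix(rng, 11, 4))
        with pytest.raises(SchemaError):
            kappa_difference_permutation(a, u, n_permutations=10, seed=0)

    def test_invalid_permutation_count_rejected(self, rng):
        a = as_matrix(random_matrix(rng, 10, 4), Session.AUGMENTED)
        u = as_matrix(a.labels ^ 0)
        with pytest.raises(ValueError):
            kappa_difference_permutation(a, u, n_permutations=0, seed=0)

    def test_smoothed_p_is_positive(self, rng):
        m = as_matrix(random_matrix(rng, 12, 4))
        same = as_matrix(m.labels, Session.AUGMENTED)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateNullWarning)
            res = kappa_difference_permutation(
                same, m, n_permutations=99, seed=3, smoothed=True
            )
        assert res.p_value == pytest.approx(1 / 100)

    def test_null_distribution_symmetric_under_exchangeability(self, rng):
        """Swapping sessions negates the observed diff but the null p-values
        stay complementary: p(A,U) + p(U,A) ~ 1 for continuous diffs."""
        a = as_matrix(random_matrix(rng, 40, 6), Session.AUGMENTED)
        u = as_matrix(random_matrix(rng, 40, 6))
        p_ab = kappa_difference_permutation(a, u, n_permutations=2000, seed=5).p_value
        p_ba = kappa_difference_permutation(u, a, n_permutations=2000, seed=5).p_value
        assert p_ab + p_ba == pytest.approx(1.0, abs=0.06)

    def test_cell_level_unit_runs_and_is_deterministic(self, rng):
        a = as_matrix(random_matrix(rng, 15, 4), Session.AUGMENTED)
        u = as_matrix(random_matrix(rng, 15, 4))
        r1 = kappa_difference_permutation(a, u, n_permutations=200, seed=1, unit="cell")
        r2 = kappa_difference_permutation(a, u, n_permutations=200, seed=1, unit="cell")
        assert r1 == r2
        assert 0.0 <= r1.p_value <= 1.0
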