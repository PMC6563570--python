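"""Synthetic cohort generator: truth strata, crossover, probit labels, times."""
import math

import numpy as np
import pytest

from readerstudy import (
    CaseRecord,
    GenerativeParams,
    Session,
    StudyConfig,
    assign_crossover,
    binarize_prediction,
    default_roster,
    fleiss_exact_kappa,
    simulate_annotation_matrices,
    simulate_annotations,
    simulate_segmentation,
    simulate_study,
    simulate_times,
    simulate_truth,
)
from readerstudy.exceptions import SchemaError


class TestTruth:
    def test_default_design_counts(self):
        """115 cases at 50% prevalence: exactly 58 positives (round-half-up)."""
        cases = simulate_truth(115, 0.5, seed=0)
        assert sum(c.truth for c in cases) == 58
        assert len(cases) == 115

    def test_positive_count_is_deterministic_not_bernoulli(self):
        for seed in range(5):
            assert sum(c.truth for c in simulate_truth(40, 0.25, seed)) == 10

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_prevalence_domain(self, bad):
        with pytest.raises(ValueError):
            simulate_truth(10, bad, 0)

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            simulate_truth(0, 0.5, 0)

    def test_same_seed_reproduces_records(self):
        assert simulate_truth(30, 0.5, 7) == simulate_truth(30, 0.5, 7)

    def test_positive_cases_have_significant_diameters(self):
        for c in simulate_truth(200, 0.5, 3):
            if c.truth:
                assert c.max_diameter_mm is not None and 3.0 < c.max_diameter_mm < 40.0
                assert c.n_lesions >= 1
            else:
                assert c.n_lesions == 0


class TestCrossover:
    def test_balanced_groups_and_reversed_orders(self):
        cases = simulate_truth(20, 0.5, 1)
        readers = assign_crossover(default_roster(StudyConfig(seed=1)), cases, seed=1)
        groups = {}
        for r in readers:
            groups.setdefault(r.group, []).append(r)
        assert sorted(groups) == [1, 2]
        assert all(len(m) == 4 for m in groups.values())
        for members in groups.values():
            orders = {m.case_order for m in members}
            assert len(orders) == 2
            a, b = orders
            assert a == tuple(reversed(b))

    def test_two_readers_split_one_per_group(self):
        cases = simulate_truth(6, 0.5, 0)
        cfg = StudyConfig(n_readers=2, n_radiologists=2)
        readers = assign_crossover(default_roster(cfg), cases, seed=0)
        assert sorted(r.group for r in readers) == [1, 2]

    def test_odd_roster_rejected(self):
        cases = simulate_truth(6, 0.5, 0)
        roster = default_roster(StudyConfig())[:5]
        with pytest.raises(SchemaError):
            assign_crossover(roster, cases, seed=0)

    def test_same_seed_same_orders(self):
        cases = simulate_truth(12, 0.5, 2)
        roster = default_roster(StudyConfig())
        a = assign_crossover(roster, cases, seed=9)
        b = assign_crossover(roster, cases, seed=9)
        assert a == b


class TestAnnotations:
    def test_record_count_and_sessions(self, small_config, small_study):
        cases, readers, annotations = small_study
        assert len(annotations) == small_config.n_cases * small_config.n_readers * 2
        assert {a.session for a in annotations} == set(Session)

    def test_empty_roster_rejected(self):
        cases = simulate_truth(5, 0.5, 0)
        params = GenerativeParams.from_config(StudyConfig())
        with pytest.raises(SchemaError):
            simulate_annotation_matrices(cases, [], params, 0)

    def test_same_seed_identical_matrices(self):
        cfg = StudyConfig(n_cases=25)
        cases = simulate_truth(25, 0.5, 4)
        readers = default_roster(cfg)
        params = GenerativeParams.from_config(cfg)
        m1 = simulate_annotation_matrices(cases, readers, params, 4)
        m2 = simulate_annotation_matrices(cases, readers, params, 4)
        for s in Session:
            assert np.array_equal(m1[s].labels, m2[s].labels)

    def test_null_effect_leaves_sessions_exchangeable(self):
        """With both deltas zero, session sensitivities agree in expectation."""
        cfg = StudyConfig(sens_augmented=0.831, spec_augmented=0.960)
        params = GenerativeParams.from_config(cfg)
        assert params.delta_sens == pytest.approx(0.0, abs=1e-12)
        assert params.delta_spec == pytest.approx(0.0, abs=1e-12)
        cases = simulate_truth(115, 0.5, 0)
        readers = default_roster(cfg)
        pos = np.array([c.truth for c in cases], dtype=bool)
        diffs = []
        for rep in range(60):
            m = simulate_annotation_matrices(cases, readers, params, rep)
            diffs.append(
                m[Session.AUGMENTED].labels[pos].mean()
                - m[Session.UNAUGMENTED].labels[pos].mean()
            )
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / math.sqrt(len(diffs)) + 0.01

    def test_zero_coupling_decorrelates_readers(self):
        """tau = 0: reader false positives on negatives are independent."""
        cfg = StudyConfig(case_coupling=0.0)
        params = GenerativeParams.from_config(cfg)
        cases = simulate_truth(115, 0.5, 1)
        readers = default_roster(cfg)
        neg = ~np.array([c.truth for c in cases], dtype=bool)
        corrs = []
        for rep in range(40):
            labels = simulate_annotation_matrices(cases, readers, params, rep)[
                Session.UNAUGMENTED
            ].labels[neg].astype(float)
            for i in range(0, 8, 2):
                a, b = labels[:, i], labels[:, i + 1]
                if a.std() > 0 and b.std() > 0:
                    corrs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(corrs)) < 0.03

    def test_agreement_rises_with_case_coupling(self):
        """Exact kappa is non-decreasing in tau across a coarse grid."""
        cases = simulate_truth(115, 0.5, 2)
        mean_kappa = []
        for tau in (0.0, 0.75, 1.75):
            cfg = StudyConfig(case_coupling=tau)
            params = GenerativeParams.from_config(cfg)
            readers = default_roster(cfg)
            ks = [
                fleiss_exact_kappa(
                    simulate_annotation_matrices(cases, readers, params, rep)[
                        Session.UNAUGMENTED
                    ]
                ).kappa
                for rep in range(40)
            ]
            mean_kappa.append(np.mean(ks))
        assert mean_kappa[0] < mean_kappa[1] < mean_kappa[2]


class TestTimes:
    def test_entry_times_strictly_increase_per_reader_session(self, small_study):
        cases, readers, annotations = small_study
        by_key = {}
        for a in annotations:
            by_key.setdefault((a.reader_id, a.session), []).append(a.entry_time_s)
        for times in by_key.values():
            t = np.sort(np.array(times))
            assert (np.diff(t) > 0).all()

    def test_degenerate_noise_recovers_the_median_exactly(self):
        cfg = StudyConfig(n_cases=12, p_interruption=0.0,
                          time_median_s=50.0, time_mean_s=50.0 + 1e-9)
        cases = simulate_truth(cfg.n_cases, 0.5, 0)
        readers = assign_crossover(default_roster(cfg), cases, 0)
        params = GenerativeParams.from_config(cfg)
        anns = simulate_times(simulate_annotations(cases, readers, params, 0),
                              readers, params, 0)
        one = sorted(
            (a for a in anns if a.reader_id == "R1" and a.session is Session.UNAUGMENTED),
            key=lambda a: a.entry_time_s,
        )
        durations = np.diff([0.0] + [a.entry_time_s for a in one])
        assert durations == pytest.approx(np.full(12, 50.0), rel=1e-3)

    def test_same_seed_same_times(self, small_config):
        a = simulate_study(small_config)[2]
        b = simulate_study(small_config)[2]
        assert a == b


class TestSegmentation:
    def test_negative_case_binarizes_to_zero(self):
        vol = simulate_segmentation(CaseRecord("n1", 0, 0), seed=1)
        assert vol.shape == (16, 32, 32)
        assert binarize_prediction(vol) == 0

    def test_positive_case_binarizes_to_one(self):
        case = CaseRecord("p1", 1, 1, 8.0)
        vol = simulate_segmentation(case, seed=1)
        assert binarize_prediction(vol) == 1

    def test_same_seed_identical_volume(self):
        case = CaseRecord("p1", 1, 1, 12.0)
        assert np.array_equal(
            simulate_segmentation(case, seed=3), simulate_segmentation(case, seed=3)
        )

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            simulate_segmentation(CaseRecord("n1", 0, 0), shape=(0, 4, 4))

    def test_probabilities_stay_in_unit_interval(self):
        for seed in range(3):
            vol = simulate_segmentation(CaseRecord("p1", 1, 2, 30.0), seed=seed)
            assert vol.min() >= 0.0 and vol.max() <= 1.0
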