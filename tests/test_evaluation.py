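import numpy as np
import pytest

import gripdec as gd
from gripdec.evaluation import CVResult, CVSpec, compare_conditions, \
    make_folds, permutation_test, run_cv, sensitivity_table


class TestFolds:
    def test_loso_one_fold_per_subject(self, velocity_dataset):
        folds = make_folds(velocity_dataset,
                           CVSpec(scheme="leave_one_subject_out"))
        assert len(folds) == 4
        for f in folds:
            assert len(f.test_idx) == 60
            test_subjects = {velocity_dataset.trials[i].subject_id
                             for i in f.test_idx}
            assert test_subjects == {f.subject_id}
            assert set(f.train_idx).isdisjoint(f.test_idx)

    def test_loro_folds_within_subject(self, within_subject_dataset):
        folds = make_folds(within_subject_dataset,
                           CVSpec(scheme="leave_one_run_out"))
        assert len(folds) == 2 * 3  # subjects x runs
        for f in folds:
            trials = within_subject_dataset.trials
            assert {trials[i].subject_id for i in f.train_idx} == {f.subject_id}
            runs_test = {trials[i].run for i in f.test_idx}
            runs_train = {trials[i].run for i in f.train_idx}
            assert len(runs_test) == 1 and runs_test.isdisjoint(runs_train)

    def test_folds_partition_all_trials(self, velocity_dataset):
        for scheme in ("leave_one_subject_out", "two_fold"):
            folds = make_folds(velocity_dataset, CVSpec(scheme=scheme))
            test_union = np.concatenate([f.test_idx for f in folds])
            assert sorted(test_union) == list(range(velocity_dataset.n_trials))

    def test_hand_size_split_separates_at_median(self, velocity_dataset):
        folds = make_folds(velocity_dataset,
                           CVSpec(scheme="two_fold",
                                  split_rule="hand_size_grouped"))
        sizes = {s: m.hand_size for s, m in velocity_dataset.subjects.items()}
        med = np.median(list(sizes.values()))
        trials = velocity_dataset.trials
        small = {sizes[trials[i].subject_id] for i in folds[1].test_idx}
        large = {sizes[trials[i].subject_id] for i in folds[0].test_idx}
        assert max(small) <= med <= min(large)

    def test_matched_split_balances_age_groups(self, velocity_dataset):
        folds = make_folds(velocity_dataset,
                           CVSpec(scheme="two_fold", split_rule="matched"))
        trials = velocity_dataset.trials
        for f in folds:
            groups = [velocity_dataset.subjects[trials[i].subject_id].age_group
                      for i in f.test_idx]
            assert groups.count("young") == groups.count("old")

    def test_age_split_groups_by_age(self, velocity_dataset):
        folds = make_folds(velocity_dataset,
                           CVSpec(scheme="two_fold", split_rule="age_grouped"))
        trials = velocity_dataset.trials
        for f in folds:
            groups = {velocity_dataset.subjects[trials[i].subject_id].age_group
                      for i in f.test_idx}
            assert len(groups) == 1


class TestCvResult:
    def test_da_consistent_with_confusion_matrix(self, velocity_dataset):
        res = run_cv(velocity_dataset,
                     CVSpec(scheme="two_fold", classifier="svm_dtw"))
        cm = res.confusion
        assert cm.sum() == velocity_dataset.n_trials
        np.testing.assert_array_equal(cm.sum(axis=1), 40)  # balanced classes
        assert res.da == pytest.approx(100.0 * np.trace(cm) / cm.sum())
        # balanced classes: mean sensitivity equals overall DA
        assert np.mean(list(res.sensitivities.values())) == \
            pytest.approx(res.da)

    def test_identity_confusion_gives_full_sensitivity(self):
        labels = np.repeat(list(gd.data.TASKS), 5)
        res = CVResult(classes=sorted(set(labels)), true=labels, pred=labels,
                       test_subjects=np.repeat(["S01", "S02"], 15))
        assert res.da == 100.0
        assert all(v == 100.0 for v in res.sensitivities.values())
        np.testing.assert_array_equal(np.diag(res.confusion), 5)

    def test_single_class_labels_warn(self, velocity_dataset):
        sub = velocity_dataset.subset(range(120))  # two subjects
        const = gd.Dataset(
            trials=[t.with_values(t.values) for t in sub.trials],
            subjects=dict(sub.subjects), calibrations=dict(sub.calibrations))
        for t in const.trials:
            t.task = "clothes_peg"
        with pytest.warns(UserWarning, match="single-class"):
            res = run_cv(const, CVSpec(scheme="two_fold", classifier="svm_dtw"))
        assert res.da == 100.0


class TestPermutation:
    def test_two_permutations_reproducible(self, velocity_dataset):
        spec = CVSpec(scheme="two_fold", classifier="svm_dtw")
        r1 = permutation_test(velocity_dataset, spec, 2, seed=3)
        r2 = permutation_test(velocity_dataset, spec, 2, seed=3)
        np.testing.assert_array_equal(r1.das, r2.das)
        assert len(r1.das) == 2

    def test_ci_brackets_mean(self, velocity_dataset):
        spec = CVSpec(scheme="two_fold", classifier="svm_dtw")
        res = permutation_test(velocity_dataset, spec, 100, seed=0)
        assert res.ci[0] <= res.mean <= res.ci[1]
        assert res.threshold == res.ci[1]


class TestCompareConditions:
    def test_identical_vectors_give_p_one(self):
        a = np.full(10, 95.0)
        with pytest.warns(UserWarning):
            assert compare_conditions(a, a) == 1.0

    def test_constant_shift_reaches_minimal_exact_p(self):
        a = np.linspace(90, 99, 17)
        p = compare_conditions(a + 1.0, a)
        assert p == pytest.approx(2.0 ** -16)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=12)
        p = compare_conditions(a + rng.normal(scale=5, size=12), a,
                               n_comparisons=1000)
        assert p <= 1.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1, 2], [3, 4])


class TestSensitivityTable:
    def test_table_shape(self, velocity_dataset):
        res = run_cv(velocity_dataset,
                     CVSpec(scheme="leave_one_subject_out",
                            classifier="svm_dtw"))
        table = sensitivity_table({("svm_dtw", "loso"): res})
        assert list(table.index) == list(gd.data.TASKS)
        assert table.shape == (6, 1)
        assert all("(" in v for v in table.iloc[:, 0])

    def test_cube_direction_pairs_carry_lowest_sensitivities(self):
        """At a noise level where errors appear, the cw/ccw cube pairs —
        which differ only by a small waveform asymmetry — are the hardest
        classes."""
        cfg = gd.SyntheticConfig(n_subjects_per_group=2, runs=1,
                                 noise_sd=0.08, seed=1)
        vel = gd.preprocess_dataset(gd.generate_dataset(cfg))
        res = run_cv(vel, CVSpec(scheme="leave_one_subject_out",
                                 classifier="svm_dtw"))
        sens = res.sensitivities
        cube = [sens[t] for t in gd.data.TASKS if "rubiks" in t]
        other = [sens[t] for t in gd.data.TASKS if "rubiks" not in t]
        assert res.da < 100.0  # errors exist at this noise level
        assert min(other) >= max(cube)
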