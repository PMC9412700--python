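from functools import lru_cache

import numpy as np
import pytest

import gripdec as gd
from gripdec.dtw import (Template, dtw, select_template, to_feature_matrix,
                         warp_to_template)

from conftest import make_trial


def dtw_brute_force(x, y):
    """Independent oracle: memoized recursion over the three path steps."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))

    @lru_cache(maxsize=None)
    def rec(i, j):
        d = float(np.linalg.norm(x[i] - y[j]))
        if i == 0 and j == 0:
            return d
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return d + best

    return rec(len(x) - 1, len(y) - 1)


def random_series(rng, max_len=10, max_ch=3):
    t = rng.integers(1, max_len + 1)
    c = rng.integers(1, max_ch + 1)
    return rng.normal(size=(t, c)), c


class TestDtw:
    def test_identical_series_give_zero_and_diagonal(self):
        x = np.random.default_rng(0).normal(size=(12, 3))
        dist, path = dtw(x, x)
        assert dist == 0.0
        np.testing.assert_array_equal(path,
                                      np.column_stack([np.arange(12)] * 2))

    def test_small_example_matches_exhaustive_minimum(self):
        dist, _ = dtw(np.array([[0.0], [1.0], [2.0]]),
                      np.array([[0.0], [2.0]]))
        assert dist == pytest.approx(dtw_brute_force([[0], [1], [2]],
                                                     [[0], [2]]), abs=1e-12)

    def test_single_sample_sums_all_distances(self):
        a = 1.5
        y = np.array([[0.0], [2.0], [4.0]])
        dist, path = dtw(np.array([[a]]), y)
        assert dist == pytest.approx(np.abs(a - y).sum())
        assert len(path) == 3

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            x, c = random_series(rng)
            y = rng.normal(size=(rng.integers(1, 11), c))
            dist, path = dtw(x, y)
            assert dist == pytest.approx(dtw_brute_force(x, y), abs=1e-9)
            # path axioms: boundary, monotone, continuous, attains distance
            assert tuple(path[0]) == (0, 0)
            assert tuple(path[-1]) == (len(x) - 1, len(y) - 1)
            steps = np.diff(path, axis=0)
            assert np.all((steps >= 0) & (steps <= 1)) and np.all(steps.sum(1) >= 1)
            along = sum(np.linalg.norm(x[p] - y[q]) for p, q in path)
            assert along == pytest.approx(dist, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(9, 2))
        y = rng.normal(size=(6, 2))
        assert dtw(x, y)[0] == pytest.approx(dtw(y, x)[0], abs=1e-12)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            dtw(np.zeros((4, 2)), np.zeros((4, 3)))


class TestTemplateSelection:
    def make_trials(self, arrays):
        return [make_trial(a, stage="velocity") for a in arrays]

    def test_outlier_never_selected(self):
        """A 10x-amplitude outlier yields high normalized distance and a low
        score for every pairing it enters; verified against an exhaustive
        score table computed independently."""
        rng = np.random.default_rng(11)
        base = rng.normal(size=(20, 2))
        arrays = [base + 0.05 * rng.normal(size=base.shape) for _ in range(6)]
        arrays[4] = 10.0 * base  # paired with trial 1
        trials = self.make_trials(arrays)
        template, scores = select_template(trials)

        # independent recomputation of every pairing score
        n, half = 6, 3
        raw, rhos = [], []
        for i in range(half - 1):
            d, path = dtw(arrays[i], arrays[i + half])
            raw.append(d)
            xa = arrays[i][path[:, 0]].ravel()
            ya = arrays[i + half][path[:, 1]].ravel()
            rhos.append(np.corrcoef(xa, ya)[0, 1])
        norm = np.array(raw) / max(raw)
        expected = rhos * (1 - norm)
        for s, e in zip(scores, expected):
            assert s.score == pytest.approx(e, abs=1e-9)
        best = int(np.argmax(expected))
        assert best != 1  # the outlier pairing loses
        assert template.provenance["trial_index"] == best

    def test_identical_trials_pick_first_pairing(self):
        base = np.sin(np.linspace(0, 3, 15))[:, None]
        trials = self.make_trials([base.copy() for _ in range(6)])
        template, scores = select_template(trials)
        assert template.provenance["trial_index"] == 0
        assert all(s.dist == 0.0 and s.score == pytest.approx(1.0)
                   for s in scores)

    def test_scores_bounded_by_rho_and_max_dist_is_one(self):
        rng = np.random.default_rng(3)
        trials = self.make_trials([rng.normal(size=(12, 2)) for _ in range(8)])
        _, scores = select_template(trials)
        assert max(s.dist for s in scores) == pytest.approx(1.0)
        assert all(s.score <= s.rho + 1e-12 for s in scores)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            select_template(self.make_trials([np.zeros((5, 1))] * 3))


class TestWarpToTemplate:
    def test_template_round_trip_is_exact(self):
        x = np.random.default_rng(1).normal(size=(15, 3))
        template = Template(x, 16.0, {})
        out = warp_to_template(make_trial(x, stage="velocity"), template)
        np.testing.assert_array_equal(out.values, x)
        assert out.stage == "aligned"

    def test_hand_worked_compression_example(self):
        # optimal path pairs x0,x1 -> t0 and x2 -> t1; averaging gives [0, 4]
        out = warp_to_template(
            make_trial(np.array([0.0, 0.0, 4.0]), stage="velocity"),
            Template(np.array([[0.0], [4.0]]), 16.0, {}))
        np.testing.assert_allclose(out.values[:, 0], [0.0, 4.0])

    def test_output_length_always_matches_template(self):
        rng = np.random.default_rng(9)
        template = Template(rng.normal(size=(14, 2)), 16.0, {})
        for _ in range(100):
            x = rng.normal(size=(rng.integers(2, 40), 2))
            out = warp_to_template(make_trial(x, stage="velocity"), template)
            assert out.n_samples == 14

    def test_time_rescaled_copies_synchronize(self):
        """Trials that are time-rescaled copies of the template land nearly
        on it after warping (event synchronization)."""
        t = np.linspace(0, 1, 60)
        template_vals = np.column_stack([np.sin(2 * np.pi * 2 * t),
                                         np.cos(2 * np.pi * 3 * t)])
        template = Template(template_vals, 16.0, {})
        t2 = np.linspace(0, 1, 95)
        rescaled = np.column_stack([np.sin(2 * np.pi * 2 * t2),
                                    np.cos(2 * np.pi * 3 * t2)])
        out = warp_to_template(make_trial(rescaled, stage="velocity"), template)
        rms = np.sqrt(np.mean((out.values - template_vals) ** 2))
        assert rms < 0.05


class TestAlignDataset:
    def test_shared_template_gives_equal_feature_lengths(self, velocity_dataset):
        trials = velocity_dataset.trials[:16]
        template, train, test = gd.align_dataset(trials[:12], trials[12:])
        feats_train = to_feature_matrix(train)
        feats_test = to_feature_matrix(test)
        assert feats_train.shape[1] == feats_test.shape[1] == \
            template.n_samples * 15

    def test_empty_test_set_is_valid(self, velocity_dataset):
        template, train, test = gd.align_dataset(velocity_dataset.trials[:8])
        assert test == []
        assert len(train) == 8
        assert all(t.n_samples == template.n_samples for t in train)
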