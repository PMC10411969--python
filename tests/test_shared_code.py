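import itertools

import numpy as np
import pytest

from mirrorcode.action_coding import coding_flags
from mirrorcode.records import BinnedNeuron
from mirrorcode.shared_code import (
    CHANCE,
    NON_SHARED,
    OBS_ONLY,
    SHARED,
    classifier_accuracies,
    cross_task_labels_from_pvalues,
    cross_task_shared,
    preference_index,
    same_discharge,
    same_preference,
)
from mirrorcode.timebase import ACTION_PERIOD_BINS

from conftest import action_rate_map, make_neuron


class TestPreferenceIndex:
    @pytest.mark.parametrize("exe, obs, polarity, expected", [
        ((10, 5, 2), (8, 3, 1), "positive", 1.0),
        ((10, 5, 2), (1, 9, 2), "positive", 0.0),
        ((10, 10, 2), (5, 1, 1), "positive", 1 / np.sqrt(2)),
        ((10, 5, 2), (7, 6, 1), "negative", 1.0),
    ])
    def test_examples(self, exe, obs, polarity, expected):
        idx = preference_index(np.array(exe, float), np.array(obs, float), polarity)
        assert np.isclose(idx, expected)

    def test_all_equal_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            preference_index(np.array([5.0, 5.0, 5.0]), np.array([1.0, 2.0, 3.0]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            exe = rng.uniform(1, 20, 3).round(1)
            obs = rng.uniform(1, 20, 3).round(1)
            if np.ptp(exe) == 0 or np.ptp(obs) == 0:
                continue
            base = preference_index(exe, obs)
            for perm in itertools.permutations(range(3)):
                p = list(perm)
                assert np.isclose(preference_index(exe[p], obs[p]), base)

    def test_range_and_unity_condition(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            exe = rng.integers(0, 6, 3).astype(float)
            obs = rng.integers(0, 6, 3).astype(float)
            if np.ptp(exe) == 0 or np.ptp(obs) == 0:
                continue
            for pol in ("positive", "negative"):
                v = preference_index(exe, obs, pol)
                assert 0.0 <= v <= 1.0 + 1e-12


class TestClassifierAccuracy:
    def test_chance_level_for_flat_neuron(self, flat_neuron):
        rng = np.random.default_rng(2)
        acc = classifier_accuracies(flat_neuron, bins=[10], n_boot=400, rng=rng)
        for mode in ("e2e", "o2o", "e2o", "o2e"):
            d = acc[(10, mode)]
            assert abs(d.mean - CHANCE) < 0.06
            assert np.all((d.accuracies >= 0) & (d.accuracies <= 1))
            assert np.isclose(d.mean, d.accuracies.mean())

    def test_separable_neuron_high_cross_task_accuracy(self, separable_neuron):
        rng = np.random.default_rng(3)
        acc = classifier_accuracies(separable_neuron, bins=[12], n_boot=400, rng=rng)
        e2o, o2o = acc[(12, "e2o")], acc[(12, "o2o")]
        assert e2o.mean > 0.9 and o2o.mean > 0.9
        assert abs(e2o.mean - o2o.mean) < 0.05
        assert e2o.p_vs_chance == 0.0

    def test_task_swapped_neuron_below_chance_cross_task(self):
        rng = np.random.default_rng(4)
        from conftest import FLAT_1600

        rec = make_neuron(
            action_rate_map(5, 0, 30, np.arange(24), obs_preferred=1),
            trials_per_condition=16, rng=rng, duration_model=FLAT_1600)
        neuron = BinnedNeuron.from_recording(rec)
        acc = classifier_accuracies(neuron, bins=[12], n_boot=400,
                                    rng=np.random.default_rng(5))
        assert acc[(12, "o2e")].mean < CHANCE
        assert acc[(12, "e2o")].mean < CHANCE
        assert acc[(12, "e2e")].mean > 0.6

    def test_trial_order_invariance(self):
        """Identical bootstrap results after shuffling the trial list."""
        rng = np.random.default_rng(6)
        rec = make_neuron(action_rate_map(10, 0, 20, np.arange(8, 20)),
                          trials_per_condition=16, rng=rng)
        shuffled = type(rec)(neuron_id=rec.neuron_id, trials=list(rec.trials))
        np.random.default_rng(7).shuffle(shuffled.trials)
        a1 = classifier_accuracies(BinnedNeuron.from_recording(rec), bins=[12],
                                   n_boot=100, rng=np.random.default_rng(8))
        a2 = classifier_accuracies(BinnedNeuron.from_recording(shuffled), bins=[12],
                                   n_boot=100, rng=np.random.default_rng(8))
        for key in a1:
            assert np.array_equal(a1[key].accuracies, a2[key].accuracies)

    def test_too_few_trials_excluded(self):
        rec = make_neuron(lambda t, a: 10.0, trials_per_condition=7,
                          rng=np.random.default_rng(9))
        with pytest.raises(ValueError, match="fewer than 8"):
            classifier_accuracies(BinnedNeuron.from_recording(rec), bins=[12])


@pytest.fixture(scope="module")
def labelled_population():
    """Three coders with known structure in grid bins 12–17 + one flat neuron.

    Neuron 0: identical action maps in both tasks (true shared).
    Neuron 1: preferred action differs between tasks (non-shared).
    Neuron 2: execution rates doubled for one action (same preference, but
              different discharge).
    """
    rng = np.random.default_rng(20)
    bins = np.arange(12, 18)

    def doubled(task, action):
        rates = np.full(24, 10.0)
        if action == "lift":
            rates[bins] += 40.0 if task == "execution" else 20.0
        return rates

    recs = [
        make_neuron(action_rate_map(10, 0, 30, bins), 64, rng, neuron_id=0),
        make_neuron(action_rate_map(10, 0, 30, bins, obs_preferred=1), 64, rng,
                    neuron_id=1),
        make_neuron(doubled, 64, rng, neuron_id=2),
        make_neuron(lambda t, a: 10.0, 64, rng, neuron_id=3),
    ]
    binned = [BinnedNeuron.from_recording(r) for r in recs]
    coding = coding_flags(binned)
    planted = bins - ACTION_PERIOD_BINS[0]
    return binned, coding, planted


class TestSameDischarge:
    def test_shared_and_non_shared_detection(self, labelled_population):
        binned, coding, planted = labelled_population
        labels = same_discharge(binned, coding)
        lab0 = labels[0, planted]
        assert (lab0 == SHARED).mean() > 0.8
        lab2 = labels[2, planted]
        both2 = coding.both_coding()[2, planted]
        assert (lab2[both2] == NON_SHARED).mean() > 0.8

    def test_labels_only_on_coding_bins(self, labelled_population):
        binned, coding, _ = labelled_population
        labels = same_discharge(binned, coding)
        assert (labels[coding.obs_only()] == OBS_ONLY).all()
        outside = ~coding.obs_coding()
        assert (labels[outside] == 0).all()


class TestSamePreference:
    def test_shared_preference_detected(self, labelled_population):
        binned, coding, planted = labelled_population
        labels = same_preference(binned, coding, n_boot=500,
                                 rng=np.random.default_rng(21))
        assert (labels[0, planted] == SHARED).mean() > 0.9
        # same preference despite doubled discharge: neuron 2 is shared here
        both2 = coding.both_coding()[2, planted]
        assert (labels[2, planted][both2] == SHARED).mean() > 0.8

    def test_opposite_preference_never_shared(self, labelled_population):
        binned, coding, planted = labelled_population
        labels = same_preference(binned, coding, n_boot=500,
                                 rng=np.random.default_rng(22))
        assert not (labels[1, planted] == SHARED).any()


class TestCrossTask:
    def test_shared_vs_swapped(self, labelled_population):
        binned, coding, planted = labelled_population
        labels = cross_task_shared(binned, coding, n_boot=500,
                                   rng=np.random.default_rng(23))
        assert (labels[0, planted] == SHARED).mean() > 0.9
        assert not (labels[1, planted] == SHARED).any()

    def test_labels_from_precomputed_pvalues_match(self, labelled_population):
        binned, coding, _ = labelled_population
        n = len(binned)
        p = np.full((n, 12), np.nan)
        rng = np.random.default_rng(24)
        for i, neuron in enumerate(binned):
            acc = classifier_accuracies(neuron, bins=ACTION_PERIOD_BINS,
                                        modes=("e2o",), n_boot=300, rng=rng)
            for j, b in enumerate(ACTION_PERIOD_BINS):
                p[i, j] = acc[(int(b), "e2o")].p_vs_chance
        labels = cross_task_labels_from_pvalues(coding, p)
        assert labels.shape == (n, 12)
        assert (labels[0] == SHARED).any()
        assert not (labels[1] == SHARED).any()
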