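"""One-pass analytic training: averaging, weight rule, routing, calibration."""

import json

import numpy as np
import pytest

from spikeamp.coding import NoResponse
from spikeamp.network import model_to_dict
from spikeamp.neuron import NeuronKind
from spikeamp.training import (
    CalibrationError,
    PatternSet,
    TrainingConfig,
    average_pattern,
    compute_input_weights,
    evaluate,
    fit,
    map_neurons,
    suggest_delta_kappa,
)

CFG = TrainingConfig(delta=1.4, kappa=26.0)


class TestAveragePattern:
    def test_symmetric_mean(self):
        ts = PatternSet(np.array([[1.0, 2, 3], [3, 2, 1]]), np.array([1, 1]))
        assert np.allclose(average_pattern(ts), [2, 2, 2])

    def test_single_pattern_identity(self):
        ts = PatternSet(np.array([[4.0, 5, 6]]), np.array([1]))
        assert np.array_equal(average_pattern(ts), [4, 5, 6])

    def test_against_per_column_loop(self, rng):
        mat = rng.uniform(0, 50, size=(5, 4))
        ts = PatternSet(mat, np.ones(5, dtype=int))
        got = average_pattern(ts)
        for col in range(4):
            s = 0.0
            for row in range(5):
                s += mat[row, col]
            assert got[col] == pytest.approx(s / 5)

    def test_empty_subset_rejected(self):
        ts = PatternSet(np.ones((2, 3)), np.array([0, 0]))
        with pytest.raises(ValueError):
            average_pattern(ts, ts.positive_mask)


class TestWeightRule:
    def test_zero_at_the_offset(self):
        assert compute_input_weights(np.array([26.0]), CFG)[0] == 0.0

    def test_low_average_gives_printed_tonic_scale(self):
        w = compute_input_weights(np.array([6.0]), CFG)[0]
        assert w == pytest.approx(28.0)
        assert 8.08 <= w <= 29.23  # the published tonic weight range

    def test_peak_average_gives_printed_inhibitory_extreme(self):
        w = compute_input_weights(np.array([65.79]), CFG)[0]
        assert w == pytest.approx(-55.71, abs=0.005)

    def test_nonfinite_average_rejected(self):
        with pytest.raises(ValueError):
            compute_input_weights(np.array([float("nan")]), CFG)


class TestNeuronRouting:
    def test_sign_cases_with_zero_mapping_to_tonic(self):
        kinds = map_neurons(np.array([-1.0, 0.0, 1.0]))
        assert kinds == (
            NeuronKind.INHIBITION_INDUCED,
            NeuronKind.TONIC_SPIKING,
            NeuronKind.TONIC_SPIKING,
        )

    def test_elementwise_sign_oracle(self, rng):
        w = rng.normal(0, 20, size=100)
        kinds = map_neurons(w)
        for wi, ki in zip(w, kinds):
            assert (ki == NeuronKind.INHIBITION_INDUCED) == (wi < 0)


class TestSuggestDeltaKappa:
    def test_reference_architecture_anchor(self):
        cfg = suggest_delta_kappa(20)
        assert (cfg.delta, cfg.kappa) == (1.4, 26.0)

    def test_monotone_directions_at_larger_size(self):
        cfg = suggest_delta_kappa(40)
        assert cfg.delta <= 1.4
        assert cfg.kappa >= 26.0

    def test_sweep_stays_in_published_ranges(self):
        for n in range(10, 41):
            cfg = suggest_delta_kappa(n)
            assert 0.95 <= cfg.delta <= 1.4
            assert 26.0 <= cfg.kappa <= 32.0

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="calibrated"):
            suggest_delta_kappa(50)

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            suggest_delta_kappa(0)


class TestFit:
    def test_degenerate_identical_patterns_give_zero_threshold(self):
        row = np.concatenate([np.full(4, 5.0), [40.0, 30.0, 20.0], np.full(3, 5.0)])
        ts = PatternSet(np.tile(row, (8, 1)), np.ones(8, dtype=int))
        model = fit(ts)
        assert model.se_threshold == 0.0
        ev = evaluate(model, ts)
        assert ev.confusion.tp == 8 and ev.confusion.fn == 0

    def test_refit_is_byte_identical(self, bench20):
        a = json.dumps(model_to_dict(fit(bench20)), sort_keys=True)
        b = json.dumps(model_to_dict(fit(bench20)), sort_keys=True)
        assert a == b

    def test_negative_labels_do_not_influence_weights(self, rng, bench20):
        pos = bench20.standardized().positives()
        neg_a = rng.uniform(0, 50, size=(10, 20))
        neg_b = rng.uniform(0, 50, size=(10, 20))
        gain = 0.05  # pin the gain so only the weight mapping is compared
        ts_a = PatternSet(
            np.vstack([pos, neg_a]),
            np.concatenate([np.ones(len(pos), int), np.zeros(10, int)]),
        )
        ts_b = PatternSet(
            np.vstack([pos, neg_b]),
            np.concatenate([np.ones(len(pos), int), np.zeros(10, int)]),
        )
        m_a = fit(ts_a, input_gain=gain)
        m_b = fit(ts_b, input_gain=gain)
        assert np.array_equal(m_a.w1, m_b.w1)
        assert m_a.neuron_map == m_b.neuron_map

    def test_strict_all_pattern_average_changes_weights(self, bench20):
        default = fit(bench20, input_gain=0.05)
        strict = fit(bench20, input_gain=0.05, use_all_patterns=True)
        assert not np.array_equal(default.w1, strict.w1)

    def test_unresponsive_positives_raise_calibration_error(self):
        # all-zero positives leave every tonic neuron silent at any gain
        ts = PatternSet(np.zeros((5, 10)), np.ones(5, dtype=int))
        with pytest.raises((CalibrationError, ValueError)):
            fit(ts)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            fit(PatternSet(np.zeros((0, 5)), np.zeros(0, dtype=int)))


class TestPatternSet:
    def test_labels_must_be_binary(self):
        with pytest.raises(ValueError):
            PatternSet(np.ones((2, 3)), np.array([0, 2]))

    def test_label_count_must_match(self):
        with pytest.raises(ValueError):
            PatternSet(np.ones((2, 3)), np.array([1]))

    def test_standardized_clips_at_zero(self):
        ts = PatternSet(np.array([[-1.0, 2.0]]), np.array([1]))
        assert np.array_equal(ts.standardized().patterns, [[0.0, 2.0]])


class TestEvaluate:
    def test_requires_trained_model(self, bench20):
        untrained = fit(bench20, input_gain=0.05)
        untrained = untrained.with_weights(untrained.w1, untrained.w2)
        from dataclasses import replace

        bare = replace(untrained, code_mode=None, se_threshold=None)
        with pytest.raises(ValueError, match="trained"):
            evaluate(bare, bench20)

    def test_confusion_total_matches_set_size(self, eval20, bench20):
        assert eval20.confusion.total == bench20.n_patterns

    def test_every_positive_training_pattern_responds(self, eval20):
        assert eval20.confusion.fn + eval20.confusion.tp == 40
        assert all(not isinstance(se, NoResponse) for se in eval20.positive_ses)
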