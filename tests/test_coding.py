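"""Latency-code extraction, squared-error scoring and classification metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeamp.coding import (
    NO_RESPONSE,
    ConfusionCounts,
    NoResponse,
    ResponseCode,
    accuracy,
    classify,
    extract_latencies,
    first_spike_classify,
    max_sampling_frequency,
    mse,
    squared_error,
)
from spikeamp.neuron import SpikeTrain

MODE = ResponseCode(3.0, 3.0)


def train(*times):
    return SpikeTrain(times=np.asarray(times, dtype=float), duration=100.0)


class TestSquaredError:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ((3, 3), 0), ((4, 5), 5), ((4, 6), 10), ((5, 7), 20),
            ((8, 4), 26), ((8, 5), 29), ((9, 4), 37), ((18, 15), 369),
            ((19, 15), 400), ((25, 13), 584), ((27, 8), 601),
        ],
    )
    def test_printed_response_table_values(self, code, expected):
        assert squared_error(ResponseCode(*code), MODE) == expected

    def test_brute_force_oracle_on_random_pairs(self, rng):
        codes = rng.integers(1, 40, size=(10_000, 4))
        for a1, a2, b1, b2 in codes:
            expected = 0.0
            for x, y in ((a1, b1), (a2, b2)):  # explicit component loop
                expected += (float(y) - float(x)) ** 2
            got = squared_error(
                ResponseCode(float(a1), float(a2)), ResponseCode(float(b1), float(b2))
            )
            assert got == expected


class TestMse:
    def test_single_element_reduces_to_squared_error(self):
        assert mse([ResponseCode(5, 7)], MODE) == squared_error(ResponseCode(5, 7), MODE)

    def test_two_element_mean(self):
        assert mse([ResponseCode(3, 3), ResponseCode(5, 7)], MODE) == pytest.approx(10.0)

    def test_permutation_invariant(self, rng):
        codes = [ResponseCode(*c) for c in rng.integers(1, 30, size=(8, 2))]
        shuffled = list(codes)
        rng.shuffle(shuffled)
        assert mse(codes, MODE) == pytest.approx(mse(shuffled, MODE))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse([], MODE)


class TestExtractLatencies:
    def test_first_latency_and_interspike_interval(self):
        assert extract_latencies(train(3.0, 6.0), k=2) == (3.0, 3.0)
        assert extract_latencies(train(4.0, 10.0), k=2) == (4.0, 6.0)

    def test_single_spike_boundary(self):
        assert extract_latencies(train(5.0), k=1) == (5.0,)
        assert isinstance(extract_latencies(train(5.0), k=2), NoResponse)

    def test_quantization_to_bin(self):
        assert extract_latencies(train(3.4, 6.1), k=2, bin_ms=1.0) == (3.0, 3.0)
        assert extract_latencies(train(3.4, 6.1), k=2, bin_ms=0.5) == (3.5, 2.5)

    def test_sub_bin_latency_reads_as_one_bin(self):
        assert extract_latencies(train(0.2, 0.4), k=2, bin_ms=1.0) == (1.0, 1.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            extract_latencies(train(1.0), k=0)
        with pytest.raises(ValueError):
            extract_latencies(train(1.0), k=1, bin_ms=0.0)


class TestClassify:
    def test_threshold_is_inclusive(self):
        assert classify(10.0, 10.0) is True

    def test_above_threshold_is_negative(self):
        assert classify(20.0, 10.0) is False

    def test_no_response_is_negative(self):
        assert classify(NO_RESPONSE, 10.0) is False

    def test_raising_threshold_never_flips_positive_to_negative(self, rng):
        ses = rng.uniform(0, 50, size=200)
        low = ses <= 10.0
        high = ses <= 25.0
        assert np.all(high[low])  # everything accepted at 10 stays accepted at 25


class TestAccuracy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((40, 38, 2, 0), 0.975),
            ((40, 37, 3, 0), 0.9625),
            ((40, 40, 0, 0), 1.0),
        ],
    )
    def test_printed_confusion_rows(self, counts, expected):
        tp, tn, fp, fn = counts
        assert accuracy(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_bounds_and_perfection_condition(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        if c.total == 0:
            return
        acc = accuracy(c)
        assert 0.0 <= acc <= 1.0
        assert (acc == 1.0) == (fp == 0 and fn == 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestMaxSamplingFrequency:
    def test_printed_positive_maxima_give_100_hz(self):
        codes = [ResponseCode(3, 3), ResponseCode(4, 5), ResponseCode(4, 6)]
        assert max_sampling_frequency(codes) == pytest.approx(100.0)

    def test_single_code(self):
        assert max_sampling_frequency([ResponseCode(10, 10)]) == pytest.approx(50.0)

    def test_dominated_code_leaves_result_unchanged(self):
        base = [ResponseCode(4, 5), ResponseCode(3, 6)]
        extended = base + [ResponseCode(2, 2)]
        assert max_sampling_frequency(base) == max_sampling_frequency(extended)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_sampling_frequency([])


class TestFirstSpikeBaseline:
    def test_reduces_se_by_exactly_the_second_component(self):
        code = ResponseCode(5.0, 9.0)
        full = squared_error(code, MODE)
        first_only = (code.dt1 - MODE.dt1) ** 2
        assert full - first_only == (code.dt2 - MODE.dt2) ** 2

    def test_equivalent_to_two_latency_rule_when_dt2_constant(self):
        trains = [train(3.0, 6.0), train(5.0, 8.0), train(9.0, 12.0)]
        one = first_spike_classify(trains, mode_dt1=3.0, threshold=4.0)
        two = []
        for t in trains:
            c = extract_latencies(t, k=2)
            se = squared_error(ResponseCode(*c), ResponseCode(3.0, 3.0))
            two.append(se <= 4.0)
        assert one == two  # all dt2 equal the mode's, so the rules agree

    def test_no_response_counts_negative(self):
        assert first_spike_classify([train()], mode_dt1=3.0, threshold=100.0) == [False]


def test_response_code_requires_positive_latencies():
    with pytest.raises(ValueError):
        ResponseCode(0.0, 3.0)


def test_no_response_is_a_singleton():
    assert NoResponse() is NO_RESPONSE
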