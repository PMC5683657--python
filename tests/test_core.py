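"""Windowing primitives, spike bookkeeping and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popcode import (
    InsufficientSpikesError,
    SpikeTrainSet,
    StimulusSet,
    ValidationError,
    Window,
    count_spikes,
    population_response,
    rate_in_window,
    read_spike_data,
    sliding_windows,
    spike_count_window,
    write_spike_data,
)
from conftest import make_spiketrainset


class TestCountSpikes:
    @pytest.mark.parametrize(
        "train, window, expected",
        [
            ([], Window(0, 100), 0),
            ([10, 20, 35], Window(10, 15), 2),  # start inclusive, end exclusive
            (np.arange(500.0), Window(0, 15), 15),  # one spike per ms
            ([9.999, 25.0], Window(10, 15), 0),  # end boundary excluded
        ],
    )
    def test_examples(self, train, window, expected):
        assert count_spikes(np.asarray(train, dtype=float), window) == expected

    def test_brute_force_oracle(self, rng):
        train = np.sort(rng.uniform(0, 500, size=300))
        w = Window(123.4, 61.7)
        brute = int(np.sum((train >= w.start) & (train < w.end)))
        assert count_spikes(train, w) == brute

    @settings(derandomize=True, max_examples=50)
    @given(
        times=st.lists(st.floats(0, 100), max_size=40),
        a=st.floats(0, 50),
        mid=st.floats(1, 25),
        rest=st.floats(1, 25),
    )
    def test_partition_conservation(self, times, a, mid, rest):
        """Counts over [a,b) + [b,c) equal the count over [a,c)."""
        train = np.sort(np.asarray(times))
        b, c = a + mid, a + mid + rest
        total = count_spikes(train, Window(a, c - a))
        assert total == count_spikes(train, Window(a, mid)) + count_spikes(
            train, Window(b, c - b)
        )


class TestRateInWindow:
    def test_rate_units(self):
        train = np.array([1.0, 5.0, 10.0])
        assert rate_in_window(train, Window(0, 15)) == pytest.approx(200.0)
        assert rate_in_window(np.empty(0), Window(0, 15)) == 0.0

    def test_matches_count(self, rng):
        train = np.sort(rng.uniform(0, 100, size=10))
        w = Window(0, 50)
        assert rate_in_window(train, w) == pytest.approx(
            count_spikes(train, w) / 0.050
        )

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            Window(0, 0)


class TestSlidingWindows:
    def test_default_scheme(self):
        wins = sliding_windows((0, 500), 15, 5)
        assert len(wins) == 98
        assert (wins[0].start, wins[0].end) == (0, 15)
        assert (wins[-1].start, wins[-1].end) == (485, 500)

    def test_single_and_empty(self):
        assert len(sliding_windows((0, 15), 15, 5)) == 1
        assert sliding_windows((0, 10), 15, 5) == []

    @settings(derandomize=True, max_examples=50)
    @given(
        span=st.floats(20, 1000),
        length=st.floats(1, 100),
        step=st.floats(0.5, 50),
    )
    def test_count_formula(self, span, length, step):
        wins = sliding_windows((0, span), length, step)
        if span >= length:
            assert len(wins) == int(np.floor((span - length) / step + 1e-9)) + 1
        for w in wins:
            assert w.end <= span + 1e-6


class TestSpikeCountWindow:
    def test_uniform_fixture(self):
        # 100 pooled spikes, one per ms at integer times 0..99
        data = make_spiketrainset(
            {(0, 0, 0): np.arange(50.0), (1, 0, 0): np.arange(50.0, 100.0)}
        )
        w = spike_count_window(data, 0.0, 100)
        assert w.length == 100.0
        # brute-force accumulation oracle: count grows 1 spike per added ms
        for target in (1, 37, 99):
            assert spike_count_window(data, 0.0, target).length == float(target)

    def test_single_spike(self):
        data = make_spiketrainset({(0, 0, 0): [10.0]})
        assert spike_count_window(data, 10.0, 1).length == 1.0

    def test_insufficient_spikes(self):
        data = make_spiketrainset({(0, 0, 0): [10.0, 20.0]})
        with pytest.raises(InsufficientSpikesError) as exc:
            spike_count_window(data, 15.0, 5)
        assert exc.value.achieved == 1

    def test_superposition_never_lengthens(self, rng):
        """Doubling every neuron's spikes cannot lengthen the window."""
        times = np.sort(rng.uniform(0, 400, size=60))
        base = make_spiketrainset({(0, 0, 0): times})
        doubled = make_spiketrainset(
            {(0, 0, 0): times, (1, 0, 0): np.sort(rng.uniform(0, 400, size=60))}
        )
        for target in (5, 20, 50):
            assert (
                spike_count_window(doubled, 0.0, target).length
                <= spike_count_window(base, 0.0, target).length
            )


class TestPopulationResponse:
    def test_known_counts(self):
        data = make_spiketrainset(
            {(0, 0, 0): [1.0, 2.0, 3.0], (1, 0, 0): []}, n_stimuli=1
        )
        X, y = population_response(data, Window(0, 15))
        assert X.shape == (1, 2)
        np.testing.assert_allclose(X[0], [200.0, 0.0])
        assert list(y) == [0]

    def test_all_silent_is_zero_vector(self):
        data = make_spiketrainset({}, n_neurons=3, n_stimuli=2, n_trials=2)
        X, _ = population_response(data, Window(0, 50))
        assert np.all(X == 0)

    def test_elementwise_oracle(self, small_pop):
        w = Window(20, 15)
        X, y = population_response(small_pop, w)
        S, T = small_pop.stimuli.n_stimuli, small_pop.n_trials
        for row in range(0, S * T, 7):
            s, tr = divmod(row, T)
            expected = [
                count_spikes(small_pop.train(n, s, tr), w) / 0.015
                for n in small_pop.neurons
            ]
            np.testing.assert_allclose(X[row], expected)
            assert y[row] == s


class TestValidation:
    def test_spikes_outside_span_rejected(self):
        with pytest.raises(ValidationError):
            make_spiketrainset({(0, 0, 0): [2000.0]})

    def test_unknown_ids_rejected(self):
        with pytest.raises(ValidationError):
            make_spiketrainset({(9, 0, 0): [1.0]})
        with pytest.raises(ValidationError):
            make_spiketrainset({(0, 7, 0): [1.0]})


class TestIO:
    def test_round_trip_csv_and_json(self, tmp_path):
        data = make_spiketrainset(
            {(0, 0, 0): [1.25, 2.5], (1, 1, 0): [-100.0, 3.75]}, n_stimuli=2
        )
        for fmt, name in (("csv", "d.csv"), ("json", "d.json")):
            p = tmp_path / name
            write_spike_data(data, p, format=fmt)
            back = read_spike_data(p, format=fmt)
            assert back.neurons == data.neurons
            assert back.n_trials == data.n_trials
            assert back.stimuli.frequencies == data.stimuli.frequencies
            for key, times in data.items():
                np.testing.assert_allclose(back.train(*key), times, atol=1e-3)

    def test_round_trip_population_checksum(self, small_pop, tmp_path):
        p = tmp_path / "pop.csv"
        write_spike_data(small_pop, p)
        back = read_spike_data(p)
        assert back.total_spikes() == small_pop.total_spikes()
        for key, times in small_pop.items():
            assert back.train(*key).size == times.size

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("neuron_id,stimulus_id,spike_time_ms\n0,0,1.0\n")
        (tmp_path / "bad.csv.manifest.json").write_text("{}")
        with pytest.raises(ValidationError, match="trial"):
            read_spike_data(p)
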