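import numpy as np
import pytest

from popcode import (
    PopulationConfig,
    SpikeTrainSet,
    StimulusSet,
    build_rate_profile,
    generate_population,
    sample_spike_trains,
)


@pytest.fixture(scope="session")
def default_pop():
    """The main-study-scale synthetic population: 171 neurons, 6 tones, 20 trials."""
    return generate_population(seed=0)


@pytest.fixture(scope="session")
def small_pop():
    """A reduced population (30 neurons) for fast unit tests."""
    cfg = PopulationConfig(n_neurons=30, seed=11)
    return sample_spike_trains(build_rate_profile(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_spiketrainset(spikes, n_neurons=2, n_stimuli=2, n_trials=1, span=(-300.0, 1200.0)):
    """Small hand-built SpikeTrainSet from a {(n, s, tr): times} dict."""
    return SpikeTrainSet(
        neurons=list(range(n_neurons)),
        stimuli=StimulusSet.octave_tones(n_tones=n_stimuli),
        n_trials=n_trials,
        spikes={k: np.asarray(v, dtype=float) for k, v in spikes.items()},
        record_span=span,
    )
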