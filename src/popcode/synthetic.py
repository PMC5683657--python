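"""Inhomogeneous-Poisson synthetic populations.

The generator emulates the structure of sequentially recorded primary
auditory cortex (A1) populations responding to pure tones: a strong,
broadly tuned onset transient that adapts within tens of milliseconds to a
sparse, narrowly tuned sustained response, on top of low spontaneous
activity, with Poisson spike statistics throughout.

Each neuron n has a best frequency ``f_n`` (log-uniform over the tone
range) and an intended rate for stimulus s at time t:

    r(t) = spont_n + G(dOct; w(t)) * A(t)

where ``dOct = |log2(f_s / f_n)|``, ``G`` is a Gaussian tuning curve with
time-varying octave width ``w(t)``, and ``A(t)`` jumps to an onset peak at
the response latency and decays exponentially (time constant ``tau``) to
the sustained rate, returning to zero after sound offset.  Differential
adaptation — the narrowing of tuning over time, which silences off-best
responses while best-frequency responses persist — is implemented by
shrinking ``w(t)`` from the onset width to the sustained width with the
same time constant.  A "uniform" mode freezes the width so that all evoked
responses adapt by the same ratio instead.

Spike trains are drawn by per-millisecond Poisson binning (counts per 1-ms
bin with the bin's intended rate, spike times jittered uniformly within
the bin), which reproduces expected counts exactly and is fast at desk
scale.  Noise correlations between neurons are deliberately absent:
sequential recordings carry none.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import SpikeTrainSet, StimulusSet, ValidationError

__all__ = [
    "PopulationConfig",
    "RateProfile",
    "build_rate_profile",
    "sample_spike_trains",
    "generate_population",
    "default_config",
    "nine_tone_config",
    "seventeen_tone_config",
    "simulate_count_population",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the synthetic A1-like population.

    Rates are in spikes/s, times in ms.  ``spontaneous_rate`` is a
    per-neuron uniform draw range; evoked rates get a modest log-normal
    per-neuron jitter (``rate_jitter`` is the log-sd) so neurons are
    heterogeneous.  ``adaptation_mode`` selects differential (tuning width
    narrows over time; the default, matching the recorded populations) or
    uniform (width fixed; all evoked rates adapt by a common ratio)
    adaptation.
    """

    n_neurons: int = 171
    stimuli: StimulusSet = field(default_factory=StimulusSet.octave_tones)
    n_trials: int = 20
    spontaneous_rate: tuple[float, float] = (1.0, 5.0)
    onset_peak_rate: float = 60.0
    sustained_rate: float = 12.0
    response_latency: float = 15.0
    adaptation_tau: float = 60.0
    tuning_width_onset: float = 1.2
    tuning_width_sustained: float = 0.35
    rate_jitter: float = 0.3
    adaptation_mode: str = "differential"
    record_span: tuple[float, float] = (-300.0, 1200.0)
    seed: int = 0

    def __post_init__(self):
        if not (self.onset_peak_rate >= self.sustained_rate >= 0):
            raise ValidationError("need onset_peak_rate >= sustained_rate >= 0")
        if self.tuning_width_onset < self.tuning_width_sustained:
            raise ValidationError("onset tuning must be at least as broad as sustained")
        if self.adaptation_mode not in ("differential", "uniform"):
            raise ValidationError(f"unknown adaptation_mode {self.adaptation_mode!r}")


@dataclass
class RateProfile:
    """Intended instantaneous rates on a 1-ms grid.

    ``rates[n, s, b]`` is the rate (spikes/s) of neuron n for stimulus s in
    the 1-ms bin starting at ``t_min + b`` ms.
    """

    rates: np.ndarray  # (n_neurons, n_stimuli, n_bins)
    t_min: float
    config: PopulationConfig
    best_frequencies: np.ndarray  # (n_neurons,)
    spontaneous: np.ndarray  # (n_neurons,)

    def rate(self, neuron: int, stimulus: int, t: float) -> float:
        """Intended rate at time t (ms, nearest 1-ms bin)."""
        b = int(np.floor(t - self.t_min))
        b = min(max(b, 0), self.rates.shape[2] - 1)
        return float(self.rates[neuron, stimulus, b])


def build_rate_profile(config: PopulationConfig) -> RateProfile:
    """Deterministically build intended rates from a config (seeded draws)."""
    rng = np.random.default_rng(config.seed)
    n, S = config.n_neurons, config.stimuli.n_stimuli
    freqs = np.asarray(config.stimuli.frequencies)
    lo, hi = np.log2(freqs[0]), np.log2(freqs[-1])
    if S == 1:
        best = np.full(n, freqs[0])
    else:
        best = 2.0 ** rng.uniform(lo, hi, size=n)
    spont = rng.uniform(*config.spontaneous_rate, size=n)
    jitter = np.exp(
        rng.normal(0.0, config.rate_jitter, size=n) - config.rate_jitter**2 / 2.0
    )
    peak = config.onset_peak_rate * jitter
    sust = config.sustained_rate * jitter

    t_min, t_max = config.record_span
    n_bins = int(round(t_max - t_min))
    t = t_min + np.arange(n_bins) + 0.5  # bin centres
    on = config.response_latency
    off = config.stimuli.duration + config.response_latency
    driven = (t >= on) & (t < off)
    decay = np.exp(-(t[driven] - on) / config.adaptation_tau)

    # amplitude envelope per neuron: sustained + (peak - sustained) * decay
    A = np.zeros((n, n_bins))
    A[:, driven] = sust[:, None] + (peak - sust)[:, None] * decay[None, :]

    # tuning width over the same time course
    w = np.full(n_bins, config.tuning_width_onset)
    if config.adaptation_mode == "differential":
        w[driven] = config.tuning_width_sustained + (
            config.tuning_width_onset - config.tuning_width_sustained
        ) * decay

    d_oct = np.abs(np.log2(freqs[None, :] / best[:, None]))  # (n, S)
    G = np.exp(-0.5 * (d_oct[:, :, None] / w[None, None, :]) ** 2)  # (n, S, B)
    rates = spont[:, None, None] + G * A[:, None, :]
    return RateProfile(
        rates=rates, t_min=t_min, config=config, best_frequencies=best, spontaneous=spont
    )


def sample_spike_trains(
    profile: RateProfile, n_trials: int | None = None, seed: int | None = None
) -> SpikeTrainSet:
    """Draw spike trains from a rate profile (inhomogeneous Poisson).

    Counts per 1-ms bin are Poisson with the bin's intended mean; spike
    times are jittered uniformly inside the bin.  Identical
    (profile, n_trials, seed) inputs reproduce the same SpikeTrainSet.
    """
    cfg = profile.config
    if n_trials is None:
        n_trials = cfg.n_trials
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n, S, B = profile.rates.shape
    lam = profile.rates * 1e-3  # expected count per 1-ms bin
    spikes: dict[tuple[int, int, int], np.ndarray] = {}
    bin_starts = profile.t_min + np.arange(B)
    for tr in range(n_trials):
        counts = rng.poisson(lam)  # (n, S, B)
        for i in range(n):
            for s in range(S):
                row = counts[i, s]
                nz = np.nonzero(row)[0]
                if nz.size == 0:
                    spikes[(i, s, tr)] = np.empty(0)
                    continue
                reps = row[nz]
                starts = np.repeat(bin_starts[nz], reps)
                times = starts + rng.random(starts.size)
                spikes[(i, s, tr)] = np.sort(times)
    return SpikeTrainSet(
        neurons=list(range(n)),
        stimuli=cfg.stimuli,
        n_trials=n_trials,
        spikes=spikes,
        record_span=cfg.record_span,
    )


def generate_population(config: PopulationConfig | None = None, seed: int | None = None) -> SpikeTrainSet:
    """Convenience: build the rate profile and sample one population."""
    cfg = config if config is not None else default_config()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return sample_spike_trains(build_rate_profile(cfg))


def default_config(seed: int = 0, **overrides) -> PopulationConfig:
    """The main-study stand-in: 171 neurons, 6 octave-spaced tones, 20 trials."""
    return PopulationConfig(seed=seed, **overrides)


def nine_tone_config(seed: int = 0) -> PopulationConfig:
    """Fine-frequency variant: 478 neurons, 9 tones 1/8 octave apart, 100-ms tones, 5 trials."""
    return PopulationConfig(
        n_neurons=478,
        stimuli=StimulusSet.octave_tones(n_tones=9, f_low=8000.0, spacing_octaves=0.125, duration=100.0),
        n_trials=5,
        record_span=(-300.0, 800.0),
        seed=seed,
    )


def seventeen_tone_config(seed: int = 0) -> PopulationConfig:
    """Fine-frequency variant: 376 neurons, 17 tones 1/16 octave apart, 100-ms tones, 5 trials."""
    return PopulationConfig(
        n_neurons=376,
        stimuli=StimulusSet.octave_tones(n_tones=17, f_low=8000.0, spacing_octaves=0.0625, duration=100.0),
        n_trials=5,
        record_span=(-300.0, 800.0),
        seed=seed,
    )


def simulate_count_population(
    base_rates: np.ndarray,
    k_r: float,
    k_T: float,
    T: float,
    n_trials: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Pure count-matrix Poisson simulation for the adaptation experiments.

    Each simulated count for neuron p, stimulus q is drawn Poisson with mean
    ``k_r * r_pq * k_T * T`` (rates in spikes/s, T in seconds); the rate and
    window scale factors apply to the whole population at once.  Returns an
    integer array of shape ``(n_neurons, n_stimuli, n_trials)``.
    """
    base_rates = np.asarray(base_rates, dtype=float)
    if np.any(base_rates < 0):
        raise ValidationError("base rates must be non-negative")
    if k_r <= 0 or k_T <= 0 or T <= 0:
        raise ValidationError("k_r, k_T and T must be positive")
    rng = np.random.default_rng(seed)
    mean = k_r * base_rates * k_T * T
    return rng.poisson(mean[:, :, None], size=mean.shape + (n_trials,))
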