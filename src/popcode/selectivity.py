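"""Per-neuron response selectivity over time.

Selectivity is quantified as the number of *effective stimuli*: stimuli
whose evoked spiking rate in a sliding test window significantly exceeds
the neuron's spontaneous rate.  Significance uses the exact Poisson
conditional test (binomial test on the split of the pooled count between
the test and reference exposures), with Bonferroni correction over the
tested family.  The more stimuli a neuron responds to, the lower its
selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SpikeTrainSet, ValidationError, sliding_windows

__all__ = [
    "SelectivityProfile",
    "poisson_conditional_test",
    "effective_stimulus_profile",
    "selectivity_profiles",
    "select_broad_tuning_subset",
]


def poisson_conditional_test(
    count_test: int, exposure_test: float, count_ref: int, exposure_ref: float
) -> float:
    """One-sided exact test of rate_test > rate_ref for two Poisson counts.

    Conditions on the total count n = count_test + count_ref, under which
    count_test ~ Binomial(n, e_t / (e_t + e_r)) when the rates are equal;
    returns p = P(X >= count_test).  With no spikes at all, p = 1.
    """
    if exposure_test <= 0 or exposure_ref <= 0:
        raise ValidationError("exposures must be positive")
    if count_test < 0 or count_ref < 0:
        raise ValidationError("counts must be non-negative")
    n = count_test + count_ref
    if n == 0:
        return 1.0
    frac = exposure_test / (exposure_test + exposure_ref)
    return float(stats.binom.sf(count_test - 1, n, frac))


@dataclass
class SelectivityProfile:
    """Effective-stimulus counts for one neuron over sliding test windows."""

    neuron: int
    times: np.ndarray  # window start times, ms
    effective_count: np.ndarray  # ints in [0, n_stimuli]
    window_length: float
    alpha: float
    correction: str  # "bonferroni" or "none"
    family: str  # "recording" or "window"

    def max_in(self, t0: float, t1: float) -> int:
        """Maximum effective count over windows starting in [t0, t1)."""
        m = (self.times >= t0) & (self.times < t1)
        return int(self.effective_count[m].max()) if m.any() else 0

    def median_in(self, t0: float, t1: float) -> float:
        m = (self.times >= t0) & (self.times < t1)
        return float(np.median(self.effective_count[m])) if m.any() else 0.0


def _windowed_counts(
    data: SpikeTrainSet, neuron: int, starts: np.ndarray, length: float
) -> np.ndarray:
    """Spike counts pooled over trials, per (stimulus, window), one neuron."""
    S = data.stimuli.n_stimuli
    out = np.zeros((S, starts.size), dtype=np.int64)
    ends = starts + length
    for s in range(S):
        for tr in range(data.n_trials):
            train = data.train(neuron, s, tr)
            if train.size == 0:
                continue
            out[s] += np.searchsorted(train, ends, side="left") - np.searchsorted(
                train, starts, side="left"
            )
    return out


def effective_stimulus_profile(
    data: SpikeTrainSet,
    neuron: int,
    alpha: float = 0.05,
    window_length: float = 50.0,
    step: float = 1.0,
    correction: str = "bonferroni",
    family: str = "recording",
    baseline_span: tuple[float, float] = (-300.0, 0.0),
) -> SelectivityProfile:
    """Effective-stimulus count over time for one neuron.

    Windows of ``window_length`` ms slide in ``step``-ms increments over the
    whole recording.  For each (stimulus, window), the spike count pooled
    across trials is tested against the spontaneous reference — the count
    pooled across all trials and stimuli in ``baseline_span`` — with the
    Poisson conditional test; Bonferroni correction spans either the whole
    recording's windows x stimuli (``family="recording"``, default) or just
    the stimuli within each window (``family="window"``).
    """
    t_min, t_max = data.record_span
    windows = sliding_windows((t_min, t_max), window_length, step)
    starts = np.array([w.start for w in windows])
    S = data.stimuli.n_stimuli

    b0, b1 = baseline_span
    ref_count = 0
    for s in range(S):
        for tr in range(data.n_trials):
            train = data.train(neuron, s, tr)
            if train.size:
                ref_count += int(
                    np.searchsorted(train, b1, side="left")
                    - np.searchsorted(train, b0, side="left")
                )
    ref_exposure = (b1 - b0) / 1000.0 * data.n_trials * S
    test_exposure = window_length / 1000.0 * data.n_trials

    counts = _windowed_counts(data, neuron, starts, window_length)  # (S, W)
    frac = test_exposure / (test_exposure + ref_exposure)
    totals = counts + ref_count
    pvals = stats.binom.sf(counts - 1, totals, frac)

    if correction == "bonferroni":
        m = counts.size if family == "recording" else S
        pvals = np.minimum(pvals * m, 1.0)
    elif correction != "none":
        raise ValidationError(f"unknown correction {correction!r}")

    eff = (pvals < alpha).sum(axis=0)
    return SelectivityProfile(
        neuron=neuron,
        times=starts,
        effective_count=eff.astype(np.int64),
        window_length=window_length,
        alpha=alpha,
        correction=correction,
        family=family,
    )


def selectivity_profiles(data: SpikeTrainSet, **kw) -> list[SelectivityProfile]:
    """Effective-stimulus profiles for every neuron in the set."""
    return [effective_stimulus_profile(data, n, **kw) for n in data.neurons]


def select_broad_tuning_subset(
    profiles: list[SelectivityProfile],
    onset_span: tuple[float, float] = (0.0, 200.0),
    sustained_span: tuple[float, float] = (200.0, 500.0),
) -> tuple[list[int], list[int]]:
    """Split neurons by differential selectivity.

    A neuron joins the broadly tuned subset when (1) its maximum
    effective-stimulus count in the onset span exceeds the maximum in the
    sustained span, and (2) its median effective count in the sustained
    span is at least 1.  Returns (subset ids, complement ids); the two
    lists partition the population.
    """
    subset, complement = [], []
    for p in profiles:
        c1 = p.max_in(*onset_span) > p.max_in(*sustained_span)
        c2 = p.median_in(*sustained_span) >= 1.0
        (subset if (c1 and c2) else complement).append(p.neuron)
    return subset, complement
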