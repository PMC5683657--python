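"""Mutual information between stimuli and windowed spike counts.

Information is computed from spike-count distributions: the mutual
information between the (equiprobable) stimulus set and a neuron's count
in a read-out window is the total entropy of the count distribution
pooled across stimuli minus the mean of the per-stimulus conditional
entropies,

    I = H_T - (1/N) * sum_i H_i ,

with all entropies in bits and probabilities estimated by frequency of
occurrence.

Finite sampling biases plug-in entropies; the correction used here
extrapolates to infinite sample size by fitting the mean entropy of
random subsamples against the inverse subsample size,

    H(M') = H_true + c1/M' + c2/M'^2 ,

and taking the fitted intercept.  The Ma bound ``-log2(sum p_k^2)``, which
is far less sensitive to sample size, serves as a data-sufficiency check:
it must sit below the plug-in entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SpikeTrainSet, ValidationError, sliding_windows

__all__ = [
    "EntropyEstimate",
    "CorrectedMI",
    "InformationTimecourse",
    "entropy",
    "ma_bound",
    "count_probabilities",
    "mutual_information_plugin",
    "treves_panzeri_correct",
    "corrected_mutual_information",
    "information_timecourse",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


class DataSufficiencyWarning(UserWarning):
    """Plug-in entropy fell below its Ma lower bound: sample likely too small."""


def count_probabilities(samples: np.ndarray, k_max: int | None = None) -> np.ndarray:
    """Empirical probability of each count 0..k_max from integer samples."""
    samples = np.asarray(samples, dtype=np.int64)
    if samples.size == 0:
        raise ValidationError("need at least one sample")
    if k_max is None:
        k_max = int(samples.max())
    p = np.bincount(samples, minlength=k_max + 1).astype(float)
    return p / samples.size


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def ma_bound(p: np.ndarray) -> float:
    """Ma lower bound on entropy: -log2 of the collision probability."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities sum to {p.sum()}, not 1")
    return float(-np.log2((p**2).sum()))


def mutual_information_plugin(counts_by_stimulus: np.ndarray) -> float:
    """Plug-in mutual information (bits) from per-stimulus count samples.

    ``counts_by_stimulus`` is an (n_stimuli, n_trials) integer array (or a
    list of equal-length sample vectors); stimuli are treated as
    equiprobable.
    """
    counts = np.asarray(counts_by_stimulus, dtype=np.int64)
    if counts.ndim != 2:
        raise ValidationError("expected a (n_stimuli, n_trials) array")
    k_max = int(counts.max())
    h_total = entropy(count_probabilities(counts.ravel(), k_max))
    h_cond = np.mean([entropy(count_probabilities(row, k_max)) for row in counts])
    return h_total - float(h_cond)


# ---------------------------------------------------------------------------
# Subsampled entropies and the bias-corrected estimate
# ---------------------------------------------------------------------------


def _row_entropies(rows: np.ndarray, k_max: int) -> np.ndarray:
    """Entropy (bits) of each row of an integer matrix, vectorised."""
    n_rows, m = rows.shape
    width = k_max + 1
    offsets = (np.arange(n_rows) * width)[:, None]
    counts = np.bincount((rows + offsets).ravel(), minlength=n_rows * width)
    p = counts.reshape(n_rows, width) / m
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def _fit_intercept(m_sizes: np.ndarray, h_means: np.ndarray) -> float:
    """Least-squares intercept of H(M') = H + c1/M' + c2/M'^2."""
    if np.unique(m_sizes).size < 3:
        raise ValidationError(
            "bias correction needs at least 3 distinct subsample sizes"
        )
    X = np.column_stack([np.ones_like(m_sizes, dtype=float), 1.0 / m_sizes, 1.0 / m_sizes**2])
    coef, *_ = np.linalg.lstsq(X, h_means, rcond=None)
    return float(coef[0])


@dataclass
class EntropyEstimate:
    """Plug-in entropy with its subsample series, corrected value and Ma bound."""

    plug_in: float
    subsample_series: list[tuple[int, float]]  # (subsample size, mean entropy)
    corrected: float
    ma_bound: float
    n_samples: int

    def __post_init__(self):
        if self.ma_bound > self.plug_in + 1e-9:
            warnings.warn(
                "Ma bound exceeds plug-in entropy: sample size likely insufficient",
                DataSufficiencyWarning,
                stacklevel=2,
            )


def treves_panzeri_correct(
    samples: np.ndarray,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    n_draws: int = 100,
    seed: int | None = None,
) -> EntropyEstimate:
    """Bias-corrected entropy of one count distribution.

    For each fraction, ``n_draws`` random subsamples (without replacement)
    are drawn, their mean plug-in entropy recorded, and the series fitted
    against 1/M' and 1/M'^2; the corrected entropy is the fitted intercept.
    """
    samples = np.asarray(samples, dtype=np.int64).ravel()
    M = samples.size
    if M < 10:
        raise ValidationError("bias correction needs at least 10 samples")
    rng = np.random.default_rng(seed)
    k_max = int(samples.max())
    p_full = count_probabilities(samples, k_max)
    series: list[tuple[int, float]] = []
    for f in fractions:
        m = max(1, int(round(f * M)))
        if m >= M:
            h_mean = entropy(p_full)
            m = M
        else:
            idx = np.argsort(rng.random((n_draws, M)), axis=1)[:, :m]
            h_mean = float(_row_entropies(samples[idx], k_max).mean())
        series.append((m, h_mean))
    m_sizes = np.array([m for m, _ in series], dtype=float)
    h_means = np.array([h for _, h in series])
    return EntropyEstimate(
        plug_in=entropy(p_full),
        subsample_series=series,
        corrected=_fit_intercept(m_sizes, h_means),
        ma_bound=ma_bound(p_full),
        n_samples=M,
    )


@dataclass
class CorrectedMI:
    """Mutual information with per-entropy bias correction.

    ``ma_ok`` is False when any entropy's Ma bound exceeded its plug-in
    value (a data-sufficiency failure).
    """

    plug_in: float
    corrected: float
    total: EntropyEstimate
    conditional: list[EntropyEstimate]
    ma_ok: bool


def corrected_mutual_information(
    counts_by_stimulus: np.ndarray,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    n_draws: int = 100,
    seed: int | None = None,
) -> CorrectedMI:
    """Bias-corrected MI from per-stimulus count samples.

    The correction is applied separately to the total entropy and to each
    conditional entropy, then combined.  Subsampling for the total entropy
    is stratified per stimulus: each draw takes the same fraction of
    trials from every stimulus, so total and conditional subsamples remain
    consistent.  Negative corrected values are retained unmodified.
    """
    counts = np.asarray(counts_by_stimulus, dtype=np.int64)
    if counts.ndim != 2:
        raise ValidationError("expected a (n_stimuli, n_trials) array")
    S, M = counts.shape
    if M < 10:
        raise ValidationError("bias correction needs at least 10 trials per stimulus")
    rng = np.random.default_rng(seed)
    k_max = int(counts.max())

    cond_series: list[list[tuple[int, float]]] = [[] for _ in range(S)]
    total_series: list[tuple[int, float]] = []
    for f in fractions:
        m = max(1, int(round(f * M)))
        if m >= M:
            m = M
            sub = np.broadcast_to(counts, (1, S, M))
            n_d = 1
        else:
            idx = np.argsort(rng.random((n_draws, S, M)), axis=2)[:, :, :m]
            sub = np.take_along_axis(np.broadcast_to(counts, (n_draws, S, M)), idx, axis=2)
            n_d = n_draws
        h_cond = _row_entropies(sub.reshape(n_d * S, m), k_max).reshape(n_d, S)
        h_tot = _row_entropies(sub.reshape(n_d, S * m), k_max)
        for s in range(S):
            cond_series[s].append((m, float(h_cond[:, s].mean())))
        total_series.append((S * m, float(h_tot.mean())))

    def _estimate(series, samples):
        m_sizes = np.array([m for m, _ in series], dtype=float)
        h_means = np.array([h for _, h in series])
        p = count_probabilities(samples, k_max)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DataSufficiencyWarning)
            est = EntropyEstimate(
                plug_in=entropy(p),
                subsample_series=series,
                corrected=_fit_intercept(m_sizes, h_means),
                ma_bound=ma_bound(p),
                n_samples=len(samples),
            )
        return est

    total = _estimate(total_series, counts.ravel())
    conditional = [_estimate(cond_series[s], counts[s]) for s in range(S)]
    corrected = total.corrected - float(np.mean([c.corrected for c in conditional]))
    plug_in = total.plug_in - float(np.mean([c.plug_in for c in conditional]))
    ma_ok = all(e.ma_bound <= e.plug_in + 1e-9 for e in [total, *conditional])
    return CorrectedMI(
        plug_in=plug_in,
        corrected=corrected,
        total=total,
        conditional=conditional,
        ma_ok=ma_ok,
    )


@dataclass
class InformationTimecourse:
    """Corrected MI per (neuron, window), with population summaries."""

    window_starts: np.ndarray  # (n_windows,)
    window_length: float
    mi: np.ndarray  # (n_neurons, n_windows), bias-corrected bits
    mi_plugin: np.ndarray  # (n_neurons, n_windows)
    neurons: list[int]

    @property
    def mean(self) -> np.ndarray:
        return self.mi.mean(axis=0)

    def quantiles(self, q=(0.1, 0.9)) -> np.ndarray:
        return np.quantile(self.mi, q, axis=0)

    def mean_in(self, t0: float, t1: float) -> float:
        """Population-mean corrected MI over windows starting in [t0, t1)."""
        m = (self.window_starts >= t0) & (self.window_starts < t1)
        return float(self.mi[:, m].mean())


def information_timecourse(
    data: SpikeTrainSet,
    window_length: float = 15.0,
    step: float = 5.0,
    span: tuple[float, float] | None = None,
    neurons: list[int] | None = None,
    n_draws: int = 100,
    seed: int | None = None,
) -> InformationTimecourse:
    """Bias-corrected MI between stimuli and counts in sliding windows.

    Negative corrected values are kept as computed; they reflect residual
    correction noise and stay small relative to the positive range on
    informative data.
    """
    span = span if span is not None else data.record_span
    windows = sliding_windows(span, window_length, step)
    if not windows:
        raise ValidationError("span too short for the requested window length")
    neuron_ids = neurons if neurons is not None else list(data.neurons)
    index = {n: i for i, n in enumerate(data.neurons)}
    counts = data.count_matrix(windows)  # (N, S, T, W)
    rng = np.random.default_rng(seed)
    mi = np.empty((len(neuron_ids), len(windows)))
    mi_plug = np.empty_like(mi)
    for i, n in enumerate(neuron_ids):
        for w in range(len(windows)):
            res = corrected_mutual_information(
                counts[index[n], :, :, w],
                n_draws=n_draws,
                seed=int(rng.integers(2**31 - 1)),
            )
            mi[i, w] = res.corrected
            mi_plug[i, w] = res.plug_in
    return InformationTimecourse(
        window_starts=np.array([w.start for w in windows]),
        window_length=window_length,
        mi=mi,
        mi_plugin=mi_plug,
        neurons=list(neuron_ids),
    )
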