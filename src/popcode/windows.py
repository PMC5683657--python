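"""Decoding accuracy across window placements, lengths and spike-count targets.

This module orchestrates the decoders over read-out window schemes:

- time courses of accuracy for fixed-length sliding windows;
- accuracy as a function of window length at a fixed start, with the
  saturation accuracy (mean over lengths 150-200 ms) and the minimum
  length reaching 80% of saturation;
- time courses for constant-spike-count windows, whose length at each
  left edge grows until the pooled population spike count reaches a
  target;
- self-normalisation of accuracy curves against their pre-onset baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    InsufficientSpikesError,
    SpikeTrainSet,
    ValidationError,
    Window,
    sliding_windows,
    spike_count_window,
)
from .decoding import METHODS, cross_validated_accuracy

__all__ = [
    "AccuracyCurve",
    "accuracy_timecourse",
    "accuracy_vs_length",
    "saturation_accuracy",
    "minimum_window_length",
    "constant_spike_count_timecourse",
    "normalize_accuracy_curve",
]


@dataclass
class AccuracyCurve:
    """Decoding accuracy per method along one sweep axis.

    ``x`` is either the window start time (ms) or the window length (ms),
    strictly increasing; ``y[method]`` holds one accuracy per x.  For
    constant-spike-count sweeps, ``window_lengths`` records the realised
    length at each left edge.
    """

    x: np.ndarray
    y: dict[str, np.ndarray]
    scheme: str
    window_length: float | None = None
    spike_target: int | None = None
    window_lengths: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.diff(self.x) <= 0):
            raise ValidationError("curve x values must be strictly increasing")

    def restrict(self, t0: float, t1: float) -> "AccuracyCurve":
        """The sub-curve with x in [t0, t1]."""
        m = (self.x >= t0) & (self.x <= t1)
        return AccuracyCurve(
            x=self.x[m],
            y={k: v[m] for k, v in self.y.items()},
            scheme=self.scheme,
            window_length=self.window_length,
            spike_target=self.spike_target,
            window_lengths=self.window_lengths[m] if self.window_lengths is not None else None,
        )


def accuracy_timecourse(
    data: SpikeTrainSet,
    methods: tuple[str, ...] = METHODS,
    window_length: float = 15.0,
    step: float = 5.0,
    span: tuple[float, float] | None = None,
    n_folds: int = 4,
) -> AccuracyCurve:
    """Cross-validated accuracy at each sliding window start."""
    span = span if span is not None else data.record_span
    wins = sliding_windows(span, window_length, step)
    if not wins:
        raise ValidationError("span too short for the requested window length")
    y = {m: np.empty(len(wins)) for m in methods}
    for i, w in enumerate(wins):
        for m in methods:
            y[m][i] = cross_validated_accuracy(data, w, m, n_folds=n_folds).accuracy
    return AccuracyCurve(
        x=np.array([w.start for w in wins]),
        y=y,
        scheme="timecourse",
        window_length=window_length,
    )


def accuracy_vs_length(
    data: SpikeTrainSet,
    methods: tuple[str, ...] = METHODS,
    start: float = 20.0,
    lengths: np.ndarray | None = None,
    n_folds: int = 4,
) -> AccuracyCurve:
    """Accuracy as a function of window length at a fixed start time.

    Default lengths sweep 2-200 ms in 2-ms steps, covering the saturation
    range 150-200 ms.
    """
    lengths = (
        np.asarray(lengths, dtype=float)
        if lengths is not None
        else np.arange(2.0, 201.0, 2.0)
    )
    if start + lengths.max() > data.record_span[1]:
        raise ValidationError("longest window exceeds the record span")
    y = {m: np.empty(lengths.size) for m in methods}
    for i, L in enumerate(lengths):
        w = Window(start, float(L))
        for m in methods:
            y[m][i] = cross_validated_accuracy(data, w, m, n_folds=n_folds).accuracy
    return AccuracyCurve(x=lengths, y=y, scheme="length-sweep")


def saturation_accuracy(
    curve: AccuracyCurve, method: str, span: tuple[float, float] = (150.0, 200.0)
) -> float:
    """Mean accuracy over tested lengths within [150, 200] ms."""
    m = (curve.x >= span[0]) & (curve.x <= span[1])
    if not m.any():
        raise ValidationError(f"curve does not cover the saturation span {span}")
    return float(curve.y[method][m].mean())


def minimum_window_length(
    curve: AccuracyCurve, saturation: float, method: str, frac: float = 0.8
) -> float:
    """Smallest tested length whose accuracy reaches ``frac`` of saturation.

    Returns NaN (reported, never raised) when no tested length reaches the
    threshold.
    """
    if saturation <= 0:
        raise ValidationError("saturation accuracy must be positive")
    hits = curve.y[method] >= frac * saturation
    if not hits.any():
        return math.nan
    return float(curve.x[np.argmax(hits)])


def constant_spike_count_timecourse(
    data: SpikeTrainSet,
    targets: tuple[int, ...] = (500, 1000, 2000),
    methods: tuple[str, ...] = METHODS,
    step: float = 5.0,
    edge_span: tuple[float, float] = (0.0, 500.0),
    within_span: bool = True,
    n_folds: int = 4,
) -> dict[int, AccuracyCurve]:
    """Accuracy in windows grown to hold a target pooled spike count.

    Left edges advance in ``step``-ms increments through ``edge_span``; at
    each edge the window is elongated rightward until the pooled count
    (all neurons, trials and stimuli) reaches the target, then decoded
    with each method under cross-validation.  With ``within_span`` (the
    default) only windows fully inside ``edge_span`` are kept, so the
    "within stimulus period" restriction is left edges in
    [0, 500 - length].  Unreachable targets raise
    :class:`~popcode.core.InsufficientSpikesError` tagged with the edge.
    """
    out: dict[int, AccuracyCurve] = {}
    edges = np.arange(edge_span[0], edge_span[1], step)
    for target in targets:
        xs, lens = [], []
        ys: dict[str, list[float]] = {m: [] for m in methods}
        for e in edges:
            try:
                w = spike_count_window(data, float(e), target)
            except InsufficientSpikesError as err:
                raise InsufficientSpikesError(target, err.achieved, float(e)) from err
            if within_span and w.end > edge_span[1]:
                continue
            xs.append(e)
            lens.append(w.length)
            for m in methods:
                ys[m].append(cross_validated_accuracy(data, w, m, n_folds=n_folds).accuracy)
        out[target] = AccuracyCurve(
            x=np.array(xs),
            y={m: np.array(v) for m, v in ys.items()},
            scheme="constant-count",
            spike_target=target,
            window_lengths=np.array(lens),
        )
    return out


def normalize_accuracy_curve(
    curve: AccuracyCurve,
    sd_span: tuple[float, float] = (-200.0, 100.0),
    baseline_span: tuple[float, float] = (-200.0, 0.0),
) -> AccuracyCurve:
    """Self-normalise a time course against its pre-onset baseline.

    Each method's curve is divided by the SD of its values over
    ``sd_span`` and offset so its mean over ``baseline_span`` (windows
    starting before onset) is exactly zero.  The result is invariant to
    affine transforms of the input.
    """
    sd_mask = (curve.x >= sd_span[0]) & (curve.x <= sd_span[1])
    base_mask = (curve.x >= baseline_span[0]) & (curve.x < baseline_span[1])
    if not sd_mask.any() or not base_mask.any():
        raise ValidationError("curve does not cover the normalisation spans")
    y_norm = {}
    for m, y in curve.y.items():
        sd = float(y[sd_mask].std(ddof=1))
        if sd <= 0:
            raise ValidationError(f"zero SD over {sd_span} for method {m!r}")
        scaled = y / sd
        y_norm[m] = scaled - scaled[base_mask].mean()
    return AccuracyCurve(
        x=curve.x.copy(),
        y=y_norm,
        scheme=curve.scheme + "-normalized",
        window_length=curve.window_length,
        spike_target=curve.spike_target,
        window_lengths=curve.window_lengths,
    )
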