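"""Domain data model and spike-train bookkeeping.

Trial-aligned spike times are the universal input: every analysis in this
package starts from a :class:`SpikeTrainSet`, which maps
``(neuron_id, stimulus_id, trial)`` to a sorted array of spike times in
milliseconds relative to sound onset (t = 0).  Rates are always reported in
spikes/s.

Windows are half-open intervals ``[start, start + length)`` so that adjacent
windows partition time exactly: the count over ``[a, b)`` plus the count over
``[b, c)`` equals the count over ``[a, c)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "Window",
    "SpikeTrainSet",
    "RateTensor",
    "ValidationError",
    "InsufficientSpikesError",
    "count_spikes",
    "rate_in_window",
    "sliding_windows",
    "spike_count_window",
    "population_response",
    "rate_tensor",
    "read_spike_data",
    "write_spike_data",
]


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


class InsufficientSpikesError(RuntimeError):
    """Raised when a spike-count window cannot reach its target count.

    Attributes
    ----------
    achieved : int
        The pooled spike count actually available right of the left edge.
    """

    def __init__(self, target: int, achieved: int, left_edge: float):
        self.target = int(target)
        self.achieved = int(achieved)
        self.left_edge = float(left_edge)
        super().__init__(
            f"insufficient spikes: needed {target} after t={left_edge} ms, "
            f"only {achieved} available within the record span"
        )


@dataclass(frozen=True)
class StimulusSet:
    """Pure-tone stimulus metadata shared by one experiment.

    Frequencies are in Hz and must be strictly increasing; all stimuli share
    the same duration (ms), level (dB SPL) and on/off ramp (ms).  Stimulus
    ids are the 0-based positions in ``frequencies``.
    """

    frequencies: tuple[float, ...]
    duration: float = 500.0
    level: float = 85.0
    ramp: float = 5.0

    def __post_init__(self):
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) < 1:
            raise ValidationError("stimulus set must contain at least one tone")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValidationError("frequencies must be strictly increasing")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")

    @property
    def n_stimuli(self) -> int:
        return len(self.frequencies)

    @classmethod
    def octave_tones(
        cls,
        n_tones: int = 6,
        f_low: float = 1000.0,
        spacing_octaves: float = 1.0,
        **kw,
    ) -> "StimulusSet":
        """Tones spaced a fixed number of octaves apart starting at ``f_low``."""
        freqs = tuple(f_low * 2.0 ** (spacing_octaves * i) for i in range(n_tones))
        return cls(frequencies=freqs, **kw)


@dataclass(frozen=True)
class Window:
    """Half-open read-out interval ``[start, start + length)`` in ms."""

    start: float
    length: float

    def __post_init__(self):
        if self.length <= 0:
            raise ValidationError(f"window length must be > 0, got {self.length}")

    @property
    def end(self) -> float:
        return self.start + self.length


class SpikeTrainSet:
    """Trial-aligned spike times for a population of sequentially recorded neurons.

    Parameters
    ----------
    neurons : sequence of int
        Neuron ids (need not be contiguous).
    stimuli : StimulusSet
    n_trials : int
        Number of repetitions per (neuron, stimulus); identical across stimuli.
    spikes : mapping
        ``(neuron_id, stimulus_id, trial) -> array of spike times (ms)``.
        Missing keys are treated as empty trains.  Times must lie inside
        ``record_span`` and be sorted (they are sorted on ingestion).
    record_span : (t_min, t_max) in ms
        Recording extent relative to sound onset.
    """

    def __init__(
        self,
        neurons: Sequence[int],
        stimuli: StimulusSet,
        n_trials: int,
        spikes: Mapping[tuple[int, int, int], np.ndarray],
        record_span: tuple[float, float] = (-300.0, 1200.0),
    ):
        if n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        t_min, t_max = float(record_span[0]), float(record_span[1])
        if t_max <= t_min:
            raise ValidationError("record_span must satisfy t_min < t_max")
        self.neurons = [int(n) for n in neurons]
        if len(set(self.neurons)) != len(self.neurons):
            raise ValidationError("duplicate neuron ids")
        self.stimuli = stimuli
        self.n_trials = int(n_trials)
        self.record_span = (t_min, t_max)
        self._spikes: dict[tuple[int, int, int], np.ndarray] = {}
        neuron_set = set(self.neurons)
        for key, times in spikes.items():
            n, s, tr = key
            if n not in neuron_set:
                raise ValidationError(f"unknown neuron id {n} in key {key}")
            if not (0 <= s < stimuli.n_stimuli):
                raise ValidationError(f"stimulus id {s} out of range in key {key}")
            if not (0 <= tr < n_trials):
                raise ValidationError(f"trial index {tr} out of range in key {key}")
            arr = np.sort(np.asarray(times, dtype=float))
            if arr.size and (arr[0] < t_min or arr[-1] > t_max):
                raise ValidationError(
                    f"spike time outside record span {record_span} for key {key}"
                )
            self._spikes[(int(n), int(s), int(tr))] = arr
        self._pooled: np.ndarray | None = None

    # -- accessors ---------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def train(self, neuron: int, stimulus: int, trial: int) -> np.ndarray:
        """Sorted spike times for one trial (empty array if no spikes)."""
        return self._spikes.get((neuron, stimulus, trial), np.empty(0))

    def items(self):
        return self._spikes.items()

    def total_spikes(self) -> int:
        return sum(a.size for a in self._spikes.values())

    def pooled_spike_times(self) -> np.ndarray:
        """All spike times across neurons, stimuli and trials, sorted."""
        if self._pooled is None:
            if self._spikes:
                self._pooled = np.sort(np.concatenate(list(self._spikes.values())))
            else:
                self._pooled = np.empty(0)
        return self._pooled

    # -- bulk counting -----------------------------------------------------

    def count_matrix(self, windows: Sequence[Window]) -> np.ndarray:
        """Spike counts per (neuron, stimulus, trial, window).

        Vectorised over windows with one pair of searchsorted calls per
        train, which keeps full timecourses cheap.
        """
        starts = np.array([w.start for w in windows])
        ends = np.array([w.end for w in windows])
        out = np.zeros(
            (self.n_neurons, self.stimuli.n_stimuli, self.n_trials, len(windows)),
            dtype=np.int64,
        )
        index = {n: i for i, n in enumerate(self.neurons)}
        for (n, s, tr), train in self._spikes.items():
            if train.size == 0:
                continue
            lo = np.searchsorted(train, starts, side="left")
            hi = np.searchsorted(train, ends, side="left")
            out[index[n], s, tr, :] = hi - lo
        return out


@dataclass
class RateTensor:
    """Windowed spiking rates, spikes/s, per (neuron, stimulus, trial, window)."""

    values: np.ndarray  # (n_neurons, n_stimuli, n_trials, n_windows)
    windows: list[Window]
    scheme: str = "fixed-length"

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValidationError("rates must be non-negative")


# ---------------------------------------------------------------------------
# Windowing primitives
# ---------------------------------------------------------------------------


def count_spikes(train: np.ndarray, window: Window) -> int:
    """Number of spikes with ``window.start <= t < window.end``."""
    train = np.asarray(train)
    if train.size == 0:
        return 0
    lo = np.searchsorted(train, window.start, side="left")
    hi = np.searchsorted(train, window.end, side="left")
    return int(hi - lo)


def rate_in_window(train: np.ndarray, window: Window) -> float:
    """Spiking rate in spikes/s over a window (count / length-in-seconds)."""
    return count_spikes(train, window) / (window.length / 1000.0)


def sliding_windows(
    span: tuple[float, float], length: float, step: float
) -> list[Window]:
    """Windows of ``length`` starting at ``t0, t0+step, ...`` while they fit in span."""
    if step <= 0:
        raise ValidationError("step must be > 0")
    if length <= 0:
        raise ValidationError("length must be > 0")
    t0, t1 = span
    out = []
    k = 0
    while True:
        start = t0 + k * step
        if start + length > t1 + 1e-9:
            break
        out.append(Window(start, length))
        k += 1
    return out


def spike_count_window(
    data: SpikeTrainSet, left_edge: float, target_count: int
) -> Window:
    """Shortest window at ``left_edge`` holding a target pooled spike count.

    The window grows rightward in 1-ms increments until the total number of
    spikes across all neurons, trials and stimuli inside it reaches
    ``target_count``.  Raises :class:`InsufficientSpikesError` (carrying the
    achieved count) if the record span cannot supply enough spikes.
    """
    if target_count < 1:
        raise ValidationError("target_count must be >= 1")
    t_min, t_max = data.record_span
    if not (t_min <= left_edge < t_max):
        raise ValidationError(f"left_edge {left_edge} outside record span")
    pooled = data.pooled_spike_times()
    i0 = np.searchsorted(pooled, left_edge, side="left")
    available = pooled.size - i0
    if available < target_count:
        raise InsufficientSpikesError(target_count, available, left_edge)
    t_k = pooled[i0 + target_count - 1]
    # smallest integer length with t_k strictly inside the half-open window
    length = float(np.floor(t_k - left_edge)) + 1.0
    return Window(left_edge, length)


def population_response(
    data: SpikeTrainSet,
    window: Window,
    stimuli: Iterable[int] | None = None,
    trials: Iterable[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-trial population rate vectors for one read-out window.

    Returns ``(X, y)`` where ``X`` has one row per selected (stimulus, trial)
    and one column per neuron (entries in spikes/s), and ``y`` holds the
    stimulus label of each row.  Rows are ordered stimulus-major.
    """
    stim_ids = list(stimuli) if stimuli is not None else list(range(data.stimuli.n_stimuli))
    trial_ids = list(trials) if trials is not None else list(range(data.n_trials))
    counts = data.count_matrix([window])[:, :, :, 0]  # (N, S, T)
    scale = 1000.0 / window.length
    X = np.empty((len(stim_ids) * len(trial_ids), data.n_neurons))
    y = np.empty(len(stim_ids) * len(trial_ids), dtype=np.int64)
    row = 0
    for s in stim_ids:
        for tr in trial_ids:
            X[row] = counts[:, s, tr] * scale
            y[row] = s
            row += 1
    return X, y


def rate_tensor(
    data: SpikeTrainSet, windows: Sequence[Window], scheme: str = "fixed-length"
) -> RateTensor:
    """Rates (spikes/s) for every (neuron, stimulus, trial, window)."""
    counts = data.count_matrix(windows).astype(float)
    lengths = np.array([w.length for w in windows])
    return RateTensor(values=counts * (1000.0 / lengths), windows=list(windows), scheme=scheme)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["neuron_id", "stimulus_id", "trial", "spike_time_ms"]


def write_spike_data(data: SpikeTrainSet, path: str | Path, format: str = "csv") -> None:
    """Write a SpikeTrainSet to disk.

    ``csv`` writes a long-form table (neuron_id, stimulus_id, trial,
    spike_time_ms) plus a sidecar JSON manifest ``<path>.manifest.json``
    holding the stimulus metadata; ``json`` writes a single self-contained
    JSON document.
    """
    path = Path(path)
    manifest = {
        "neurons": data.neurons,
        "n_trials": data.n_trials,
        "record_span": list(data.record_span),
        "stimuli": {
            "frequencies": list(data.stimuli.frequencies),
            "duration": data.stimuli.duration,
            "level": data.stimuli.level,
            "ramp": data.stimuli.ramp,
        },
    }
    if format == "csv":
        rows = []
        for (n, s, tr), times in sorted(data.items()):
            for t in times:
                rows.append((n, s, tr, t))
        df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        df.to_csv(path, index=False, float_format="%.4f")
        Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))
    elif format == "json":
        manifest["spikes"] = {
            f"{n},{s},{tr}": [round(float(t), 4) for t in times]
            for (n, s, tr), times in sorted(data.items())
        }
        path.write_text(json.dumps(manifest))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_spike_data(path: str | Path, format: str = "csv") -> SpikeTrainSet:
    """Read a SpikeTrainSet written by :func:`write_spike_data`."""
    path = Path(path)
    if format == "csv":
        manifest = json.loads(Path(str(path) + ".manifest.json").read_text())
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"CSV missing required column(s): {missing}")
        if df[_CSV_COLUMNS[:3]].isna().any().any():
            bad = df[df[_CSV_COLUMNS[:3]].isna().any(axis=1)].index[0]
            raise ValidationError(f"malformed row {bad}: missing id field")
        spikes: dict[tuple[int, int, int], list[float]] = {}
        for n, s, tr, t in df[_CSV_COLUMNS].itertuples(index=False):
            spikes.setdefault((int(n), int(s), int(tr)), []).append(float(t))
    elif format == "json":
        manifest = json.loads(path.read_text())
        spikes = {}
        for key, times in manifest["spikes"].items():
            n, s, tr = (int(x) for x in key.split(","))
            spikes[(n, s, tr)] = [float(t) for t in times]
    else:
        raise ValueError(f"unknown format {format!r}")
    stim = manifest["stimuli"]
    return SpikeTrainSet(
        neurons=manifest["neurons"],
        stimuli=StimulusSet(
            frequencies=tuple(stim["frequencies"]),
            duration=stim["duration"],
            level=stim["level"],
            ramp=stim["ramp"],
        ),
        n_trials=manifest["n_trials"],
        spikes={k: np.asarray(v) for k, v in spikes.items()},
        record_span=tuple(manifest["record_span"]),
    )
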