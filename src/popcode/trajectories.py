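"""Population response trajectories in principal-component space.

Trial-averaged rates in nonoverlapping 10-ms bins form, for each
stimulus, a time series of population vectors (one dimension per neuron).
Concatenating the stimuli column-wise yields a neurons x (stimuli * bins)
matrix — 171 x 318 at the default scale (6 stimuli, 53 bins spanning
30 ms before onset to sound offset).  PCA over the columns (centred on
the per-neuron mean) projects the trajectories onto the leading
components; the projected curves are smoothed with a 5-point moving
average (shrinking windows at the ends) for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpikeTrainSet, ValidationError, sliding_windows

__all__ = ["TrajectorySet", "build_trajectory_matrix", "project_trajectories"]


@dataclass
class TrajectorySet:
    """Low-dimensional population trajectories, one curve per stimulus."""

    points: np.ndarray  # (n_stimuli, n_bins, n_components), smoothed
    times: np.ndarray  # bin centres, ms
    explained_variance_ratio: np.ndarray  # full PCA spectrum, non-increasing
    basis: np.ndarray  # (n_neurons, n_kept) principal axes
    mean: np.ndarray  # per-neuron centring mean
    n_components: int  # components actually returned


def build_trajectory_matrix(
    data: SpikeTrainSet,
    bin_length: float = 10.0,
    span: tuple[float, float] = (-30.0, 500.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged binned rates, stimuli concatenated along columns.

    Returns ``(matrix, times)`` where the matrix is
    (n_neurons, n_stimuli * n_bins) in spikes/s — columns ordered
    stimulus-major — and ``times`` holds the bin centres.  The span must
    divide evenly into bins.
    """
    t0, t1 = span
    n_bins = (t1 - t0) / bin_length
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValidationError(f"span {span} does not divide into {bin_length}-ms bins")
    wins = sliding_windows(span, bin_length, bin_length)
    counts = data.count_matrix(wins).astype(float)  # (N, S, T, B)
    rates = counts.mean(axis=2) * (1000.0 / bin_length)  # (N, S, B)
    N, S, B = rates.shape
    matrix = rates.reshape(N, S * B)
    times = np.array([w.start + bin_length / 2.0 for w in wins])
    return matrix, times


def project_trajectories(
    matrix: np.ndarray,
    times: np.ndarray,
    n_stimuli: int,
    n_components: int = 3,
    smooth: int = 5,
) -> TrajectorySet:
    """PCA-project and smooth the concatenated trajectory matrix.

    The matrix columns are the samples (stimulus-time points) and rows the
    neuron dimensions; centring subtracts each neuron's mean over all
    columns, with no variance scaling (rates share units).  Projection
    keeps the first ``n_components`` axes (fewer, flagged by
    ``n_components`` on the result, if the data have lower rank);
    smoothing is a centred ``smooth``-point moving average applied after
    projection, with shrinking windows at the curve ends.
    """
    matrix = np.asarray(matrix, dtype=float)
    N, C = matrix.shape
    if C % n_stimuli:
        raise ValidationError("column count must be a multiple of n_stimuli")
    B = C // n_stimuli
    if times.size != B:
        raise ValidationError("times must hold one centre per bin")
    mean = matrix.mean(axis=1, keepdims=True)
    X = matrix - mean
    # PCA over the C column-samples in N-dim space
    U, svals, _ = np.linalg.svd(X, full_matrices=False)
    var = svals**2
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    rank = int((svals > svals[0] * 1e-12).sum()) if svals.size and svals[0] > 0 else 0
    kept = min(n_components, rank)
    basis = U[:, :kept]  # (N, kept)
    scores = (basis.T @ X).T.reshape(n_stimuli, B, kept)

    if smooth > 1:
        kernel = np.ones(smooth)
        norm = np.convolve(np.ones(B), kernel, mode="same")
        smoothed = np.empty_like(scores)
        for s in range(n_stimuli):
            for c in range(kept):
                smoothed[s, :, c] = (
                    np.convolve(scores[s, :, c], kernel, mode="same") / norm
                )
        scores = smoothed

    return TrajectorySet(
        points=scores,
        times=np.asarray(times, dtype=float),
        explained_variance_ratio=evr,
        basis=basis,
        mean=mean.ravel(),
        n_components=kept,
    )
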