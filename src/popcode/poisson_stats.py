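"""Poisson spiking diagnostics and theory.

For a Poisson process observed at true rate r over a window of T seconds,
the spike count has variance equal to its mean (Fano factor 1) and the
rate estimate count/T has coefficient of variation

    CV_Poisson = 1 / sqrt(r * T),

i.e. the reliability of the rate estimate depends only on the expected
spike count r*T.  This module measures observed Fano factors and CVs,
scores their match to the Poisson prediction with a coefficient of
determination, tests count samples for Poisson dispersion against a
negative-binomial alternative, and computes the two-stimulus count
discriminability d' whose invariance under uniform rate adaptation (rates
scaled by k, window by 1/k) underlies constant-spike-count read-out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import SpikeTrainSet, ValidationError, sliding_windows

__all__ = [
    "fano_factor",
    "cv_observed",
    "cv_poisson",
    "cv_r_squared",
    "poisson_gof_test",
    "poisson_discriminability",
    "poisson_diagnostics",
    "EPOCHS",
]

# reporting epochs relative to sound onset, ms
EPOCHS = {"silence": (-300.0, 0.0), "onset": (0.0, 200.0), "sustained": (200.0, 500.0)}


def fano_factor(counts: np.ndarray, ddof: int = 1) -> float:
    """Spike-count variance over mean across trials; NaN when the mean is 0."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValidationError("Fano factor needs at least 2 trials")
    mean = counts.mean()
    if mean == 0:
        return float("nan")
    return float(counts.var(ddof=ddof) / mean)


def cv_observed(rates: np.ndarray, ddof: int = 1) -> float:
    """SD over mean of trial-wise rate estimates; NaN when the mean is 0."""
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValidationError("CV needs at least 2 trials")
    mean = rates.mean()
    if mean == 0:
        return float("nan")
    return float(rates.std(ddof=ddof) / mean)


def cv_poisson(r_m: float, T: float) -> float:
    """Poisson-predicted CV of the rate estimate: 1/sqrt(r_m * T), T in s."""
    if r_m <= 0 or T <= 0:
        raise ValidationError("rate and window length must be positive")
    return float(1.0 / np.sqrt(r_m * T))


def cv_r_squared(cv_obs: np.ndarray, cv_pred: np.ndarray) -> float:
    """Coefficient of determination of observed CVs against the Poisson curve.

    r2 = 1 - SS_res / SS_tot with SS_tot taken around the arithmetic mean
    of the observed CVs; may be negative when the Poisson prediction fits
    worse than that mean.
    """
    cv_obs = np.asarray(cv_obs, dtype=float)
    cv_pred = np.asarray(cv_pred, dtype=float)
    ok = np.isfinite(cv_obs) & np.isfinite(cv_pred)
    cv_obs, cv_pred = cv_obs[ok], cv_pred[ok]
    if cv_obs.size < 2:
        raise ValidationError("need at least 2 usable CV points")
    ss_tot = ((cv_obs - cv_obs.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValidationError("observed CVs have zero variance")
    ss_res = ((cv_obs - cv_pred) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)


def _negbin_loglik(alpha: float, x: np.ndarray, mu: float) -> float:
    """Log-likelihood of NB2 counts with mean mu and dispersion alpha."""
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(x + inv)
            - special.gammaln(inv)
            - special.gammaln(x + 1.0)
            + inv * np.log(inv / (inv + mu))
            + x * np.log(mu / (inv + mu))
        )
    )


def poisson_gof_test(counts: np.ndarray) -> float:
    """Likelihood-ratio test of Poisson dispersion vs a negative binomial.

    The Poisson null sits on the boundary (dispersion -> 0) of the NB2
    alternative, so the LR statistic is referred to the boundary mixture
    0.5*chi2_0 + 0.5*chi2_1.  Underdispersed or constant samples give
    p = 1: only overdispersion is the tested alternative.  Correction for
    testing many cells is the caller's responsibility.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValidationError("GOF test needs at least 2 trials")
    mu = x.mean()
    if mu == 0:
        return 1.0
    # the sample mean is the ML mean under both models
    if x.var() <= mu:  # dispersion MLE at the boundary
        return 1.0
    ll_pois = float(np.sum(x * np.log(mu) - mu - special.gammaln(x + 1.0)))
    res = optimize.minimize_scalar(
        lambda a: -_negbin_loglik(np.exp(a), x, mu),
        bounds=(np.log(1e-8), np.log(1e4)),
        method="bounded",
    )
    lr = 2.0 * (-res.fun - ll_pois)
    if lr <= 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(lr, df=1))


def poisson_discriminability(r1: float, r2: float, T: float) -> float:
    """Count-domain d' between two Poisson rates observed for T seconds.

    d' = |r1 - r2| T / sqrt((r1 + r2) T / 2): the mean-count separation
    over the pooled Poisson SD.  Exactly invariant under uniform
    adaptation, d'(k r1, k r2, T/k) = d'(r1, r2, T), so discriminability
    is preserved when the window is lengthened to keep the expected spike
    count.  Zero when both rates are zero.
    """
    if r1 < 0 or r2 < 0 or T <= 0:
        raise ValidationError("rates must be >= 0 and T > 0")
    if r1 == 0 and r2 == 0:
        return 0.0
    return float(abs(r1 - r2) * T / np.sqrt((r1 + r2) * T / 2.0))


def poisson_diagnostics(
    data: SpikeTrainSet,
    window_length: float = 15.0,
    span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Fano factor and CV per (neuron, stimulus, window) in nonoverlapping windows.

    Returns a tidy frame with mean_count, var_count, fano, mean_rate
    (spikes/s), cv_obs, cv_poisson (from the mean rate as the estimate of
    the true rate), the window length T in seconds, and the reporting
    epoch of the window start.  Cells with zero mean count have NaN
    diagnostics (flagged by ``usable``), mirroring their exclusion from
    summary statistics.
    """
    span = span if span is not None else data.record_span
    wins = sliding_windows(span, window_length, window_length)  # nonoverlapping
    counts = data.count_matrix(wins).astype(float)  # (N, S, T, W)
    T_s = window_length / 1000.0
    mean_c = counts.mean(axis=2)
    var_c = counts.var(axis=2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean_c > 0, var_c / mean_c, np.nan)
        mean_rate = mean_c / T_s
        cv_obs = np.where(mean_c > 0, np.sqrt(var_c) / mean_c, np.nan)
        cv_pred = np.where(mean_rate > 0, 1.0 / np.sqrt(mean_rate * T_s), np.nan)

    starts = np.array([w.start for w in wins])
    epoch = np.full(starts.size, "other", dtype=object)
    for name, (t0, t1) in EPOCHS.items():
        epoch[(starts >= t0) & (starts < t1)] = name

    N, S, W = mean_c.shape
    n_idx, s_idx, w_idx = np.meshgrid(
        np.arange(N), np.arange(S), np.arange(W), indexing="ij"
    )
    return pd.DataFrame(
        {
            "neuron_id": np.array(data.neurons)[n_idx.ravel()],
            "stimulus_id": s_idx.ravel(),
            "window_start": starts[w_idx.ravel()],
            "epoch": epoch[w_idx.ravel()],
            "T": T_s,
            "mean_count": mean_c.ravel(),
            "var_count": var_c.ravel(),
            "fano": fano.ravel(),
            "mean_rate": mean_rate.ravel(),
            "cv_obs": cv_obs.ravel(),
            "cv_poisson": cv_pred.ravel(),
            "usable": mean_c.ravel() > 0,
        }
    )
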