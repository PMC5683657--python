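# Methods

## The analysis problem

A population of sensory neurons responds to a small stimulus set with
firing that changes character over the response: a high-rate, broadly
tuned onset transient gives way, within tens of milliseconds, to sparse,
narrowly tuned sustained firing. The analyses in this package quantify
how stimulus identity is encoded across that trajectory: per-neuron
selectivity over time, mutual information between stimuli and windowed
spike counts, single-trial population decoding under different read-out
window schemes, and the Poisson spiking properties that link decoding
accuracy to the number of spikes a window contains.

All analyses consume a `SpikeTrainSet`: sorted spike times in ms relative
to sound onset, indexed by (neuron, stimulus, trial), with an identical
trial count per condition. Neurons are sequentially recorded, so no
within-trial correlation structure across neurons is assumed anywhere.

## Windowing conventions

Windows are half-open, `[start, start + length)`. This is a convention,
not an empirical claim: it makes adjacent windows partition time exactly
(counts are additive over a partition), which the tests exploit. Sliding
schemes place starts at `t0, t0+step, …` while the window fits in the
span. Rates are `count / (length in s)`, in spikes/s.

Constant-spike-count windows fix the left edge and grow rightward in
**1-ms increments** until the spike count pooled over all neurons, trials
and stimuli reaches the target; 1 ms matches the finest step used
elsewhere (selectivity testing). An unreachable target raises an error
carrying the achieved count. "Within the stimulus period" for
constant-count sweeps means left edges in `[0, 500 − length]`, so kept
windows lie wholly inside the tone.

## Synthetic population

The generator is a parametric stand-in for the recorded A1 population,
stated once and used as-is; its defaults are not fitted to any analysis
outcome. Each neuron has a best frequency (log-uniform across the tone
range, so every tone drives some neurons), a spontaneous rate drawn
uniformly from 1–5 spikes/s, and an intended rate

    r(t) = spont + G(Δoct; w(t)) · A(t),

with `G` Gaussian in octave distance and `A(t)` an envelope that steps up
at the response latency, decays exponentially to the sustained rate, and
returns to zero at offset. Defaults: onset peak 60 spikes/s, sustained
12 spikes/s, latency 15 ms, adaptation time constant 60 ms, tuning width
1.2 octaves at onset narrowing to 0.35 octaves (per-neuron log-normal
rate jitter, sd 0.3). These values were chosen once to reproduce the
qualitative A1 picture — population rate peaking within ~50 ms of onset at
roughly 4–5× the sustained level, ~3 effective stimuli at onset vs ~1
sustained, a 2,000-spike pooled window a few ms long at onset versus
~20 ms in the sustained epoch.

Differential adaptation is implemented by narrowing `w(t)` with the same
time constant, which silences off-best responses while best-frequency
responses persist; a `uniform` mode freezes the width so all evoked rates
adapt by a common ratio (used by the adaptation experiments).

Spikes are drawn by per-ms Poisson binning (counts per 1-ms bin, uniform
jitter within the bin). This reproduces expected counts exactly, is fast,
and — because the process is exactly Poisson — makes the Fano/CV/GOF
diagnostics verifiable against closed forms. What the generator does
**not** emulate: noise correlations between neurons (absent from
sequential recordings by construction), non-Poisson spiking (refractory
structure, bursting), rate heterogeneity beyond the log-normal jitter,
and any particular parametric truth about the real onset transient's
shape. A green test on this world therefore establishes that the
*machinery* behaves as specified on data satisfying its assumptions, not
that real cortex satisfies them.

Scaled variants mirror the fine-frequency data sets (478 neurons × 9
tones at 1/8 octave; 376 × 17 at 1/16 octave; 100-ms tones, 5 trials) via
`nine_tone_config()` / `seventeen_tone_config()`.

## Selectivity

A stimulus is *effective* at time t when the spike count in the 50-ms
window at t (pooled over trials; exposure `0.05 s × n_trials`)
significantly exceeds the spontaneous reference — the count pooled over
all trials and stimuli in `[−300, 0)` ms (exposure
`0.3 s × n_trials × n_stimuli`; pooling maximises reference precision).
Significance uses the exact Poisson conditional test: conditional on the
total count n, the test count is Binomial(n, e_t/(e_t+e_r)) under the
null, and p = P(X ≥ observed). Bonferroni correction defaults to the
whole-recording family (all windows × stimuli for one neuron); a
per-window family is available, since the correct scope is genuinely
ambiguous. Only rate *increases* are tested; suppression is out of scope.

The broadly tuned subset comprises neurons whose maximum effective count
in `[0, 200)` ms exceeds the maximum in `[200, 500)` ms **and** whose
median effective count in `[200, 500)` ms is ≥ 1; epoch membership is by
window start time.

## Mutual information

`I = H_T − (1/N) Σᵢ Hᵢ` with equiprobable stimuli and probabilities by
frequency of occurrence. Entropies use the standard Shannon sign and
base 2 throughout (bits). Bias correction fits the mean entropy of random
subsamples (fractions 0.1…1.0, 100 draws each, without replacement)
against `1/M'` and `1/M'²` by least squares and takes the intercept;
`M'` is the realised subsample size in trials. The correction is applied
to each entropy separately — total and per-stimulus — and then combined;
subsampling for the total entropy is stratified per stimulus so the same
draws feed both. Negative corrected MI values are retained unmodified;
on null data they are small relative to the positive range. The Ma bound
is computed for every entropy and a data-sufficiency warning is raised if
it exceeds the plug-in value.

The correction removes the *bias* of the plug-in entropy (on Poisson(2)
counts at M = 120 it shrinks the mean error by an order of magnitude) but
cannot reduce single-draw sampling noise, which is shared with the
plug-in estimate; claims about the correction are therefore claims about
means over replicate data sets.

## Decoding

All decoders assign a test response to the stimulus with the nearest
training-set mean. `lda` first reduces the training trials with PCA
(smallest component count reaching ≥ 90% cumulative variance, centred on
training means only), then fits LDA (≤ n_classes − 1 axes, SVD solver,
which tolerates collinear inputs) and measures Euclidean distance to
class means in the discriminant space; test samples pass through the
stored transforms. If a training matrix has numerically zero variance the
model degenerates to constant templates (every tie resolves to the lowest
stimulus index). `tmpeuc` and `tmpcos` match raw rate vectors by
Euclidean and angular distance respectively; a zero-norm test vector
under the angular metric receives distance 1 to every template (neutral;
ties resolve by index). Ties always break to the lowest stimulus index —
deterministic and documented, since no convention is canonical.

4-fold cross-validation uses contiguous blocks of 5 trials per stimulus
(randomised folds available); the random-split scheme draws 15 train / 5
test per stimulus, seeded. Accuracy is the mean fraction of correctly
classified test trials.

## Window sweeps

Saturation accuracy is the arithmetic mean over all tested lengths in
`[150, 200]` ms at the sweep's step; the minimum informative length is
the smallest tested length whose accuracy reaches 80% of saturation (NaN
sentinel when never reached). Curve self-normalisation divides by the SD
over window starts in `[−200, 100]` ms and offsets so the mean over
`[−200, 0)` ms is exactly zero — invariant to affine transforms of the
input curve.

## Poisson diagnostics

Fano factors and CVs use the unbiased (n−1) variance — the standard
choice at 20 trials, configurable via `ddof`. Diagnostics run in 15-ms
nonoverlapping windows per (neuron, stimulus); the trial-mean rate stands
in for the true rate in `CV_Poisson = 1/√(rT)`. Cells with zero mean
count are flagged and excluded from summaries. The coefficient of
determination compares observed CVs to the Poisson curve around the
arithmetic mean of the observed CVs (it can be negative). Reporting
epochs: silence `[−300, 0)`, onset `[0, 200)`, sustained `[200, 500]` ms.

The dispersion test is a likelihood-ratio test of Poisson against an
NB2 negative binomial. The Poisson null sits on the boundary of the
alternative (dispersion → 0), so the statistic is referred to the
mixture `0.5·χ²₀ + 0.5·χ²₁`; under-dispersed samples give p = 1 by
construction (only overdispersion is the alternative). The NB family and
boundary handling are this package's documented choice of test.

`d′ = |r₁ − r₂| T / √((r₁ + r₂) T / 2)` is the count-domain
discriminability with pooled Poisson variance. The binding property is
its exact invariance `d′(k r₁, k r₂, T/k) = d′(r₁, r₂, T)`, which holds
algebraically for every k > 0 and is property-tested.

## Adaptation experiments

Base rates come from a spike-count window starting 30 ms after onset and
grown to 2,000 pooled spikes (both defaults overridable), as
trial-averaged rates per (neuron, stimulus). Counts are then simulated
Poisson with mean `k_r · r_pq · k_T · T` for 20 trials and decoded
directly as response vectors — valid because T is common to all neurons
within a condition, so counts and rates differ by a shared scale.
Under the reciprocal rule (`k_T = 1/k_r`, grid 0.1–1.0) the count
distributions are identical across the grid, so any decoder's expected
accuracy is flat; under the unity rule (grid 0.1–1.5) accuracy grows with
the expected count. Twenty replicate seeds furnish standard errors;
4-fold cross-validation is used throughout for consistency with the main
analyses.

## Trajectories

Trial-averaged rates in 10-ms nonoverlapping bins over `[−30, 500]` ms
(53 bins), stimuli concatenated column-wise: 171 × 318 at default scale.
PCA treats the columns as samples in neuron space, centred on each
neuron's mean with no variance scaling (rates share units). Smoothing is
a 5-point centred moving average applied **after** projection (the order
is ambiguous in principle; after-projection is implemented), with
shrinking windows at the curve ends so constant curves are preserved.

## Known limitations

- The onset-transient shape (step + exponential decay) is a stand-in
  chosen for qualitative fidelity, not an inferred model of real A1
  dynamics.
- Constant-count accuracy curves retain two sources of spread across left
  edges even when encoding is time-invariant: edges earlier than the
  response latency mix silent and driven time, and cross-validated
  accuracy on 120 trials carries an irreducible ~0.04 binomial noise
  floor. Comparisons of curve flatness should account for both.
- The exact conditional test is conservative at low counts; rejection
  rates sit below nominal α.
- No NSB/jackknife entropy estimators, no temporal-pattern codes, no
  probabilistic decoders, no ISI-based variability measures.
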