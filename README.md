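# popcode

Analysis toolkit for **dynamic population coding** in sensory cortex, built
around trial-aligned spike trains from sequentially recorded neurons. It is
aimed at systems neuroscientists asking how much stimulus information a
neural population carries at different times during a response, how fast
that information can be read out, and whether read-out accuracy is governed
by *when* spikes occur or simply by *how many* spikes a decoder is given.

The package ships a synthetic stand-in for a primary auditory cortex (A1)
data set — 171 neurons × 6 pure tones (1–32 kHz, octave-spaced, 500 ms,
85 dB SPL) × 20 trials, recorded from 300 ms before onset to 700 ms after
offset — generated as an inhomogeneous Poisson population with a strong,
broadly tuned onset transient that differentially adapts to a sparse,
narrowly tuned sustained response.

## What it computes

- **Selectivity over time** — the number of *effective stimuli* per neuron
  (stimuli driving a significant rate increase over the spontaneous rate,
  exact Poisson conditional test, Bonferroni-corrected) in 50-ms windows at
  1-ms steps, plus subset selection by differential selectivity.
- **Mutual information** — `I = H_T − (1/N) Σᵢ Hᵢ` between the stimulus set
  and windowed spike counts, in bits, with finite-sampling bias removed by
  extrapolating subsampled entropies against `1/M'` and `1/M'²` to the
  infinite-data intercept, and the Ma bound `−log₂ Σ p_k²` as a
  data-sufficiency check.
- **Population decoding** — three single-trial classifiers: PCA(90%
  variance)+LDA with nearest class mean, Euclidean template matching, and
  angular (cosine) template matching; 4-fold or repeated random-split
  cross-validation; single-neuron template decoding.
- **Window analyses** — accuracy time courses, window-length sweeps with
  saturation accuracy (mean over 150–200 ms) and the minimum length reaching
  80% of saturation, **constant-spike-count read-out windows** (grown until
  the pooled population count hits a target), and pre-onset
  self-normalisation of accuracy curves.
- **Poisson diagnostics** — Fano factors, observed vs predicted coefficient
  of variation `CV = 1/√(rT)`, a likelihood-ratio dispersion test against a
  negative-binomial alternative, and the count discriminability
  `d′ = |r₁−r₂|T / √((r₁+r₂)T/2)`, which is exactly invariant under uniform
  adaptation `(r₁, r₂, T) → (k r₁, k r₂, T/k)`.
- **Uniform-adaptation simulations** — Poisson count populations with
  expected counts `k_r · r_pq · k_T · T`, decoded across a grid of rate
  scalings with either compensating (`k_T = 1/k_r`) or fixed windows.
- **Population trajectories** — trial-averaged 10-ms-binned responses,
  stimuli concatenated into a neurons × (stimuli·bins) matrix (171 × 318 at
  default scale), PCA-projected and smoothed.

## Worked example

```python
import popcode

pop = popcode.generate_population(seed=1)          # 171 neurons, 6 tones, 20 trials
w = popcode.Window(20, 15)                          # 15-ms window at 20 ms post onset
res = popcode.cross_validated_accuracy(pop, w, "lda")
print(round(res.accuracy, 3))                       # 0.967

cc = popcode.spike_count_window(pop, 30.0, 2000)    # grown to hold 2000 pooled spikes
print(cc.length)                                    # 5.0  (ms)
```

Running the full pipeline (`python scripts/acceptance.py --seed 1 --out
results/acceptance.json`) prints, among other lines:

```
effective stimuli (mean max): onset 2.95, sustained 0.93
corrected MI per 15-ms window (bits): onset 0.119, sustained 0.041
lda: 15-ms accuracy onset 0.862 / sustained 0.599; 2000-spike windows mean 0.723 (SD 0.075)
mean Fano factor over 34950 usable cells: 0.999
trajectory matrix 171 x 318; first 3 PCs explain 59.5% of variance
```

Read: neurons respond to ~3 tones at onset but ~1 during the sustained
epoch (differential adaptation); per-15-ms information and decoding
accuracy are higher at onset than later; windows holding a fixed pooled
spike count decode with far less variation across time than fixed-length
windows; spiking is Poisson-like (Fano ≈ 1); and the trajectory matrix has
the expected structural dimensions.

`scripts/acceptance.py` regenerates the synthetic population from the seed
you pass and recomputes every stage of the analysis from scratch —
selectivity, corrected information, fixed-window and constant-count
decoding with all three decoders, Poisson diagnostics, the
uniform-adaptation sweep, and the trajectory projection — then writes its
results file to `--out`.

## Layout

| module | contents |
| --- | --- |
| `popcode.core` | spike-train containers, windows, counting, CSV/JSON I/O |
| `popcode.synthetic` | inhomogeneous-Poisson population generator, count simulations |
| `popcode.selectivity` | Poisson conditional test, effective-stimulus profiles |
| `popcode.information` | entropies, Ma bound, bias-corrected MI, time courses |
| `popcode.decoding` | LDA and template decoders, cross-validation |
| `popcode.windows` | time-course / length / constant-count sweeps, normalisation |
| `popcode.poisson_stats` | Fano, CV, dispersion GOF, discriminability |
| `popcode.adaptation` | uniform-adaptation simulation experiments |
| `popcode.trajectories` | PCA population response trajectories |

See `docs/methods.md` for the model, parameter choices and limitations.
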