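# Methods

## Signal model and transforms

A linear probe with `n_channels` contacts (default 32) at `spacing_um`
pitch (default 50 µm) records LFP at `fs_hz` (default 1000 Hz),
perpendicular to the cortical laminae.  The analysis chain is:

1. **Depth smoothing.**  Each channel is replaced by a Hamming-weighted
   average of itself and its neighbours across depth (default window 7
   channels ≈ 300 µm).  At the probe edges the window is truncated and
   re-normalized rather than extended with invented data; constants are
   therefore preserved exactly everywhere.  The operator is realized as a
   banded row-stochastic matrix applied over the channel axis.

2. **CSD.**  The second spatial difference
   `(Φ_{z+nΔz} − 2Φ_z + Φ_{z−nΔz})/(nΔz)²`, applied literally: no sign
   flip and no conductivity factor, so sinks are negative.  The
   differential grid defaults to `n = 1` and is configurable.  Boundary
   handling: `pad="none"` drops `n` channels per edge; `pad="replicate"`
   duplicates the edge channels so every contact gets a value, with the
   edge rows flagged in the profile's provenance.  The end-to-end
   pipeline defaults to `pad="replicate"` because the default layer map
   assigns layer II starting at the first contact, which `pad="none"`
   would drop; the two CSD variants agree exactly on interior channels.

3. **AVREC and layer traces.**  AVREC is the channel-mean of |CSD| per
   trial and time sample (≥ 0).  A layer trace zeroes positive (source)
   values and averages the remaining sink values over the layer's full
   channel count, zeroed channels included in the divisor (≤ 0).  The
   alternative reading — excluding non-sink channels from the divisor —
   would make the operator non-linear in sink amplitude; the full-count
   divisor keeps layer traces exactly linear for fully-sinking layers and
   is the implemented choice.  Default 32-channel layer map (1-based
   contacts): II = 1–6, IV = 7–12, V = 13–20, VI = 21–26, contacts 27–32
   unassigned; always overridable in the run configuration, since real
   preparations assign layers per animal from tone-evoked CSD.

4. **Best frequency.**  For a tonotopy series, the layer-IV trace of each
   frequency is trial-averaged and scored by RMS over 0–200 ms post
   onset; the maximizing frequency wins, ties going to the lowest.

## Features

Windows are half-open `[onset, onset + width)`, anchored on the stimulus
event grid: 200 ms windows at 5 Hz (0–200, …, 800–1000 ms), 100 ms at
10 Hz, and contiguous 1400 ms bins for spontaneous recordings (no peak
detection there).  Evoked trials are recorded for 1000 ms around the
999 ms stimulus so the last window is complete.

* **RMS**: `sqrt(mean(x²))` per window; sign-insensitive so AVREC and
  sink traces are treated identically.
* **Peak**: all strict interior local maxima of the windowed trace
  (negated for sink traces) are enumerated and scored by topographic
  prominence — height above the higher of the two minima on the walks to
  the next higher terrain or window edge.  The most prominent peak is
  kept iff its prominence reaches the absolute floor 8·10⁻⁵ (pipeline CSD
  units); otherwise the trial-window is marked undetected and excluded
  from latency-based analyses.  Exact ties break toward earlier latency.
  The floor's units follow the CSD scale of the data; it is configurable.
* **First/last ratio**: RMS(first window)/RMS(last window); NaN flags a
  zero denominator.
* **Vector strength**: peak latencies map to phases `2πf·t/1000` of the
  modulation frequency; VS is the resultant length of the unit vectors
  (1 = perfect locking).  Click trains have no physical phase; the same
  mapping is applied (the phase an AM tone would have at those
  latencies).  One peak per analysis window of the active scheme enters,
  at both 5 and 10 Hz.

## Statistics

* **Mixed model**: `log(RMS) ~ Group*Measurement + (1|Animal/TrialNumber)`,
  natural log (effects are then additive logs of multiplicative gains),
  REML, treatment coding with the treated group and post-laser
  measurement as the reference cell.  The nested term is a variance
  component for trial-number within animal; when that fit is singular or
  non-convergent (which is the expected outcome when the true
  trial-number variance is zero, as in the default generator), the model
  falls back to the animal-only random intercept and flags it in the
  output.  Wald-t inference with df = n_obs − n_fixed; degrees of freedom
  conventions differ across mixed-model engines, so estimates and SEs are
  the comparable surface.  Only the first response window (0–200 ms)
  enters the default reports.
* **t-tests**: two-sided pooled-variance Student's t at the single-trial
  level, Bonferroni-adjusted with the family size (default 14: 6
  between-group AVREC comparisons pre/post, 3 within-group AVREC pre-vs-
  post, 3 post-laser between-group layer-IV comparisons, and the treated
  group's layer IV and V pre-vs-post).  The family is configurable; the
  single-trial pooling pseudo-replicates the animal effect, which is why
  these tests are companions to the mixed model, not substitutes.
* **Cohen's d**: mean difference over the pooled SD with the
  `n_a + n_b − 2` denominator, sign preserved.
* **Vector-strength ANOVA**: two-way factorial OLS ANOVA with interaction
  (type-II sums of squares; identical to type I/III for balanced cells).

## Synthetic generator

The generator defines the study conditions the pipeline is validated
under.  Ground truth lives in CSD space:

* **Evoked templates.**  Each sink event is a Gaussian in depth (center,
  width in channel units) with a peak-normalized difference-of-
  exponentials time course (default rise 5 ms, decay 30 ms) triggered at
  every stimulus onset.  Two flanking Gaussian source bands at ±2σ carry
  half the sink's discrete integral each, so every time slice sums to
  zero across channels exactly (charge balance).  AM-tone drive is
  additionally shaped by a 100 ms linear onset ramp per cycle, matching
  the slow rise of a modulated envelope at 5 Hz; the same 100 ms is used
  at 10 Hz.  The default laminar pattern is a dominant granular (IV)
  sink with a layer-V sink and weaker, lagged II/VI sinks.
* **Forward model.**  LFP is the exact discrete inverse of the `n = 1`
  CSD operator: `Φ_{k+1} = 2Φ_k − Φ_{k−1} + CSD_k·Δz²` with
  `Φ₁ = Φ₂ = 0`.  The CSD estimator therefore recovers the injected
  ground truth on interior channels to machine precision, which is the
  anchor for the pipeline's correctness tests.  Round-trip accuracy is
  measured normwise (`max|back − x| / max|x|`), the meaningful metric
  when elements of x can be arbitrarily close to zero.
* **Experiment design.**  Default: three groups — treated (10 animals,
  post-laser evoked gain e^−0.13), naïve control (10) and viral control
  (7), all pre-laser gains 1 — 50 trials per condition, pre and post.
  Per animal a lognormal baseline factor (sd 0.3 log-units, drawn once),
  per trial a lognormal evoked-gain factor (sd 0.25 log-units) and
  additive i.i.d. Gaussian CSD noise (sd 1·10⁻⁴ CSD units), injected
  before the forward model so it is spatially structured in the LFP.
  All randomness flows from one seeded generator; identical seeds give
  bit-identical datasets.
* **Amplitude scale.**  CSD units are arbitrary; sink amplitudes
  (0.008–0.03) put evoked traces roughly two orders of magnitude above
  the 8·10⁻⁵ prominence floor, and the additive noise floor well below
  the evoked response, representing a clean laminar preparation.

### Why the per-trial gain factor exists

With purely additive CSD noise, rectification gives the AVREC a
near-constant noise-floor offset whose trial-to-trial variance is tiny.
The log-RMS laser contrast would then be biased by the offset while the
mixed model's SE shrinks toward zero, and no additive-noise level makes
the estimator's CI cover a multiplicative ground truth — the bias/SE
ratio is scale-invariant.  Trial-to-trial evoked-amplitude variability is
a standard feature of cortical evoked responses and supplies the residual
variance the mixed model actually models; with the default scales, the
residual rectification bias is a small fraction of the contrast SE.

### What the generator does not emulate

No biophysical conductivity, electrode noise spectra, laser-heating
physiology, anesthesia-state dynamics, per-animal layer-boundary
variability, or latency jitter of evoked peaks.  The last point means
synthetic vector strengths sit near 1 at both 5 and 10 Hz — the generator
validates the VS computation and its ANOVA, not physiological
synchronicity levels, which in real cortex fall with modulation rate.
Passing tests demonstrate that the chain recovers known injected effects
under these idealized conditions, not that real data meet the model's
assumptions.

## Error-rate calibration

Family-wise error control of the Bonferroni family is validated under an
exchangeable null: all gains equal and zero between-animal baseline
variance.  With baseline variance present, single-trial between-group
t-tests are pseudo-replicated and no multiplicity correction can bound
their error rate; the null study therefore validates the test's own
null, and the pseudo-replication caveat is documented above.

## Problem sizes and determinism

The shipped validation studies use: 100 forward/inverse round trips on
32×1000 arrays; ≥1000 random instances per brute-force oracle;
100 seeded replicates of the full-scale (10/10/7 × 50 trials) recovery
design; 500 replicates of a reduced null design (3 groups × 2 animals ×
5 trials) for the family-wise error rate; and a 2/2/2 × 10-trial demo
configuration.  These sizes were chosen so each study's Monte-Carlo error
is small relative to the property it checks while the whole suite stays
convenient to run.  Every stochastic path is seeded; reports are written
with a fixed float format so identical configurations produce
byte-identical CSVs.

## Known limitations

* The differential-grid order and probe-edge policy are conventions, not
  estimates; results at the two edge contacts under `pad="replicate"`
  are flagged and should not be over-interpreted.
* Mixed-model degrees of freedom are large-sample approximations, not
  Satterthwaite/Kenward-Roger.
* The prominence floor is an absolute threshold in data units; data on a
  different amplitude scale need a rescaled threshold.
* Layer maps are static per run; no automatic per-animal layer
  segmentation.
* No inverse-CSD variants (kCSD, spline iCSD) and no spectral/wavelet or
  phase-coherence analyses.
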