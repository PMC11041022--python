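# lamcsd

Laminar current-source-density (CSD) analysis of multi-channel local field
potentials (LFP), built for pre/post intervention designs in sensory
cortex — e.g. optogenetic manipulations of auditory-cortex population
activity recorded with a 32-contact linear probe (50 µm pitch, 1 kHz
sampling) while click trains and amplitude-modulated (AM) tones are
presented.

It is aimed at systems-neuroscience labs that record trial-resolved
laminar LFP and want a tested, deterministic route from raw trials to
group statistics, plus a forward-modelled synthetic generator to validate
every stage against known ground truth.

## What it computes

**CSD.** For LFP `Φ_z` at depth `z` with inter-contact spacing `Δz`, the
current source density is estimated as the second spatial difference

```
CSD_z ≈ (Φ_{z+nΔz} − 2Φ_z + Φ_{z−nΔz}) / (nΔz)²
```

on a differential grid `n` (default 1), after smoothing the depth profile
with a 7-channel Hamming-weighted running average (~300 µm spatial
kernel).  Sinks (excitatory synaptic population activity) are negative.

**AVREC.** The average rectified CSD, `AVREC(t) = Σᵢ |CSDᵢ(t)| / n` over
the valid channels — a measure of overall columnar current flow.

**Layer traces.** Per cortical layer (II, IV, V, VI; channel ranges
configurable), the mean of the negative-only CSD over the layer's
channels: the time course of sink activity in that layer.

**Features.** Per trial and per stimulus-locked window (200 ms at 5 Hz,
100 ms at 10 Hz, 1400 ms bins for spontaneous activity): RMS, the most
prominent peak (topographic prominence with an absolute detection floor
of 8·10⁻⁵), first/last response ratios, and the vector strength of peak
latencies against the modulation period.

**Statistics.** A linear mixed model on log RMS,

```
log(RMS) ~ Group * Measurement + (1 | Animal / TrialNumber)
```

with treatment coding referenced to the treated group post-laser (REML);
Bonferroni-corrected (n = 14) single-trial Student's t-tests with Cohen's
d; and a two-way ANOVA (group × measurement) on vector strength.

**Synthetic generator.** Ground-truth laminar sink patterns (Gaussian in
depth, difference-of-exponentials in time, charge-balanced with flanking
sources) are converted to LFP through the exact discrete inverse of the
CSD operator, with group gains, per-animal lognormal baselines, per-trial
gain variability and additive CSD noise — so injected effects are known
exactly and the whole chain is testable.

## Worked example

```
lamcsd report --config configs/demo.yaml --out out/
```

simulates a scaled-down three-group experiment (2/2/2 animals, 10
trials/condition, treated post-laser evoked gain exp(−0.13) ≈ 0.878),
analyzes it end to end, and prints the reference-group laser contrast per
stimulus × trace, e.g.:

```
am_tone_5hz:AVREC: reference-group post-vs-pre log-RMS contrast -0.1920
am_tone_5hz:II: reference-group post-vs-pre log-RMS contrast -0.1731
...
click_train_5hz:AVREC: reference-group post-vs-pre log-RMS contrast -0.1291
click_train_5hz:IV: reference-group post-vs-pre log-RMS contrast -0.1295
...
report written to out
```

Each number is the fitted post-minus-pre shift in log AVREC RMS for the
treated group: ≈ −0.13 means the evoked response strength dropped by a
factor of e^−0.13 ≈ 0.88 after the manipulation, matching the injected
suppression up to sampling error.  `out/` contains the per-trial feature
table, the LMM / t-test / vector-strength CSV tables, a JSON summary, CSD
depth×time heatmaps and pre-vs-post AVREC overlays per group.

The same chain is available as a library:

```python
import lamcsd as L

cfg = L.SimConfig(rng_seed=1)
ds = L.simulate_experiment(cfg, [L.StimulusSpec.click_train(5)])
feats = L.build_feature_table(ds)
lmm = L.fit_lmm(feats[feats.window == 0])
```

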