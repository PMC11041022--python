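# Demo run: a scaled-down three-group pre/post experiment (2/2/2 animals,
# 10 trials/condition) with the default treated-group post-laser evoked
# suppression of exp(-0.13), analyzed end to end.
simulation:
  n_trials_per_condition: 10
  rng_seed: 1234
  groups:
    - name: treated
      n_animals: 2
      evoked_gain_pre: 1.0
      evoked_gain_post: 0.8781013867211895   # exp(-0.13)
    - name: naive_control
      n_animals: 2
    - name: viral_control
      n_animals: 2
  stimuli:
    - kind: click_train
      rate_hz: 5
    - kind: am_tone
      rate_hz: 5

layer_map:
  II: [1, 6]
  IV: [7, 12]
  V: [13, 20]
  VI: [21, 26]

peak:
  threshold: 0.00008

stats:
  reference_group: treated
  reference_measurement: post_laser
  n_tests: 14
  alpha: 0.05

output:
  dir: out
  figures: true
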