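# Full default configuration for `hrvscreen run-all` (the study conditions).
# Every key mirrors a RunConfig field; omitted keys keep these defaults.

# cohort
n_hc: 66
n_iwd: 30
seed: 0
sampling_rate: 500.0
effect_profiles: default   # "default" (sadness-dominant divergence) or "null"

# preprocessing front-end: when true, each segment is rendered to a 500-Hz
# waveform, band-pass/notch filtered and R-detected before epoching; when
# false the generator's beat times feed epoching directly
render_ecg: false
write_rr: true

# dual-phase screening
stats_alpha: 0.05
stats_d_threshold: 0.2
stats_unit: epoch          # or "participant" (epoch means per participant)

# classifier battery
test_fraction: 0.3
cv_folds: 5
search_budget: 10
search_strategy: smbo      # or "random"
n_bootstrap: 2000
algorithms: [ertc, logreg]

log_level: INFO
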