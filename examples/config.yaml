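# Demo experiment: 12 synthetic noise events at the SoundTrap HF300
# deployment configuration. Seed is overridden by `--seed` on the CLI.
seed: 1
n_events: 12
sampling_rate_hz: 288000
treatment_duration_s: 60.0
vessel_rolloffs_hz: [30000.0, 50000.0, 80000.0, 144000.0]
rates_per_min:
  CC: {before: 2.0, during: 0.6, after: 1.6}
  HFBP: {before: 3.0, during: 3.0, after: 3.0}
  OTHER: {before: 2.5, during: 0.8, after: 2.2}
nb_dispersion: 2.0
event_sd: 0.8
ambient_level_db_at_1khz: 60.0
uncertainty_db: 3.0
write_audio: false
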