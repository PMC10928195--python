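# Demo pipeline configuration: simulate the default 15-study design
# under the time x rate interaction regime, partition it, and fit the
# model hierarchy.
seed: 1
out: overyield_out
simulate:
  preset: interaction
adjustment_c: 1.0
matching_policy: study_year_treatment
# deposition comes from the generator for simulated runs; for CSV input
# list per-study rates (kg/ha/yr) here:
# deposition:
#   S01: 6.0
models:
  - {name: h1a_binary, response: ce}
  - {name: h1a_richness, response: ce}
  - {name: h1b_rate, response: ce, include_ambient: true}
  - {name: h2_time, response: ce, study: S01}
  - {name: h3_cumulative, response: nbe, mode: both}
  - {name: rate_time_additive, response: nbe}
log_level: info
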