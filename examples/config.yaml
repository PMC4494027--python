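seed: 20260904
n_subjects: 15
grid_shape:
- 16
- 16
- 12
voxel_size_mm:
- 2.0
- 2.0
- 3.0
out_dir: results
design:
  tr_s: 2.5
  block_s: 10.0
  fix_s: 7.5
  initial_fix_s: 10.0
  blocks_per_cond: 6
  word_s: 0.4
  words_per_sentence: 6
  sentences_per_block: 4
  conditions:
  - sentences
  - nonwords
  n_main_sessions:
  - 7
  - 11
  n_localizer_sessions:
  - 3
  - 5
signal:
  baseline: 100.0
  pattern_amplitude: 0.1
  global_offset: 0.0
  localizer_amplitude: 3.0
  localizer_gain: 1.0
  signal_regions:
  - L_PosteriorSTS
  - L_MiddleFrontalGyrus
noise:
  white_sd: 1.0
  ar1: 0.3
  drift_amplitude: 0.5
  drift_period_s: 128.0
awareness:
  p_guessed:
    sentences: 0.803
    nonwords: 0.826
  p_correct_given_guessed: 0.517
  p_correct_given_knew:
    sentences: 0.624
    nonwords: 0.865
preproc:
  discard_volumes: 4
  smoothing_fwhm_mm: 6.0
  lag_trs: 3
roi:
  sizes:
  - 100
  - 50
  - 150
  connectivity: 26
  mask_seed: 1234
classifier:
  C: 1.0
stats:
  family_alpha: 0.05
  chance: 50.0
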