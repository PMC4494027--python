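# blockmvpa

Block-design fMRI simulation and ROI-based multivoxel pattern decoding,
end to end and without any external dataset:

- **Synthetic data** — session timelines (10 s blocks, 7.5 s fixation,
  TR 2.5 s, 12 blocks/session), a forward BOLD model (condition boxcars
  convolved with a canonical double-gamma HRF, AR(1) + drift + white
  noise), and behavioral awareness reports ("knew"/"guessed" with
  objective correctness at configurable probabilities).
- **Localizer GLM** — per-session design matrices, concatenated OLS fit
  with per-session nuisance columns, contrast t→z maps, volume-wise
  Gaussian smoothing.
- **ROI selection** — deterministic greedy growth of the contiguous
  fixed-size cluster of highest z inside a named mask (6/18/26
  connectivity, prefix-nested across sizes).
- **Pattern preparation** — per-session linear detrend + z-scoring,
  3-TR hemodynamic lag shift, block averaging, guessed-only filtering,
  class balancing, and per-session per-condition global-mean
  ("cocktail") subtraction.
- **Decoding** — leave-one-session-out linear SVM (C = 1), the
  single-dimension univariate control (ROI-mean feature, no cocktail
  subtraction), ROI-size sweeps, and permutation nulls.
- **Group statistics** — one-tailed one-sample t vs 50% with Bonferroni
  families (temporal: 7 ROIs, threshold 0.0071; frontal: 4 ROIs,
  threshold 0.0125), paired t, and a 2×2 repeated-measures ANOVA
  (region × hemisphere).

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (design
arithmetic, null calibration, the pattern-vs-global dissociation, oracle
equivalence, and full-pipeline parameter recovery); the stochastic ones
run several minutes at reduced problem sizes with fixed seeds.

## CLI

All verbs read a single YAML config (see `examples/config.yaml`); the
master `seed` is mandatory and fixes every stochastic stage.

```bash
blockmvpa all --config examples/config.yaml --out results/
blockmvpa simulate --config examples/config.yaml --out sim/
blockmvpa localize --bold sim/sub-00/localizer_ses-00_bold.nii \
    --events sim/sub-00/localizer_ses-00_events.tsv --out zmap.nii
blockmvpa roi grow --zmap zmap.nii --mask sim/mask-L_PosteriorSTS.nii \
    --size 100 --connectivity 26 --out roi.nii
blockmvpa decode run --config examples/config.yaml --out results/
blockmvpa group --decoding results/decoding.tsv --out group.tsv
```

`all`/`decode run` write `decoding.tsv` (per subject × ROI × size ×
analysis kind), `group.tsv`, `anova.tsv`, a human-readable
`summary.txt`, and `manifest.json` recording the seed and config hash
for every output. Volumes are NIfTI-1; tables are TSV.

## Library use

```python
from blockmvpa import (
    DesignParams, build_session_timeline, SignalSpec, NoiseSpec,
    simulate_bold, fit_contrast_zmap, grow_roi, prepare_patterns,
    loso_decode, group_report,
)
```

See the module docstrings for the full API; `blockmvpa.pipeline.run_pipeline`
is the programmatic equivalent of `blockmvpa all`.

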