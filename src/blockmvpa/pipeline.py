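"""End-to-end orchestration: simulate subjects, localize, grow ROIs,
prepare patterns, decode, and run group statistics."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from blockmvpa import io
from blockmvpa.config import PipelineConfig
from blockmvpa.decode import loso_decode, univariate_decode
from blockmvpa.design import DesignParams, EventTable, build_session_timeline
from blockmvpa.errors import BlockMvpaError, PipelineStageError
from blockmvpa.glm import build_design_matrix, concat_designs, fit_contrast_zmap, smooth
from blockmvpa.patterns import prepare_patterns
from blockmvpa.roi import (
    FRONTAL_REGIONS,
    MaskSet,
    TEMPORAL_REGIONS,
    default_mask_set,
    grow_roi,
)
from blockmvpa.simulate import (
    AwarenessModel,
    BoldRun,
    NoiseSpec,
    SignalSpec,
    discard_initial_volumes,
    simulate_awareness,
    simulate_bold,
)
from blockmvpa.stats import format_group_summary, group_report, rm_anova_2x2

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES = {
    **{r: "temporal" for r in TEMPORAL_REGIONS},
    **{r: "frontal" for r in FRONTAL_REGIONS},
}


@dataclass
class SubjectData:
    """One simulated subject's runs and event tables (post-discard)."""

    subject_id: int
    localizer_runs: list[BoldRun] = field(default_factory=list)
    localizer_events: list[EventTable] = field(default_factory=list)
    main_runs: list[BoldRun] = field(default_factory=list)
    main_events: list[EventTable] = field(default_factory=list)


def _design_params(cfg: PipelineConfig) -> DesignParams:
    d = cfg.design
    return DesignParams(
        tr_s=d.tr_s,
        block_s=d.block_s,
        fix_s=d.fix_s,
        initial_fix_s=d.initial_fix_s,
        blocks_per_cond=d.blocks_per_cond,
        word_s=d.word_s,
        words_per_sentence=d.words_per_sentence,
        sentences_per_block=d.sentences_per_block,
        conditions=tuple(d.conditions),
    )


def _resolve_n_sessions(value, rng: np.random.Generator) -> int:
    """An int is fixed; a [lo, hi] pair draws per subject (inclusive)."""
    if isinstance(value, (list, tuple)):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def build_signal_spec(
    cfg: PipelineConfig, mask_set: MaskSet, rng: np.random.Generator
) -> SignalSpec:
    """Subject-specific condition amplitude maps.

    The localizer selectivity lives in every parcel (condition A responds
    more than condition B everywhere language-selective).  The
    main-experiment *pattern* difference is an antisymmetric +-1 voxel
    pattern inside the configured signal regions: it sums to zero across
    each region, so it carries no global-level information.  The
    univariate component is a scalar per-condition offset.
    """
    shape = tuple(cfg.grid_shape)
    cond_a, cond_b = cfg.design.conditions
    loc_a = np.zeros(shape)
    loc_b = np.zeros(shape)
    for name in mask_set.names():
        m = mask_set[name]
        # per-voxel selectivity gain gives the z-map internal structure
        loc_a[m] += cfg.signal.localizer_amplitude * rng.uniform(0.5, 1.5, int(m.sum()))
    amp_a = np.zeros(shape)
    amp_b = np.zeros(shape)
    if cfg.signal.pattern_amplitude != 0:
        for name in cfg.signal.signal_regions:
            m = mask_set[name]
            n = int(m.sum())
            signs = np.ones(n)
            signs[: n // 2] = -1.0
            signs = signs[rng.permutation(n)]
            delta = cfg.signal.pattern_amplitude * signs
            amp_a[m] += delta / 2.0
            amp_b[m] -= delta / 2.0
    offsets = {
        cond_a: cfg.signal.global_offset / 2.0,
        cond_b: -cfg.signal.global_offset / 2.0,
    }
    return SignalSpec(
        baseline=cfg.signal.baseline,
        amplitudes={cond_a: amp_a, cond_b: amp_b},
        offsets=offsets,
        localizer_amplitudes={cond_a: loc_a, cond_b: loc_b},
        localizer_gain=cfg.signal.localizer_gain,
    )


def simulate_subject(
    cfg: PipelineConfig, subject_id: int, seed_seq: np.random.SeedSequence,
    mask_set: MaskSet,
) -> SubjectData:
    """Simulate one subject: localizer + main sessions, awareness, discard."""
    params = _design_params(cfg)
    rng = np.random.default_rng(seed_seq)
    signal = build_signal_spec(cfg, mask_set, rng)
    awareness = AwarenessModel(
        p_guessed=dict(cfg.awareness.p_guessed),
        p_correct_given_guessed=cfg.awareness.p_correct_given_guessed,
        p_correct_given_knew=dict(cfg.awareness.p_correct_given_knew),
    )
    n_loc = _resolve_n_sessions(cfg.design.n_localizer_sessions, rng)
    n_main = _resolve_n_sessions(cfg.design.n_main_sessions, rng)
    shape = tuple(cfg.grid_shape)
    vox = tuple(cfg.voxel_size_mm)
    data = SubjectData(subject_id=subject_id)

    def one_session(session_id: int, localizer: bool):
        events = build_session_timeline(
            params, seed=int(rng.integers(2**31)), session_id=session_id
        )
        noise = NoiseSpec(
            white_sd=cfg.noise.white_sd,
            ar1=cfg.noise.ar1,
            drift_amplitude=cfg.noise.drift_amplitude,
            drift_period_s=cfg.noise.drift_period_s,
            seed=int(rng.integers(2**31)),
        )
        run = simulate_bold(
            events, signal, noise, shape,
            tr_s=params.tr_s, n_volumes=params.n_volumes,
            voxel_size_mm=vox, localizer=localizer,
        )
        if not localizer:
            events = simulate_awareness(events, awareness, seed=int(rng.integers(2**31)))
        return discard_initial_volumes(run, events, n=cfg.preproc.discard_volumes)

    for s in range(n_loc):
        run, events = one_session(s, localizer=True)
        data.localizer_runs.append(run)
        data.localizer_events.append(events)
    for s in range(n_main):
        run, events = one_session(s, localizer=False)
        if cfg.preproc.smooth_main:
            run = smooth(run, cfg.preproc.smoothing_fwhm_mm)
        data.main_runs.append(run)
        data.main_events.append(events)
    logger.info(
        "subject %d: %d localizer + %d main sessions, %d voxels",
        subject_id, n_loc, n_main, int(np.prod(shape)),
    )
    return data


def localize_subject(cfg: PipelineConfig, data: SubjectData):
    """Smooth the localizer runs, fit the concatenated GLM, return the z-map."""
    cond_a, cond_b = cfg.design.conditions
    runs = [smooth(r, cfg.preproc.smoothing_fwhm_mm) for r in data.localizer_runs]
    designs = [
        build_design_matrix(ev, r.n_volumes, r.tr_s, add_drift=True)
        for ev, r in zip(data.localizer_events, runs)
    ]
    design = concat_designs(designs)
    contrast = np.zeros(design.n_regressors)
    contrast[design.names.index(cond_a)] = 1.0
    contrast[design.names.index(cond_b)] = -1.0
    Y = np.concatenate([r.data for r in runs], axis=-1)
    run_cat = BoldRun(
        data=Y, tr_s=runs[0].tr_s, voxel_size_mm=runs[0].voxel_size_mm,
        affine=runs[0].affine,
    )
    return fit_contrast_zmap(
        run_cat, design, contrast, contrast_name=f"{cond_a}>{cond_b}"
    )


def decode_subject(
    cfg: PipelineConfig,
    data: SubjectData,
    zmap,
    mask_set: MaskSet,
    balance_seed: int,
) -> pd.DataFrame:
    """Grow ROIs at each size, run multivariate + univariate decoding."""
    rows = []
    main_size = cfg.roi.sizes[0]
    for region in mask_set.names():
        for size in cfg.roi.sizes:
            roi = grow_roi(
                zmap, mask_set[region], size,
                connectivity=cfg.roi.connectivity, name=region,
            )
            patterns = prepare_patterns(
                data.main_runs, data.main_events, roi,
                lag_trs=cfg.preproc.lag_trs, balance_seed=balance_seed,
            )
            res = loso_decode(patterns, C=cfg.classifier.C, roi_size=size)
            rows.append(_result_row(data.subject_id, res))
            if size == main_size:
                uni = univariate_decode(
                    data.main_runs, data.main_events, roi,
                    lag_trs=cfg.preproc.lag_trs, balance_seed=balance_seed,
                    C=cfg.classifier.C,
                )
                rows.append(_result_row(data.subject_id, uni))
    return pd.DataFrame(rows)


def _result_row(subject_id: int, res) -> dict:
    return dict(
        subject=subject_id,
        roi=res.roi_name,
        size=res.roi_size,
        kind=res.kind,
        n_folds=res.n_folds,
        mean_accuracy=res.mean_accuracy,
        fold_accuracies=";".join(f"{a:.4f}" for a in res.fold_accuracies),
    )


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
    families: dict | None = None,
    write_artifacts: bool = True,
) -> dict:
    """Full analysis: returns {'decoding', 'group', 'anova', 'roi_summary'}.

    Deterministic under the master seed; every stage failure is re-raised
    as :class:`PipelineStageError` naming the stage.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    families = DEFAULT_FAMILIES if families is None else families
    seed_root = np.random.SeedSequence(cfg.seed)
    subject_seqs = seed_root.spawn(cfg.n_subjects)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except BlockMvpaError as exc:
            if isinstance(exc, PipelineStageError):
                raise
            raise PipelineStageError(name, str(exc)) from exc

    mask_set = stage(
        "roi_select", default_mask_set, tuple(cfg.grid_shape), seed=cfg.roi.mask_seed
    )
    max_size = max(cfg.roi.sizes)
    deficits = {
        name: count
        for name, count in mask_set.voxel_counts().items()
        if count < max_size
    }
    if deficits:
        raise PipelineStageError(
            "roi_select",
            f"requested ROI size {max_size} exceeds mask size(s): {deficits}",
        )

    all_rows = []
    for i, seq in enumerate(subject_seqs):
        data = stage("synthetic_data", simulate_subject, cfg, i, seq, mask_set)
        zmap = stage("glm_localizer", localize_subject, cfg, data)
        balance_seed = int(np.random.default_rng(seq.spawn(1)[0]).integers(2**31))
        table = stage("decoder", decode_subject, cfg, data, zmap, mask_set, balance_seed)
        all_rows.append(table)
    decoding = pd.concat(all_rows, ignore_index=True)

    main_size = cfg.roi.sizes[0]
    multi = decoding[(decoding["kind"] == "multivariate") & (decoding["size"] == main_size)]
    accs_by_roi = {
        roi: sub.sort_values("subject")["mean_accuracy"].to_numpy()
        for roi, sub in multi.groupby("roi")
    }
    group = stage(
        "group_stats", group_report, accs_by_roi, families,
        family_alpha=cfg.stats.family_alpha, chance=cfg.stats.chance,
    )

    anova = None
    bilateral = {"L_PosteriorSTS", "R_PosteriorSTS", "L_MidAnteriorTemporal", "R_MidAnteriorTemporal"}
    if bilateral <= set(accs_by_roi):
        cube = np.stack(
            [
                np.stack([accs_by_roi["L_PosteriorSTS"], accs_by_roi["R_PosteriorSTS"]], axis=1),
                np.stack(
                    [accs_by_roi["L_MidAnteriorTemporal"], accs_by_roi["R_MidAnteriorTemporal"]],
                    axis=1,
                ),
            ],
            axis=1,
        )
        anova = stage("group_stats", rm_anova_2x2, cube, ("region", "hemisphere"))

    results = {"decoding": decoding, "group": group, "anova": anova}
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        io.write_table(decoding, out / "decoding.tsv")
        io.write_table(group, out / "group.tsv")
        if anova is not None:
            io.write_table(anova, out / "anova.tsv")
        (out / "summary.txt").write_text(format_group_summary(group) + "\n")
        manifest = {
            "seed": cfg.seed,
            "config_hash": cfg.content_hash(),
            "n_subjects": cfg.n_subjects,
            "outputs": {
                "decoding.tsv": {"seed": cfg.seed, "config_hash": cfg.content_hash()},
                "group.tsv": {"seed": cfg.seed, "config_hash": cfg.content_hash()},
                "summary.txt": {"seed": cfg.seed, "config_hash": cfg.content_hash()},
                **(
                    {"anova.tsv": {"seed": cfg.seed, "config_hash": cfg.content_hash()}}
                    if anova is not None
                    else {}
                ),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
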