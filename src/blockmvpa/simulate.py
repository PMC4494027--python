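"""Forward BOLD model and behavioral awareness simulation.

Each voxel's timecourse is

    baseline + sum_c (pattern_amplitude_c[voxel] + global_offset_c) * r_c(t)
             + drift(t) + AR(1)-filtered white noise

where ``r_c`` is the condition boxcar convolved with the canonical HRF at
volume resolution — the same regressor the localizer GLM fits, so noiseless
recovery is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from blockmvpa.design import EventTable
from blockmvpa.errors import ConfigError
from blockmvpa.glm import condition_regressor

DEFAULT_VOXEL_SIZE_MM = (2.0, 2.0, 3.0)


def default_affine(voxel_size_mm=DEFAULT_VOXEL_SIZE_MM) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class BoldRun:
    """4-D (x, y, z, t) BOLD lattice with geometry metadata."""

    data: np.ndarray = field(repr=False)
    tr_s: float = 2.5
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ConfigError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("BOLD data contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class SignalSpec:
    """Condition-locked signal: multivoxel pattern + scalar global level.

    ``amplitudes`` maps condition -> per-voxel amplitude volume (the
    pattern component); ``offsets`` maps condition -> scalar added to
    every voxel (the univariate component).  In visible-localizer mode
    ``localizer_amplitudes`` (if given) replaces ``amplitudes``, and
    ``localizer_gain`` multiplies the signal.
    """

    baseline: float = 100.0
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)
    localizer_amplitudes: dict[str, np.ndarray] | None = None
    localizer_gain: float = 1.0

    def amplitude_maps(self, localizer: bool) -> dict[str, np.ndarray]:
        if localizer and self.localizer_amplitudes is not None:
            return self.localizer_amplitudes
        return self.amplitudes

    def validate_grid(self, shape: tuple[int, int, int]) -> None:
        maps = dict(self.amplitudes)
        if self.localizer_amplitudes:
            maps.update(self.localizer_amplitudes)
        for cond, amp in maps.items():
            if np.shape(amp) != tuple(shape):
                raise ConfigError(
                    f"amplitude map for {cond!r} has shape {np.shape(amp)}, "
                    f"expected {tuple(shape)}"
                )


@dataclass
class NoiseSpec:
    """AR(1) + sinusoidal drift + white noise, fully seeded."""

    white_sd: float = 1.0
    ar1: float = 0.3
    drift_amplitude: float = 0.5
    drift_period_s: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise ConfigError("white_sd must be >= 0")
        if not (0 <= self.ar1 < 1):
            raise ConfigError(f"ar1 must be in [0, 1), got {self.ar1}")
        if self.drift_period_s <= 0:
            raise ConfigError("drift_period_s must be > 0")


@dataclass
class AwarenessModel:
    """Block-wise subjective report and objective correctness model."""

    p_guessed: dict[str, float] = field(
        default_factory=lambda: {"sentences": 0.803, "nonwords": 0.826}
    )
    p_correct_given_guessed: float = 0.517
    p_correct_given_knew: dict[str, float] = field(
        default_factory=lambda: {"sentences": 0.624, "nonwords": 0.865}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            list(self.p_guessed.values())
            + [self.p_correct_given_guessed]
            + list(self.p_correct_given_knew.values())
        )
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p} outside [0, 1]")


def drift_timecourse(n_volumes: int, tr_s: float, spec: NoiseSpec) -> np.ndarray:
    t = np.arange(n_volumes) * tr_s
    return spec.drift_amplitude * np.sin(2.0 * np.pi * t / spec.drift_period_s)


def ar1_noise(
    n_voxels: int, n_volumes: int, spec: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """AR(1)-filtered white noise, shape (n_voxels, n_volumes)."""
    white = rng.normal(0.0, spec.white_sd, size=(n_voxels, n_volumes))
    if spec.ar1 == 0:
        return white
    return scipy.signal.lfilter([1.0], [1.0, -spec.ar1], white, axis=1)


def simulate_bold(
    events: EventTable,
    signal: SignalSpec,
    noise: NoiseSpec,
    shape: tuple[int, int, int],
    tr_s: float = 2.5,
    n_volumes: int | None = None,
    voxel_size_mm=DEFAULT_VOXEL_SIZE_MM,
    localizer: bool = False,
) -> BoldRun:
    """Simulate one session's BOLD run on the given spatial grid.

    Deterministic given ``noise.seed``: two calls with the same arguments
    produce bit-identical runs.
    """
    signal.validate_grid(shape)
    exp = events.experimental
    if n_volumes is None:
        end_s = (events.frame["onset"] + events.frame["duration"]).max()
        n_volumes = int(round(end_s / tr_s))
    conditions = list(exp["trial_type"].unique())

    gain = signal.localizer_gain if localizer else 1.0
    amp_maps = signal.amplitude_maps(localizer)
    n_vox = int(np.prod(shape))
    data = np.full((n_vox, n_volumes), float(signal.baseline))
    for cond in conditions:
        reg = condition_regressor(events, cond, n_volumes, tr_s)
        amp = amp_maps.get(cond)
        amp_flat = (
            np.zeros(n_vox) if amp is None else np.asarray(amp, float).reshape(n_vox)
        )
        level = amp_flat + signal.offsets.get(cond, 0.0)
        data += gain * np.outer(level, reg)
    data += drift_timecourse(n_volumes, tr_s, noise)[None, :]
    rng = np.random.default_rng(noise.seed)
    data += ar1_noise(n_vox, n_volumes, noise, rng)
    return BoldRun(
        data=data.reshape(*shape, n_volumes),
        tr_s=tr_s,
        voxel_size_mm=voxel_size_mm,
    )


def simulate_awareness(
    events: EventTable, model: AwarenessModel, seed: int | None = None
) -> EventTable:
    """Assign subjective ('knew'/'guessed') and objective-correct labels.

    Each experimental block draws its subjective label from the
    condition's guessed probability, then its objective correctness from
    the conditional matching that label.  Fixation rows are untouched.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    frame = events.frame.copy()
    exp_mask = (frame["trial_type"] != "fixation").to_numpy()
    conds = frame.loc[exp_mask, "trial_type"].to_numpy()
    missing = set(conds) - set(model.p_guessed)
    if missing:
        raise ConfigError(f"no guessed probability for condition(s) {sorted(missing)}")
    n = len(conds)
    p_g = np.array([model.p_guessed[c] for c in conds])
    # one (guessed, correct) uniform pair per block, drawn in block order
    draws = rng.random((n, 2))
    guessed = draws[:, 0] < p_g
    p_correct = np.where(
        guessed,
        model.p_correct_given_guessed,
        [model.p_correct_given_knew[c] for c in conds],
    )
    correct = draws[:, 1] < p_correct
    frame.loc[exp_mask, "subjective"] = np.where(guessed, "guessed", "knew")
    frame.loc[exp_mask, "objective_correct"] = np.where(correct, "true", "false")
    return EventTable(frame)


def discard_initial_volumes(
    run: BoldRun, events: EventTable, n: int = 4
) -> tuple[BoldRun, EventTable]:
    """Drop the first ``n`` volumes and shift all onsets back by n * TR.

    Leading events that end at or before the cut are dropped; an event
    spanning the cut is truncated at it.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    if n == 0:
        return run, events
    if run.n_volumes <= n:
        raise ConfigError(
            f"run has {run.n_volumes} volumes; cannot discard {n}"
        )
    cut_s = n * run.tr_s
    new_run = BoldRun(
        data=run.data[..., n:].copy(),
        tr_s=run.tr_s,
        voxel_size_mm=run.voxel_size_mm,
        affine=run.affine.copy(),
    )
    frame = events.frame.copy()
    ends = frame["onset"] + frame["duration"]
    frame = frame[ends > cut_s + 1e-9].copy()
    new_onset = (frame["onset"] - cut_s).clip(lower=0.0)
    frame["duration"] = (frame["onset"] + frame["duration"] - cut_s) - new_onset
    frame["onset"] = new_onset
    exp = frame[frame["trial_type"] != "fixation"]
    if (exp["onset"] < -1e-9).any():
        raise ConfigError("discarding made an experimental onset negative")
    return new_run, EventTable(frame.reset_index(drop=True))
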