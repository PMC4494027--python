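"""Localizer GLM: canonical HRF, design matrices, contrast z-maps, smoothing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.special
import scipy.stats

from blockmvpa.design import EventTable, FIXATION
from blockmvpa.errors import ConfigError, DesignMatrixError

HRF_DURATION_S = 32.0

# Double-gamma shape constants (response gamma(6,1), undershoot gamma(16,1),
# undershoot ratio 1/6); peak-normalized so a unit-amplitude block regressor
# has interpretable units.
_A1, _B1, _A2, _B2, _C = 6.0, 1.0, 16.0, 1.0, 1.0 / 6.0


def _double_gamma(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    h = scipy.stats.gamma.pdf(t, _A1, scale=1.0 / _B1) - _C * scipy.stats.gamma.pdf(
        t, _A2, scale=1.0 / _B2
    )
    return h


def canonical_hrf(tr_s: float, duration_s: float = HRF_DURATION_S) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the volume grid.

    The kernel spans ``duration_s`` (default 32 s), is zero at t=0 and
    peaks near 5 s.  Peak-normalized to max 1.
    """
    if tr_s <= 0:
        raise ConfigError(f"tr_s must be > 0, got {tr_s}")
    n = int(np.ceil(duration_s / tr_s)) + 1
    t = np.arange(n) * tr_s
    h = _double_gamma(t)
    peak = _double_gamma(np.linspace(0, duration_s, 4096)).max()
    return h / peak


def condition_boxcar(
    events: EventTable, condition: str, n_volumes: int, tr_s: float
) -> np.ndarray:
    """Volume-resolution 0/1 boxcar for one condition of one session."""
    box = np.zeros(n_volumes)
    sub = events.frame[events.frame["trial_type"] == condition]
    for _, row in sub.iterrows():
        start = int(np.floor(row["onset"] / tr_s))
        n_vols = int(round(row["duration"] / tr_s))
        if start + n_vols > n_volumes:
            raise DesignMatrixError(
                f"block at onset {row['onset']} s overruns the {n_volumes}-volume run"
            )
        box[start : start + n_vols] = 1.0
    return box


def condition_regressor(
    events: EventTable, condition: str, n_volumes: int, tr_s: float
) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, truncated to the run."""
    box = condition_boxcar(events, condition, n_volumes, tr_s)
    return np.convolve(box, canonical_hrf(tr_s))[:n_volumes]


@dataclass
class DesignMatrix:
    """Volumes x regressors matrix with named columns."""

    matrix: np.ndarray = field(repr=False)
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise DesignMatrixError("matrix shape does not match regressor names")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DesignMatrixError(
                f"design matrix is rank deficient (columns: {self.names})"
            )

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


def build_design_matrix(
    events: EventTable,
    n_volumes: int,
    tr_s: float,
    add_drift: bool = True,
) -> DesignMatrix:
    """One HRF-convolved boxcar per condition plus intercept (and drift).

    Conditions are the distinct non-fixation ``trial_type`` values, in
    order of first appearance.
    """
    conditions = [
        c for c in events.frame["trial_type"].unique() if c != FIXATION
    ]
    if not conditions:
        raise DesignMatrixError("event table contains no experimental blocks")
    cols = [condition_regressor(events, c, n_volumes, tr_s) for c in conditions]
    names = list(conditions)
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    if add_drift:
        drift = np.linspace(-0.5, 0.5, n_volumes)
        cols.append(drift)
        names.append("drift")
    return DesignMatrix(np.column_stack(cols), names)


def concat_designs(designs: list[DesignMatrix]) -> DesignMatrix:
    """Stack session designs block-diagonally on nuisance columns.

    Condition columns (shared names) are concatenated; each session gets
    its own intercept/drift columns so session-level offsets are absorbed
    per session.
    """
    if not designs:
        raise DesignMatrixError("no designs to concatenate")
    cond_names = [n for n in designs[0].names if n not in ("intercept", "drift")]
    for d in designs:
        if {n for n in d.names if n not in ("intercept", "drift")} != set(cond_names):
            raise DesignMatrixError("sessions have mismatched condition regressors")
    total = sum(d.n_volumes for d in designs)
    cols, names = [], []
    for name in cond_names:
        col = np.concatenate(
            [d.matrix[:, d.names.index(name)] for d in designs]
        )
        cols.append(col)
        names.append(name)
    offset = 0
    for i, d in enumerate(designs):
        for nuis in ("intercept", "drift"):
            if nuis in d.names:
                col = np.zeros(total)
                col[offset : offset + d.n_volumes] = d.matrix[:, d.names.index(nuis)]
                cols.append(col)
                names.append(f"{nuis}_s{i}")
        offset += d.n_volumes
    return DesignMatrix(np.column_stack(cols), names)


@dataclass
class ZMap:
    """Per-voxel contrast z-statistic on the run's spatial grid."""

    data: np.ndarray = field(repr=False)
    contrast_name: str = "contrast"
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigError(f"z-map must be 3-D, got shape {self.data.shape}")


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Exact t -> z via the t CDF, numerically stable in the far tails."""
    t = np.asarray(t, dtype=float)
    sign = np.sign(t)
    logp = scipy.stats.t.logsf(np.abs(t), df)
    z = -scipy.special.ndtri_exp(logp)
    return sign * z


def fit_contrast_zmap(
    run,
    design: DesignMatrix,
    contrast: np.ndarray,
    contrast_name: str = "contrast",
) -> ZMap:
    """OLS per voxel; t statistic of the contrast converted to a z-map.

    Degenerate voxels — constant timecourses or zero residual variance —
    map to z = 0 so downstream ROI growth cannot select them.
    Returns a :class:`ZMap`; the per-voxel contrast estimates are attached
    as the ``contrast_estimate`` attribute for exact-recovery checks.
    """
    from blockmvpa.simulate import BoldRun  # local import to avoid cycle

    if isinstance(run, BoldRun):
        data = run.data
        affine = run.affine
    else:
        data = np.asarray(run, dtype=float)
        affine = None
    if data.ndim != 4:
        raise ConfigError("expected 4-D (x, y, z, t) data")
    X = design.matrix
    c = np.asarray(contrast, dtype=float)
    if X.shape[0] != data.shape[-1]:
        raise DesignMatrixError(
            f"design has {X.shape[0]} rows but run has {data.shape[-1]} volumes"
        )
    if c.shape != (X.shape[1],):
        raise DesignMatrixError(
            f"contrast length {c.shape} does not match {X.shape[1]} regressors"
        )
    shape3 = data.shape[:3]
    Y = data.reshape(-1, data.shape[-1]).T  # volumes x voxels
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise DesignMatrixError("no residual degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    cvar = float(c @ xtx_inv @ c)
    cb = c @ beta
    se = np.sqrt(sigma2 * cvar)

    constant = Y.std(axis=0) == 0
    degenerate = constant | (se == 0)
    t = np.zeros(Y.shape[1])
    np.divide(cb, se, out=t, where=~degenerate)
    z = _t_to_z(t, df)
    z[degenerate] = 0.0

    zmap = ZMap(z.reshape(shape3), contrast_name=contrast_name, affine=affine)
    zmap.contrast_estimate = cb.reshape(shape3)
    zmap.df = df
    return zmap


def smooth(run, fwhm_mm: float):
    """Volume-wise separable Gaussian smoothing.

    sigma per axis = fwhm / (2 * sqrt(2 ln 2)), converted from mm to
    voxels with the run's voxel size.  fwhm 0 is the identity.
    """
    from blockmvpa.simulate import BoldRun

    if fwhm_mm < 0:
        raise ConfigError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return run
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in run.voxel_size_mm]
    out = np.empty_like(run.data)
    for t in range(run.data.shape[-1]):
        out[..., t] = scipy.ndimage.gaussian_filter(run.data[..., t], sigma_vox)
    return BoldRun(
        data=out,
        tr_s=run.tr_s,
        voxel_size_mm=run.voxel_size_mm,
        affine=run.affine.copy(),
    )
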