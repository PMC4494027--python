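"""Pattern preparation: from voxel timecourses to classifier-ready blocks.

Fixed stage order (leakage-safe by construction):

    detrend/z-score (per session) -> lag shift + block averaging ->
    guessed-only filter -> class balancing -> per-session per-condition
    global-mean ("cocktail") subtraction

The cocktail stage subtracts a *scalar* — the mean over all of one
condition's blocks and all ROI voxels within a session — so a classifier
cannot exploit condition-wise global activation level.  A per-voxel
variant is available for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from blockmvpa.design import EventTable
from blockmvpa.errors import PatternError
from blockmvpa.roi import ROI
from blockmvpa.simulate import BoldRun

logger = logging.getLogger(__name__)


@dataclass
class BlockPatterns:
    """Blocks x voxels matrix with per-block labels."""

    X: np.ndarray = field(repr=False)
    conditions: np.ndarray = field(repr=False)  # str per block
    sessions: np.ndarray = field(repr=False)  # int per block
    subjective: np.ndarray = field(repr=False)  # str per block
    roi_name: str = "roi"
    lag_trs: int = 3
    condition_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.sessions = np.asarray(self.sessions, dtype=int)
        self.subjective = np.asarray(self.subjective, dtype=object)
        n = self.X.shape[0]
        if not (len(self.conditions) == len(self.sessions) == len(self.subjective) == n):
            raise PatternError("label arrays do not match the block count")
        if not self.condition_order:
            self.condition_order = tuple(dict.fromkeys(self.conditions))

    @property
    def n_blocks(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def take(self, idx: np.ndarray) -> "BlockPatterns":
        return replace(
            self,
            X=self.X[idx],
            conditions=self.conditions[idx],
            sessions=self.sessions[idx],
            subjective=self.subjective[idx],
        )


def detrend_standardize(timecourses: np.ndarray) -> np.ndarray:
    """Per-voxel linear detrend then z-score, for one session.

    ``timecourses`` is (n_volumes, n_voxels).  Voxels with zero variance
    after detrending come back all-zero instead of NaN.
    """
    Y = np.asarray(timecourses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if n < 3:
        raise PatternError(f"session has only {n} volumes; need >= 3")
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t - t.mean()])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0)
    # zero-variance contract: residual SD at rounding-error scale counts as 0
    tol = 1e-10 * np.maximum(np.abs(Y).max(axis=0), 1.0)
    ok = sd > tol
    out = np.zeros_like(resid)
    np.divide(resid - resid.mean(axis=0), sd, out=out, where=ok)
    out[:, ~ok] = 0.0
    return out


def roi_timecourses(run: BoldRun, roi: ROI) -> np.ndarray:
    """Extract (n_volumes, n_roi_voxels) from a 4-D run."""
    return run.data[tuple(roi.voxels.T)].T


def extract_block_patterns(
    timecourses: np.ndarray,
    events: EventTable,
    tr_s: float,
    lag_trs: int = 3,
    roi_name: str = "roi",
) -> BlockPatterns:
    """Average each block's lag-shifted volume window into one pattern row.

    The block window is [onset_vol + lag, onset_vol + lag + block_vols);
    the lag compensates hemodynamic delay without rolling the data.
    ``timecourses`` is a single session's (n_volumes, n_voxels) matrix.
    """
    Y = np.asarray(timecourses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n_vol = Y.shape[0]
    exp = events.experimental
    if exp.empty:
        raise PatternError("no experimental blocks in events")
    onsets = exp["onset"].to_numpy(float)
    durations = exp["duration"].to_numpy(float)
    starts = np.floor(onsets / tr_s).astype(int) + lag_trs
    stops = starts + np.round(durations / tr_s).astype(int)
    if (stops > n_vol).any():
        bad = int(np.argmax(stops > n_vol))
        raise PatternError(
            f"block {exp['block_id'].iloc[bad]} (session "
            f"{exp['session'].iloc[bad]}): shifted window "
            f"[{starts[bad]}, {stops[bad]}) overruns the {n_vol}-volume session"
        )
    rows = [Y[a:b].mean(axis=0) for a, b in zip(starts, stops)]
    conds = exp["trial_type"].tolist()
    sess = exp["session"].tolist()
    subj = exp["subjective"].tolist()
    return BlockPatterns(
        X=np.array(rows),
        conditions=np.array(conds, dtype=object),
        sessions=np.array(sess, dtype=int),
        subjective=np.array(subj, dtype=object),
        roi_name=roi_name,
        lag_trs=lag_trs,
    )


def concat_patterns(parts: list[BlockPatterns]) -> BlockPatterns:
    if not parts:
        raise PatternError("nothing to concatenate")
    return replace(
        parts[0],
        X=np.vstack([p.X for p in parts]),
        conditions=np.concatenate([p.conditions for p in parts]),
        sessions=np.concatenate([p.sessions for p in parts]),
        subjective=np.concatenate([p.subjective for p in parts]),
    )


def filter_guessed(patterns: BlockPatterns) -> BlockPatterns:
    """Keep only blocks reported 'guessed' (subjectively invisible)."""
    keep = patterns.subjective == "guessed"
    if not keep.any():
        raise PatternError("no 'guessed' blocks remain after filtering")
    logger.info(
        "guessed filter: kept %d of %d blocks", int(keep.sum()), patterns.n_blocks
    )
    return patterns.take(np.flatnonzero(keep))


def balance_classes(patterns: BlockPatterns, seed: int) -> BlockPatterns:
    """Equalize per-condition block counts by seeded random discard.

    Discards are drawn uniformly without replacement from the larger
    class, once per subject (not per fold).
    """
    conds = patterns.condition_order
    idx_by_cond = {c: np.flatnonzero(patterns.conditions == c) for c in conds}
    for c, idx in idx_by_cond.items():
        if len(idx) == 0:
            raise PatternError(f"condition {c!r} has zero blocks")
    n_keep = min(len(idx) for idx in idx_by_cond.values())
    rng = np.random.default_rng(seed)
    kept = []
    for c in conds:
        idx = idx_by_cond[c]
        if len(idx) > n_keep:
            idx = np.sort(rng.choice(idx, size=n_keep, replace=False))
        kept.append(idx)
    keep = np.sort(np.concatenate(kept))
    logger.info(
        "class balance: %d blocks per condition (discarded %d)",
        n_keep, patterns.n_blocks - len(keep),
    )
    return patterns.take(keep)


def cocktail_subtract(
    patterns: BlockPatterns, per_voxel: bool = False
) -> BlockPatterns:
    """Subtract the per-session per-condition global mean from each block.

    Default: a scalar mean over all the condition's blocks and voxels in
    the session.  With ``per_voxel=True`` the per-voxel mean pattern is
    subtracted instead (sensitivity variant).  Computed within session
    only, so held-out sessions never influence training patterns.
    """
    X = patterns.X.copy()
    for s in np.unique(patterns.sessions):
        in_s = patterns.sessions == s
        present = set(patterns.conditions[in_s])
        missing = set(patterns.condition_order) - present
        if missing:
            raise PatternError(
                f"session {s} lacks condition(s) {sorted(missing)}; "
                "per-condition subtraction would leak across sessions"
            )
        for c in present:
            sel = in_s & (patterns.conditions == c)
            if per_voxel:
                X[sel] -= X[sel].mean(axis=0, keepdims=True)
            else:
                X[sel] -= X[sel].mean()
    return replace(patterns, X=X)


def prepare_patterns(
    runs: list[BoldRun],
    events_list: list[EventTable],
    roi: ROI,
    lag_trs: int = 3,
    balance_seed: int = 0,
    cocktail: bool = True,
    per_voxel_cocktail: bool = False,
) -> BlockPatterns:
    """Full preparation chain for one subject's main-experiment sessions."""
    if len(runs) != len(events_list):
        raise PatternError("runs and event tables must pair up")
    parts = []
    for run, events in zip(runs, events_list):
        tc = detrend_standardize(roi_timecourses(run, roi))
        parts.append(
            extract_block_patterns(
                tc, events, tr_s=run.tr_s, lag_trs=lag_trs, roi_name=roi.name
            )
        )
    patterns = concat_patterns(parts)
    patterns = filter_guessed(patterns)
    patterns = balance_classes(patterns, seed=balance_seed)
    if cocktail:
        patterns = drop_incomplete_sessions(patterns)
        patterns = cocktail_subtract(patterns, per_voxel=per_voxel_cocktail)
    return patterns


def drop_incomplete_sessions(patterns: BlockPatterns) -> BlockPatterns:
    """Remove sessions that no longer contain every condition.

    Awareness filtering or balancing can occasionally empty a session's
    cell for one condition; the per-session per-condition mean is then
    undefined, so the whole session is excluded (leakage-safe: no other
    session's statistics change).
    """
    keep_sessions = [
        s
        for s in np.unique(patterns.sessions)
        if set(patterns.conditions[patterns.sessions == s])
        >= set(patterns.condition_order)
    ]
    dropped = sorted(set(patterns.sessions) - set(keep_sessions))
    if not keep_sessions:
        raise PatternError("every session lacks a condition after filtering")
    if dropped:
        logger.warning(
            "dropping session(s) %s lacking a condition after filtering/balancing",
            dropped,
        )
        patterns = patterns.take(
            np.flatnonzero(np.isin(patterns.sessions, keep_sessions))
        )
    return patterns
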