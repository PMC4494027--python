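"""Leave-one-session-out linear SVM decoding and the univariate control."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from blockmvpa.errors import DecodingError
from blockmvpa.glm import ZMap
from blockmvpa.patterns import (
    BlockPatterns,
    balance_classes,
    detrend_standardize,
    extract_block_patterns,
    concat_patterns,
    filter_guessed,
    prepare_patterns,
    roi_timecourses,
)
from blockmvpa.roi import ROI, grow_roi


@dataclass
class DecodingResult:
    """Per-fold and mean cross-validated accuracy, in percent."""

    fold_accuracies: list[float]
    roi_name: str = "roi"
    roi_size: int = 0
    kind: str = "multivariate"  # or "univariate"
    C: float = 1.0
    fold_sessions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.fold_accuracies:
            if not (0.0 <= a <= 100.0):
                raise DecodingError(f"fold accuracy {a} outside [0, 100]")

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def _encode_labels(patterns: BlockPatterns) -> np.ndarray:
    # 0 = first condition; decision ties (margin exactly 0) fall to it.
    order = patterns.condition_order
    lut = {c: i for i, c in enumerate(order)}
    return np.array([lut[c] for c in patterns.conditions], dtype=int)


def loso_decode(
    patterns: BlockPatterns,
    C: float = 1.0,
    kind: str = "multivariate",
    roi_size: int | None = None,
) -> DecodingResult:
    """Leave-one-session-out soft-margin linear SVM classification.

    Each session serves once as the test fold; fold accuracy is percent
    correct on that session's blocks; the result carries all folds.
    """
    sessions = np.unique(patterns.sessions)
    if len(sessions) < 2:
        raise DecodingError(f"need >= 2 sessions for LOSO, got {len(sessions)}")
    y = _encode_labels(patterns)
    accs, fold_sessions = [], []
    for s in sessions:
        test = patterns.sessions == s
        train = ~test
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise DecodingError(
                f"training fold excluding session {s} is missing a condition"
            )
        clf = SVC(kernel="linear", C=C)
        clf.fit(patterns.X[train], y_tr)
        scores = clf.decision_function(patterns.X[test])
        pred = (scores > 0).astype(int)  # tie (score == 0) -> first condition
        accs.append(100.0 * float(np.mean(pred == y[test])))
        fold_sessions.append(int(s))
    return DecodingResult(
        fold_accuracies=accs,
        roi_name=patterns.roi_name,
        roi_size=roi_size if roi_size is not None else patterns.n_voxels,
        kind=kind,
        C=C,
        fold_sessions=fold_sessions,
    )


def univariate_decode(
    runs,
    events_list,
    roi: ROI,
    lag_trs: int = 3,
    balance_seed: int = 0,
    C: float = 1.0,
) -> DecodingResult:
    """Single-dimension control: classify on the ROI-mean timecourse.

    Identical chain to the multivariate analysis except that (a) no
    per-condition global mean is subtracted and (b) the feature is the
    ROI-average signal, so only global activation level can drive it.
    """
    if len(runs) != len(events_list):
        raise DecodingError("runs and event tables must pair up")
    parts = []
    for run, events in zip(runs, events_list):
        tc = detrend_standardize(roi_timecourses(run, roi))
        mean_tc = tc.mean(axis=1, keepdims=True)
        parts.append(
            extract_block_patterns(
                mean_tc, events, tr_s=run.tr_s, lag_trs=lag_trs, roi_name=roi.name
            )
        )
    patterns = concat_patterns(parts)
    patterns = filter_guessed(patterns)
    patterns = balance_classes(patterns, seed=balance_seed)
    return loso_decode(patterns, C=C, kind="univariate", roi_size=roi.size)


def roi_size_sweep(
    zmap: ZMap,
    mask: np.ndarray,
    runs,
    events_list,
    sizes: tuple[int, ...] = (50, 100, 150),
    connectivity: int = 26,
    lag_trs: int = 3,
    balance_seed: int = 0,
    C: float = 1.0,
    roi_name: str = "roi",
) -> list[DecodingResult]:
    """Repeat the multivariate analysis across ROI sizes.

    Greedy growth is prefix-nested, so the 50-voxel ROI is a subset of
    the 100-voxel ROI, etc.  All downstream settings are shared.
    """
    results = []
    for size in sizes:
        roi = grow_roi(zmap, mask, size, connectivity=connectivity, name=roi_name)
        patterns = prepare_patterns(
            runs, events_list, roi, lag_trs=lag_trs, balance_seed=balance_seed
        )
        results.append(loso_decode(patterns, C=C, roi_size=size))
    return results


def permutation_null(
    patterns: BlockPatterns,
    n_permutations: int = 200,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Null distribution of mean LOSO accuracy under within-session label
    permutation.  Returns the permuted mean accuracies (percent)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        shuffled = patterns.conditions.copy()
        for s in np.unique(patterns.sessions):
            idx = np.flatnonzero(patterns.sessions == s)
            shuffled[idx] = shuffled[rng.permutation(idx)]
        permuted = BlockPatterns(
            X=patterns.X,
            conditions=shuffled,
            sessions=patterns.sessions,
            subjective=patterns.subjective,
            roi_name=patterns.roi_name,
            lag_trs=patterns.lag_trs,
            condition_order=patterns.condition_order,
        )
        out[i] = loso_decode(permuted, C=C).mean_accuracy
    return out
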