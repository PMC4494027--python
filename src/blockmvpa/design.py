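"""Session design parameters and event-table construction.

A session is a fixed alternation of experimental blocks and fixation
periods, preceded by an initial fixation.  Event tables are thin wrappers
around :class:`pandas.DataFrame` with one row per block or fixation period
and the awareness-report columns used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from blockmvpa.errors import ConfigError, EventTableError

SUBJECTIVE_LABELS = ("knew", "guessed", "none")
OBJECTIVE_LABELS = ("true", "false", "none")

#: Columns every event table must carry.
EVENT_COLUMNS = (
    "onset",
    "duration",
    "trial_type",
    "session",
    "block_id",
    "subjective",
    "objective_correct",
)

FIXATION = "fixation"


def _is_multiple(value: float, base: float, tol: float = 1e-9) -> bool:
    ratio = value / base
    return abs(ratio - round(ratio)) < tol


@dataclass(frozen=True)
class DesignParams:
    """Timing and structure of one scanning session.

    Defaults give a 220 s session of 88 volumes: a 10 s initial fixation
    followed by 12 experimental blocks (6 per condition) of 10 s, each
    trailed by 7.5 s of fixation.
    """

    tr_s: float = 2.5
    block_s: float = 10.0
    fix_s: float = 7.5
    initial_fix_s: float = 10.0
    blocks_per_cond: int = 6
    word_s: float = 0.4
    words_per_sentence: int = 6
    sentences_per_block: int = 4
    n_sessions: int = 1
    conditions: tuple[str, str] = ("sentences", "nonwords")

    def __post_init__(self) -> None:
        for name in ("tr_s", "block_s", "fix_s", "word_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.initial_fix_s < 0:
            raise ConfigError("initial_fix_s must be >= 0")
        if self.blocks_per_cond < 1:
            raise ConfigError(
                f"blocks_per_cond must be >= 1, got {self.blocks_per_cond}"
            )
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ConfigError("conditions must be two distinct labels")
        if not _is_multiple(self.block_s + self.fix_s, self.tr_s):
            raise ConfigError(
                "block_s + fix_s must be an integer multiple of tr_s "
                f"({self.block_s} + {self.fix_s} vs TR {self.tr_s})"
            )
        if not _is_multiple(self.initial_fix_s, self.tr_s):
            raise ConfigError("initial_fix_s must be an integer multiple of tr_s")
        stim_s = self.words_per_sentence * self.word_s * self.sentences_per_block
        if stim_s > self.block_s + 1e-9:
            raise ConfigError(
                f"stimulus content ({stim_s} s) exceeds block duration "
                f"({self.block_s} s)"
            )

    @property
    def n_blocks(self) -> int:
        """Experimental blocks per session."""
        return self.blocks_per_cond * len(self.conditions)

    @property
    def sentence_s(self) -> float:
        """Duration of one sentence event (consecutive words, no ISI)."""
        return self.words_per_sentence * self.word_s

    @property
    def session_duration_s(self) -> float:
        return self.initial_fix_s + self.n_blocks * (self.block_s + self.fix_s)

    @property
    def n_volumes(self) -> int:
        n = self.session_duration_s / self.tr_s
        if not _is_multiple(self.session_duration_s, self.tr_s):
            raise ConfigError(
                f"session duration {self.session_duration_s} s is not an "
                f"integer number of volumes at TR {self.tr_s} s"
            )
        return int(round(n))

    @property
    def block_volumes(self) -> int:
        if not _is_multiple(self.block_s, self.tr_s):
            raise ConfigError("block_s must be an integer multiple of tr_s")
        return int(round(self.block_s / self.tr_s))

    def with_sessions(self, n: int) -> "DesignParams":
        return replace(self, n_sessions=n)


@dataclass
class EventTable:
    """Per-block event listing for one or more sessions.

    Rows with ``trial_type == "fixation"`` are non-experimental filler;
    all other rows are experimental blocks with a condition label and
    (possibly unset) awareness-report columns.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise EventTableError(f"event table missing columns: {missing}")
        bad_subj = set(self.frame["subjective"]) - set(SUBJECTIVE_LABELS)
        if bad_subj:
            raise EventTableError(f"invalid subjective labels: {sorted(bad_subj)}")
        bad_obj = set(self.frame["objective_correct"]) - set(OBJECTIVE_LABELS)
        if bad_obj:
            raise EventTableError(f"invalid objective labels: {sorted(bad_obj)}")
        for session, sub in self.frame.groupby("session"):
            onsets = sub["onset"].to_numpy(float)
            ends = onsets + sub["duration"].to_numpy(float)
            order = np.argsort(onsets)
            if np.any(ends[order][:-1] > onsets[order][1:] + 1e-9):
                raise EventTableError(f"overlapping events in session {session}")

    @property
    def experimental(self) -> pd.DataFrame:
        """Rows that are experimental blocks (not fixation)."""
        return self.frame[self.frame["trial_type"] != FIXATION]

    @property
    def sessions(self) -> list[int]:
        return sorted(self.frame["session"].unique())

    def for_session(self, session: int) -> "EventTable":
        return EventTable(self.frame[self.frame["session"] == session].reset_index(drop=True))

    def copy(self) -> "EventTable":
        return EventTable(self.frame.copy())

    def __len__(self) -> int:
        return len(self.frame)


def _session_condition_order(
    params: DesignParams, rng: np.random.Generator
) -> list[str]:
    # Seeded uniform permutation under the fixed per-condition count.
    labels = [c for c in params.conditions for _ in range(params.blocks_per_cond)]
    return [labels[i] for i in rng.permutation(len(labels))]


def build_session_timeline(
    params: DesignParams, seed: int, session_id: int = 0
) -> EventTable:
    """Build the event table of a single session.

    The timeline is the initial fixation followed by alternating
    (block, fixation) pairs; block conditions are a seeded random
    permutation with exactly ``blocks_per_cond`` blocks per condition.
    """
    params.n_volumes  # raises ConfigError if the grid does not tile
    rng = np.random.default_rng(seed)
    order = _session_condition_order(params, rng)

    rows = []
    t = 0.0
    rows.append(
        dict(
            onset=t,
            duration=params.initial_fix_s,
            trial_type=FIXATION,
            session=session_id,
            block_id=-1,
            subjective="none",
            objective_correct="none",
        )
    )
    t += params.initial_fix_s
    for block_id, condition in enumerate(order):
        rows.append(
            dict(
                onset=t,
                duration=params.block_s,
                trial_type=condition,
                session=session_id,
                block_id=block_id,
                subjective="none",
                objective_correct="none",
            )
        )
        t += params.block_s
        rows.append(
            dict(
                onset=t,
                duration=params.fix_s,
                trial_type=FIXATION,
                session=session_id,
                block_id=-1,
                subjective="none",
                objective_correct="none",
            )
        )
        t += params.fix_s
    if not math.isclose(t, params.session_duration_s):
        raise ConfigError("internal timeline accounting error")
    return EventTable(pd.DataFrame(rows))


def build_multisession_timeline(
    params: DesignParams, seed: int, n_sessions: int | None = None
) -> list[EventTable]:
    """One independent timeline per session, with per-session derived seeds."""
    n = params.n_sessions if n_sessions is None else n_sessions
    if n < 1:
        raise ConfigError("need at least one session")
    children = np.random.SeedSequence(seed).spawn(n)
    return [
        build_session_timeline(params, seed=child.generate_state(1)[0], session_id=i)
        for i, child in enumerate(children)
    ]
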