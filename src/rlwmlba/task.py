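"""Task session generation for the three-response instrumental learning task.

A session consists of a short training block (two stimuli) followed by ten
learning blocks with block-unique stimuli. Within a block each of the
``set_size`` stimuli is shown 12-14 times (13 on average, ``13 * set_size``
trials total) in a pseudo-randomized interleaved order in which the delay
between two successive presentations of the same stimulus is bounded by
``[1, 2 * set_size]`` and approximately uniform over that range. Feedback is
binary and deterministic: reward 1 iff the chosen action matches the
stimulus' correct action.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: set-size composition of the ten learning blocks
SESSION_COMPOSITION = (2, 2, 3, 3, 3, 4, 4, 5, 5, 5)
#: number of presentations per stimulus on average
PRESENTATIONS_PER_STIMULUS = 13
#: number of response alternatives
N_ACTIONS = 3
#: stimulus-id stride per block, so block stimuli are globally disjoint
_STIM_STRIDE = 8
#: stimulus ids used for the training block
TRAINING_STIMULI = (900, 901)
TRAINING_BLOCK_INDEX = -1

#: canonical trial-table column order (CSV schema)
TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "trial_in_block",
    "set_size",
    "stimulus_id",
    "correct_action",
    "action",
    "reward",
    "rt",
    "iteration",
    "delay",
    "reward_history",
]


class SequenceGenerationError(RuntimeError):
    """No valid stimulus sequence found within the attempt budget."""


@dataclass(frozen=True)
class TrialRecord:
    """A single task trial: design fields, behavior, and derived factors.

    ``action``, ``reward`` and ``rt`` are ``None`` for non-responses;
    ``delay`` is ``None`` on the first presentation of a stimulus.
    """

    subject_id: int
    block: int
    trial_in_block: int
    set_size: int
    stimulus_id: int
    correct_action: int
    action: Optional[int] = None
    reward: Optional[int] = None
    rt: Optional[float] = None
    iteration: Optional[int] = None
    delay: Optional[int] = None
    reward_history: Optional[int] = None


@dataclass(frozen=True)
class BlockDesign:
    block_index: int
    set_size: int
    stimulus_sequence: tuple
    correct_action_map: dict = field(hash=False)

    @property
    def n_trials(self) -> int:
        return len(self.stimulus_sequence)

    @property
    def stimuli(self) -> tuple:
        return tuple(sorted(self.correct_action_map))


@dataclass(frozen=True)
class SessionDesign:
    blocks: tuple
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def set_sizes(self) -> tuple:
        return tuple(b.set_size for b in self.blocks)


def _stimulus_counts(set_size: int, rng: np.random.Generator) -> np.ndarray:
    """Per-stimulus presentation counts in [12, 14] summing to 13 * set_size."""
    counts = np.full(set_size, PRESENTATIONS_PER_STIMULUS, dtype=np.int64)
    if rng.random() < 0.5:
        i, j = rng.choice(set_size, size=2, replace=False)
        counts[i] += 1
        counts[j] -= 1
    return counts


def _greedy_sequence(
    counts: np.ndarray, max_delay: int, rng: np.random.Generator
) -> Optional[np.ndarray]:
    """One greedy attempt at an interleaved sequence with bounded delays.

    Returns local stimulus indices, or None on a dead end (restart).
    """
    set_size = len(counts)
    n_total = int(counts.sum())
    remaining = counts.copy()
    last_seen = np.full(set_size, -1, dtype=np.int64)
    # target: uniform delay histogram over [1, max_delay]
    n_delays = n_total - set_size
    target = n_delays / max_delay
    hist = np.zeros(max_delay + 1)
    seq = np.empty(n_total, dtype=np.int64)

    for t in range(n_total):
        active = np.flatnonzero(remaining > 0)
        gaps = t - last_seen[active]
        seen = last_seen[active] >= 0
        if np.any(seen & (gaps > max_delay)):
            return None  # a stimulus already overdue: dead end
        forced = active[seen & (gaps == max_delay)]
        if len(forced) > 1:
            return None
        if len(forced) == 1:
            choice = forced[0]
        else:
            weights = np.empty(len(active))
            for idx, j in enumerate(active):
                if last_seen[j] < 0:
                    w = 1.0
                else:
                    w = max(target - hist[t - last_seen[j]], 0.0) + 0.15
                weights[idx] = w * remaining[j]
            total = weights.sum()
            if total <= 0:
                return None
            choice = rng.choice(active, p=weights / total)
        if last_seen[choice] >= 0:
            hist[t - last_seen[choice]] += 1
        seq[t] = choice
        last_seen[choice] = t
        remaining[choice] -= 1
    return seq


def delay_histogram(sequence: Sequence[int], max_delay: int) -> np.ndarray:
    """Counts of successive-presentation delays, indexed 1..max_delay."""
    last = {}
    hist = np.zeros(max_delay + 1)
    for t, s in enumerate(sequence):
        if s in last:
            d = t - last[s]
            if d > max_delay:
                raise ValueError(f"delay {d} exceeds bound {max_delay}")
            hist[d] += 1
        last[s] = t
    return hist[1:]


def _uniformity_statistic(hist: np.ndarray) -> float:
    expected = hist.sum() / len(hist)
    return float(((hist - expected) ** 2 / expected).sum())


def generate_block(
    set_size: int,
    block_index: int,
    seed: int,
    *,
    uniformity_alpha: float = 0.01,
    max_attempts: int = 10_000,
) -> BlockDesign:
    """Generate one learning block design.

    The stimulus sequence is built by randomized greedy construction and
    accepted when every successive-presentation delay lies in
    ``[1, 2 * set_size]`` and the chi-square uniformity statistic of the delay
    histogram is below the critical value at ``uniformity_alpha``.
    Deterministic in ``(set_size, block_index, seed)``.
    """
    if set_size not in (2, 3, 4, 5):
        raise ValueError(f"set_size must be in 2..5, got {set_size}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, block_index & 0xFFFF, set_size])
    max_delay = 2 * set_size
    critical = stats.chi2.ppf(1.0 - uniformity_alpha, df=max_delay - 1)
    for _ in range(max_attempts):
        counts = _stimulus_counts(set_size, rng)
        seq = _greedy_sequence(counts, max_delay, rng)
        if seq is None:
            continue
        hist = delay_histogram(seq, max_delay)
        if _uniformity_statistic(hist) >= critical:
            continue
        offset = block_index * _STIM_STRIDE
        stimuli = np.arange(set_size) + offset
        actions = rng.integers(0, N_ACTIONS, size=set_size)
        return BlockDesign(
            block_index=block_index,
            set_size=set_size,
            stimulus_sequence=tuple(int(s + offset) for s in seq),
            correct_action_map={int(s): int(a) for s, a in zip(stimuli, actions)},
        )
    raise SequenceGenerationError(
        f"no valid sequence for set_size={set_size} within {max_attempts} attempts"
    )


def generate_session(
    seed: int, *, uniformity_alpha: float = 0.01, max_attempts: int = 10_000
) -> SessionDesign:
    """Generate a full 10-block session (468 trials) with shuffled block order."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xD1CE])
    order = rng.permutation(np.array(SESSION_COMPOSITION))
    blocks = tuple(
        generate_block(
            int(ss),
            b,
            seed,
            uniformity_alpha=uniformity_alpha,
            max_attempts=max_attempts,
        )
        for b, ss in enumerate(order)
    )
    return SessionDesign(blocks=blocks, seed=seed)


def generate_training_block(
    agent_policy: Callable[[TrialRecord], int],
    seed: int,
    *,
    subject_id: int = 0,
    min_trials: int = 15,
    max_trials: int = 50,
    window: int = 10,
    criterion: float = 0.8,
) -> list[TrialRecord]:
    """Run the two-stimulus training block against a response policy.

    Stops at the first trial index >= ``min_trials`` where mean accuracy over
    the trailing ``window`` trials exceeds ``criterion``, else at
    ``max_trials``.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x7121])
    correct = {s: int(a) for s, a in zip(TRAINING_STIMULI, rng.integers(0, N_ACTIONS, 2))}
    trials: list[TrialRecord] = []
    rewards: list[int] = []
    for t in range(max_trials):
        stim = int(TRAINING_STIMULI[rng.integers(0, len(TRAINING_STIMULI))])
        probe = TrialRecord(
            subject_id=subject_id,
            block=TRAINING_BLOCK_INDEX,
            trial_in_block=t,
            set_size=len(TRAINING_STIMULI),
            stimulus_id=stim,
            correct_action=correct[stim],
        )
        action = int(agent_policy(probe))
        reward = int(action == correct[stim])
        trials.append(replace(probe, action=action, reward=reward))
        rewards.append(reward)
        if t + 1 >= min_trials and np.mean(rewards[-window:]) > criterion:
            break
    return compute_task_factors(trials)


def session_to_trials(
    session: SessionDesign, subject_id: int = 0
) -> list[TrialRecord]:
    """Expand a session design into unanswered trial records."""
    out = []
    for block in session.blocks:
        for t, stim in enumerate(block.stimulus_sequence):
            out.append(
                TrialRecord(
                    subject_id=subject_id,
                    block=block.block_index,
                    trial_in_block=t,
                    set_size=block.set_size,
                    stimulus_id=stim,
                    correct_action=block.correct_action_map[stim],
                )
            )
    return compute_task_factors(out)


def compute_task_factors(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Fill iteration, delay, and reward_history on ordered trials.

    delay = within-block trial-index difference between successive
    presentations of the same stimulus (undefined on the first presentation);
    reward_history = cumulative rewards for the stimulus BEFORE the trial.
    Idempotent; raises on out-of-order trials or stimulus/set-size mismatch.
    """
    out: list[TrialRecord] = []
    state: dict = {}
    expected_t: dict = {}
    for rec in trials:
        key = (rec.subject_id, rec.block)
        exp = expected_t.get(key, 0)
        if rec.trial_in_block != exp:
            raise ValueError(
                f"out-of-order trial: subject {rec.subject_id} block {rec.block} "
                f"trial {rec.trial_in_block}, expected {exp}"
            )
        expected_t[key] = exp + 1
        block_state = state.setdefault(key, {})
        if rec.stimulus_id not in block_state:
            if len(block_state) >= rec.set_size:
                raise ValueError(
                    f"unknown stimulus {rec.stimulus_id}: block {rec.block} already "
                    f"has {rec.set_size} distinct stimuli"
                )
            block_state[rec.stimulus_id] = {"iter": 0, "last": None, "rsum": 0}
        st = block_state[rec.stimulus_id]
        st["iter"] += 1
        delay = None if st["last"] is None else rec.trial_in_block - st["last"]
        out.append(
            replace(
                rec,
                iteration=st["iter"],
                delay=delay,
                reward_history=st["rsum"],
            )
        )
        st["last"] = rec.trial_in_block
        if rec.reward is not None:
            st["rsum"] += int(rec.reward)
    return out


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to the canonical trial table."""
    df = pd.DataFrame([vars(t) for t in trials], columns=TRIAL_COLUMNS)
    for col in ("action", "reward", "iteration", "delay", "reward_history"):
        df[col] = df[col].astype("Int64")
    df["rt"] = df["rt"].astype(float)
    for col in (
        "subject_id",
        "block",
        "trial_in_block",
        "set_size",
        "stimulus_id",
        "correct_action",
    ):
        df[col] = df[col].astype(np.int64)
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame`."""

    def _opt(v):
        return None if pd.isna(v) else v

    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialRecord(
                subject_id=int(row.subject_id),
                block=int(row.block),
                trial_in_block=int(row.trial_in_block),
                set_size=int(row.set_size),
                stimulus_id=int(row.stimulus_id),
                correct_action=int(row.correct_action),
                action=None if pd.isna(row.action) else int(row.action),
                reward=None if pd.isna(row.reward) else int(row.reward),
                rt=None if pd.isna(row.rt) else float(row.rt),
                iteration=None if pd.isna(row.iteration) else int(row.iteration),
                delay=None if pd.isna(row.delay) else int(row.delay),
                reward_history=(
                    None if pd.isna(row.reward_history) else int(row.reward_history)
                ),
            )
        )
    return out
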