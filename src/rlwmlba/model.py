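"""The RLWM-LBA generative model.

Two value-learning modules (an incremental delta-rule module and a fast,
decaying, capacity-limited working-memory module) are mixed into a single
action policy per stimulus. Drift rates for a three-accumulator linear
ballistic accumulator are the mixed policy scaled by ``eta`` and divided by
the Shannon entropy of the stimulus-averaged policy; the LBA then yields the
joint choice/RT likelihood and sampler.

This module is the slow, readable reference implementation; ``_fast`` holds
the numba replica used inside the optimizer (the two are cross-checked in
the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .task import (
    SessionDesign,
    TrialRecord,
    compute_task_factors,
    session_to_trials,
)

#: fixed softmax inverse temperature
FIXED_BETA = 50.0
#: fixed non-decision time, seconds
FIXED_TAU = 0.15
#: fixed between-trial drift-rate standard deviation (scaling constraint)
FIXED_S = 1.0
#: floor for the entropy divisor, in bits
H_FLOOR = 0.01
#: per-trial likelihood floor
LIK_FLOOR = 1e-10
LOG_LIK_FLOOR = math.log(LIK_FLOOR)
#: initial action value for both modules (1 / number of actions)
Q_INIT = 1.0 / 3.0
#: response window in seconds
RESPONSE_WINDOW = 7.0

PARAM_NAMES = ("alpha", "bias", "phi", "rho", "C", "eta", "A", "k")


@dataclass(frozen=True)
class SubjectParameters:
    """The eight free parameters plus the fixed constants.

    alpha: learning rate; bias: positive-learning bias (scales down learning
    after negative prediction errors); phi: working-memory decay; rho:
    working-memory prior weight; C: working-memory capacity; eta: drift
    scaling; A: start-point upper limit; k: relative threshold (decision
    threshold b = A + k).
    """

    alpha: float
    bias: float
    phi: float
    rho: float
    C: float
    eta: float
    A: float
    k: float
    beta: float = FIXED_BETA
    tau: float = FIXED_TAU
    s: float = FIXED_S

    def __post_init__(self):
        for name in ("alpha", "bias", "phi", "rho"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 2.0 < self.C < 5.0:
            raise ValueError(f"C must lie in (2, 5), got {self.C}")
        for name in ("eta", "A", "k"):
            v = getattr(self, name)
            if v <= 0.0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def b(self) -> float:
        """Decision threshold."""
        return self.A + self.k

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values, **fixed) -> "SubjectParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))), **fixed)


@dataclass
class LearnerState:
    """Per-block value tables over (stimulus, action), entries in [0, 1]."""

    Q_RL: np.ndarray
    Q_WM: np.ndarray

    @classmethod
    def fresh(cls, set_size: int) -> "LearnerState":
        return cls(
            Q_RL=np.full((set_size, 3), Q_INIT),
            Q_WM=np.full((set_size, 3), Q_INIT),
        )


def rl_update(q: float, r: int, alpha: float, bias: float) -> float:
    """Delta-rule update; negative prediction errors use rate (1 - bias) * alpha."""
    delta = r - q
    rate = (1.0 - bias) * alpha if delta < 0 else alpha
    return q + rate * delta


def wm_update(q: float, r: int, bias: float) -> float:
    """Working-memory update: learning rate 1, scaled by (1 - bias) when r < q."""
    if r >= q:
        return float(r)
    return q + (1.0 - bias) * (r - q)


def wm_decay(q_wm: np.ndarray, phi: float) -> np.ndarray:
    """Pull every working-memory entry toward the initial value by phi."""
    return q_wm + phi * (Q_INIT - q_wm)


def softmax_policy(q_row: np.ndarray, beta: float = FIXED_BETA) -> np.ndarray:
    """Numerically stable softmax over action values."""
    z = beta * np.asarray(q_row, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def mixing_weight(rho: float, C: float, set_size: int) -> float:
    """Working-memory contribution W = rho * min(1, C / set_size)."""
    return rho * min(1.0, C / set_size)


def mixed_policy(p_wm: np.ndarray, p_rl: np.ndarray, w: float) -> np.ndarray:
    return w * np.asarray(p_wm) + (1.0 - w) * np.asarray(p_rl)


def average_policy(policies: np.ndarray) -> np.ndarray:
    """Stimulus-average of per-stimulus mixed policies (one row per stimulus)."""
    return np.asarray(policies, dtype=float).mean(axis=0)


def prior_entropy(avg_policy: np.ndarray) -> float:
    """Shannon entropy in bits, with 0 * log2(0) = 0."""
    p = np.asarray(avg_policy, dtype=float)
    nz = p[p > 0.0]
    return float(-(nz * np.log2(nz)).sum())


def drift_rates(
    policy: np.ndarray, h_prior: float, eta: float, h_floor: float = H_FLOOR
) -> np.ndarray:
    """Entropy-scaled drift rates V = eta * policy / max(h_prior, h_floor)."""
    return eta * np.asarray(policy, dtype=float) / max(h_prior, h_floor)


# ---------------------------------------------------------------------------
# Linear ballistic accumulator
# ---------------------------------------------------------------------------


def _lba_pdf_cdf(t: float, v: float, A: float, b: float, s: float):
    """Per-accumulator first-passage density and CDF at decision time t."""
    ts = t * s
    z1 = (b - t * v) / ts
    z2 = (b - A - t * v) / ts
    f = (1.0 / A) * (
        -v * norm.cdf(z2) + s * norm.pdf(z2) + v * norm.cdf(z1) - s * norm.pdf(z1)
    )
    F = (
        1.0
        + ((b - A - t * v) / A) * norm.cdf(z2)
        - ((b - t * v) / A) * norm.cdf(z1)
        + (ts / A) * norm.pdf(z2)
        - (ts / A) * norm.pdf(z1)
    )
    return f, F


def lba_defective_density(
    choice: int,
    rt,
    v: np.ndarray,
    A: float,
    k: float,
    s: float = FIXED_S,
    tau: float = FIXED_TAU,
):
    """Unnormalized density that `choice` wins at time rt: f_c * prod(1 - F_j).

    ``rt`` may be a scalar or an array of response times.
    """
    scalar = np.isscalar(rt)
    t = np.atleast_1d(np.asarray(rt, dtype=float)) - tau
    valid = t > 0.0
    t = np.where(valid, t, 1.0)  # placeholder; masked out below
    b = A + k
    f_c, _ = _lba_pdf_cdf(t, float(v[choice]), A, b, s)
    dens = np.maximum(f_c, 0.0)
    for j in range(len(v)):
        if j == choice:
            continue
        _, F_j = _lba_pdf_cdf(t, float(v[j]), A, b, s)
        dens = dens * np.clip(1.0 - F_j, 0.0, 1.0)
    dens = np.where(valid, dens, 0.0)
    return float(dens[0]) if scalar else dens


def lba_logpdf(
    choice: int,
    rt: float,
    v: np.ndarray,
    A: float,
    k: float,
    s: float = FIXED_S,
    tau: float = FIXED_TAU,
) -> float:
    """Log defective choice/RT density, floored at log(1e-10).

    ``rt <= tau`` signals an invalid decision time and returns the floor
    (see :func:`is_valid_rt`).
    """
    if rt <= tau:
        return LOG_LIK_FLOOR
    dens = lba_defective_density(choice, rt, v, A, k, s, tau)
    if not np.isfinite(dens) or dens < LIK_FLOOR:
        return LOG_LIK_FLOOR
    return float(np.log(dens))


def is_valid_rt(rt: float, tau: float = FIXED_TAU) -> bool:
    """A response time is scoreable only if it exceeds the non-decision time."""
    return rt is not None and rt > tau


def lba_termination_probability(v: np.ndarray, s: float = FIXED_S) -> float:
    """Probability that at least one accumulator has a positive drift draw."""
    return 1.0 - float(np.prod(norm.cdf(-np.asarray(v, dtype=float) / s)))


def lba_sample(
    v: np.ndarray,
    A: float,
    k: float,
    s: float = FIXED_S,
    tau: float = FIXED_TAU,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    max_resample: int = 1000,
) -> tuple[int, float]:
    """Draw one (choice, rt) from the accumulator race.

    Start points are Uniform(0, A); drifts Normal(v_i, s). The drift vector
    is resampled while all drifts are negative (capped; then the max-v
    accumulator is forced positive).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    v = np.asarray(v, dtype=float)
    b = A + k
    starts = rng.uniform(0.0, A, size=len(v))
    drifts = rng.normal(v, s)
    attempts = 0
    while np.all(drifts <= 0.0):
        attempts += 1
        if attempts >= max_resample:
            i = int(np.argmax(v))
            drifts[i] = abs(drifts[i]) + 1e-12
            break
        drifts = rng.normal(v, s)
    times = np.where(drifts > 0.0, (b - starts) / drifts, np.inf)
    choice = int(np.argmin(times))
    return choice, float(tau + times[choice])


def lba_sample_many(
    v: np.ndarray,
    A: float,
    k: float,
    n: int,
    s: float = FIXED_S,
    tau: float = FIXED_TAU,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    max_resample: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of ``n`` (choice, rt) pairs from one race configuration."""
    if rng is None:
        rng = np.random.default_rng(seed)
    v = np.asarray(v, dtype=float)
    b = A + k
    starts = rng.uniform(0.0, A, size=(n, len(v)))
    drifts = rng.normal(v, s, size=(n, len(v)))
    stuck = np.all(drifts <= 0.0, axis=1)
    for _ in range(max_resample):
        if not stuck.any():
            break
        drifts[stuck] = rng.normal(v, s, size=(int(stuck.sum()), len(v)))
        stuck = np.all(drifts <= 0.0, axis=1)
    if stuck.any():
        i = int(np.argmax(v))
        drifts[stuck, i] = np.abs(drifts[stuck, i]) + 1e-12
    times = np.where(drifts > 0.0, (b - starts) / drifts, np.inf)
    choices = times.argmin(axis=1)
    rts = tau + times[np.arange(n), choices]
    return choices, rts


# ---------------------------------------------------------------------------
# Session-level simulation and likelihood
# ---------------------------------------------------------------------------


def _trial_policy_and_drifts(
    state: LearnerState, stim_idx: int, params: SubjectParameters, h_floor: float
) -> np.ndarray:
    """Drift rates for the current trial from the pre-trial learner state."""
    set_size = state.Q_RL.shape[0]
    w = mixing_weight(params.rho, params.C, set_size)
    mixed = np.empty((set_size, 3))
    for j in range(set_size):
        p_rl = softmax_policy(state.Q_RL[j], params.beta)
        p_wm = softmax_policy(state.Q_WM[j], params.beta)
        mixed[j] = mixed_policy(p_wm, p_rl, w)
    h = prior_entropy(average_policy(mixed))
    return drift_rates(mixed[stim_idx], h, params.eta, h_floor)


def _apply_updates(
    state: LearnerState, stim_idx: int, action: int, reward: int, params: SubjectParameters
) -> None:
    state.Q_RL[stim_idx, action] = rl_update(
        state.Q_RL[stim_idx, action], reward, params.alpha, params.bias
    )
    state.Q_WM[stim_idx, action] = wm_update(
        state.Q_WM[stim_idx, action], reward, params.bias
    )
    state.Q_WM = wm_decay(state.Q_WM, params.phi)


def simulate_agent(
    session: SessionDesign,
    params: SubjectParameters,
    seed: int,
    *,
    subject_id: int = 0,
    h_floor: float = H_FLOOR,
    timeout_policy: str = "resample",
) -> pd.DataFrame:
    """Simulate one full session of behavior from the generative model.

    ``timeout_policy`` controls races finishing after the 7 s response
    window: "resample" reruns the race (the agent always responds in time),
    "miss" records a non-response.
    """
    if timeout_policy not in ("resample", "miss"):
        raise ValueError(f"unknown timeout_policy {timeout_policy!r}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x51A7, subject_id & 0xFFFF])
    records: list[TrialRecord] = []
    for block in session.blocks:
        stimuli = block.stimuli
        stim_index = {s: i for i, s in enumerate(stimuli)}
        state = LearnerState.fresh(block.set_size)
        for t, stim in enumerate(block.stimulus_sequence):
            si = stim_index[stim]
            v = _trial_policy_and_drifts(state, si, params, h_floor)
            choice, rt = lba_sample(v, params.A, params.k, params.s, params.tau, rng=rng)
            if rt > RESPONSE_WINDOW and timeout_policy == "resample":
                for _ in range(1000):
                    choice, rt = lba_sample(
                        v, params.A, params.k, params.s, params.tau, rng=rng
                    )
                    if rt <= RESPONSE_WINDOW:
                        break
            responded = rt <= RESPONSE_WINDOW or timeout_policy == "resample"
            rec = TrialRecord(
                subject_id=subject_id,
                block=block.block_index,
                trial_in_block=t,
                set_size=block.set_size,
                stimulus_id=stim,
                correct_action=block.correct_action_map[stim],
            )
            if responded:
                reward = int(choice == block.correct_action_map[stim])
                rec = replace(rec, action=choice, reward=reward, rt=min(rt, RESPONSE_WINDOW))
                _apply_updates(state, si, choice, reward, params)
            records.append(rec)
    from .task import trials_to_frame

    return trials_to_frame(compute_task_factors(records))


def session_loglik(
    trials,
    params: SubjectParameters,
    *,
    h_floor: float = H_FLOOR,
    fast: bool = False,
) -> float:
    """Total log-likelihood of observed (choice, rt) pairs for one subject.

    Replays the learning model on the observed history, scoring every trial
    with the LBA density. Pure function of (trials, params); raises if a
    trial is missing its choice or rt (non-responses must be excluded
    upstream).
    """
    df = trials if isinstance(trials, pd.DataFrame) else None
    if df is None:
        from .task import trials_to_frame

        df = trials_to_frame(list(trials))
    if len(df) == 0:
        return 0.0
    if df["action"].isna().any() or df["rt"].isna().any():
        bad = df.index[df["action"].isna() | df["rt"].isna()][0]
        raise ValueError(f"trial at index {bad} is missing choice or rt")
    if fast:
        from . import _fast

        stim, act, rew, rt, block_ptr, ss_arr = pack_subject_arrays(df)
        return float(
            _fast.subject_loglik(
                stim, act, rew, rt, block_ptr, ss_arr,
                params.alpha, params.bias, params.phi, params.rho,
                params.C, params.eta, params.A, params.k,
                params.beta, params.tau, params.s, h_floor,
            )
        )
    total = 0.0
    for block_id, bdf in df.groupby("block", sort=False):
        set_size = int(bdf["set_size"].iloc[0])
        stimuli = sorted(bdf["stimulus_id"].unique())
        stim_index = {s: i for i, s in enumerate(stimuli)}
        state = LearnerState.fresh(set_size)
        for row in bdf.itertuples(index=False):
            si = stim_index[row.stimulus_id]
            v = _trial_policy_and_drifts(state, si, params, h_floor)
            total += lba_logpdf(
                int(row.action), float(row.rt), v, params.A, params.k, params.s, params.tau
            )
            _apply_updates(state, si, int(row.action), int(row.reward), params)
    return total


def pack_subject_arrays(df: pd.DataFrame):
    """Flatten one subject's trial table into arrays for the fast likelihood.

    Returns (stim_local, action, reward, rt, block_ptr, set_sizes): local
    stimulus indices 0..set_size-1 per block, block start offsets, and per-
    block set sizes, in table order.
    """
    stim = np.empty(len(df), dtype=np.int64)
    block_ptr = [0]
    set_sizes = []
    pos = 0
    for _, bdf in df.groupby("block", sort=False):
        stimuli = {s: i for i, s in enumerate(sorted(bdf["stimulus_id"].unique()))}
        stim[pos : pos + len(bdf)] = [stimuli[s] for s in bdf["stimulus_id"]]
        pos += len(bdf)
        block_ptr.append(pos)
        set_sizes.append(int(bdf["set_size"].iloc[0]))
    return (
        stim,
        df["action"].to_numpy(dtype=np.int64),
        df["reward"].to_numpy(dtype=np.int64),
        df["rt"].to_numpy(dtype=np.float64),
        np.array(block_ptr, dtype=np.int64),
        np.array(set_sizes, dtype=np.int64),
    )
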