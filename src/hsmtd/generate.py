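"""Synthetic odor-guided choice task sessions and small fixture processes.

A session consists of four unsignalled blocks of forced-choice trials.
Blocks 1 and 2 manipulate reward timing (one well immediate, the other on
a titrated 1-7 s delay, contingencies swapped at the block switch); blocks
3 and 4 manipulate reward number (one well two boli 500 ms apart, the
other a single bolus, swapped at the switch).  Each trial is a fixed cycle
of events -- house light on, odor cue, well entry, reward boli, house
light off -- separated by an inter-trial interval; all timing is
discretized at ``dt``.  Block boundaries carry no distinguishing
observation: inferring the current block from reward history is exactly
the computational problem the hierarchical model solves.

Reward omissions are encoded as the *absence* of the reward symbol at the
previously scheduled time; the generator annotates those expected times so
downstream analyses can align to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spaces import StateSpace, normalize_observation_rows, uniform_dwell

__all__ = [
    "VOCAB", "NULL", "SessionConfig", "Session",
    "generate_session", "make_fixture_hsmm", "sample_sequence",
    "synthesize_spike_counts", "titrated_delay_sequence",
]

#: canonical task observation vocabulary (null last)
VOCAB = ["light_on", "odor_left", "odor_right", "well_entry", "reward",
         "light_off", "null"]
NULL = "null"

SIDES = ("left", "right")

#: per-block contingencies: (left condition, right condition)
BLOCK_PLAN = [
    ("short", "long"),   # block 1: timing manipulation
    ("long", "short"),   # block 2: contingencies swapped
    ("big", "small"),    # block 3: number manipulation (first big block)
    ("small", "big"),    # block 4: swapped
]


@dataclass
class SessionConfig:
    """Task schedule parameters (defaults reproduce the modelled task)."""

    trials_per_block: int = 60
    n_sessions: int = 30
    dt: float = 0.1                  # s per step
    iti: float = 4.0                 # inter-trial interval, s
    light_to_odor: float = 0.5       # s from house light to odor cue
    odor_to_well: float = 1.0        # s from odor to well entry
    short_delay: float = 0.5         # immediate-reward delay, s
    bolus_gap: float = 0.5           # gap between boli in big blocks, s
    light_off_delay: float = 1.0     # s from last bolus to light off
    delay_start: float = 1.0         # long-side titration start, s
    delay_step: float = 1.0          # titration increment, s
    delay_plateau: float = 3.0       # first plateau of the titration, s
    delay_max: float = 7.0           # titration ceiling, s
    delay_demotion_min: float = 3.0  # floor when demotion triggers, s
    max_side_repeat: int = 3         # pseudorandom side sequence constraint

    def __post_init__(self) -> None:
        if self.trials_per_block < 10:
            raise ValueError(
                "trials_per_block must be >= 10 (first/last five-trial analyses)"
            )
        if not 0 < self.dt:
            raise ValueError("dt must be positive")

    def steps(self, seconds: float) -> int:
        return int(round(seconds / self.dt))

    def mean_long_delay(self) -> float:
        """Mean titrated delay over a block's long-side trials (s)."""
        seq = titrated_delay_sequence(self, self.trials_per_block // 2)
        return float(np.mean(seq))

    def long_delay_stats(self) -> tuple[float, float]:
        """Mean and standard deviation (s) of the titrated long delays a
        block actually produces."""
        seq = np.asarray(titrated_delay_sequence(self, self.trials_per_block // 2))
        return float(seq.mean()), float(seq.std())


@dataclass
class Session:
    """One generated session: symbol stream plus tidy event annotations."""

    codes: np.ndarray          # observation code per step (indices into VOCAB)
    rewards: np.ndarray        # reward magnitude per step
    trial_start: np.ndarray    # bool mask, True at light-on steps
    events: pd.DataFrame       # block, trial, trial_in_block, side, event, t, reward
    config: SessionConfig
    vocab: list[str] = field(default_factory=lambda: list(VOCAB))

    @property
    def n_steps(self) -> int:
        return len(self.codes)

    def symbols(self) -> list[str]:
        return [self.vocab[c] for c in self.codes]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-step table (t, symbol, reward)."""
        return pd.DataFrame({
            "t": np.arange(self.n_steps),
            "symbol": self.symbols(),
            "reward": self.rewards,
        })


def titrated_delay_sequence(config: SessionConfig, n_long_trials: int) -> list[float]:
    """Delay (s) on successive long-side trials of a delay block.

    Starts at ``delay_start`` and grows ``delay_step`` per long-side choice
    until ``delay_plateau``, then keeps growing to ``delay_max`` while the
    side continues to be chosen (forced trials always are).
    """
    seq, delay = [], config.delay_start
    for _ in range(n_long_trials):
        seq.append(delay)
        delay = min(delay + config.delay_step, config.delay_max)
    return seq


def demote_delay(delay: float, chosen_long_of_last10: int,
                 config: SessionConfig) -> float:
    """Titration demotion rule: if the long side was chosen on fewer than 8
    of the last 10 choice trials, the delay drops one step (floor 3 s).
    Inactive in default simulations, which contain no free choices."""
    if chosen_long_of_last10 < 8:
        return max(delay - config.delay_step, config.delay_demotion_min)
    return delay


def _side_sequence(n_trials: int, max_repeat: int, rng: np.random.Generator):
    """Equal left/right counts with at most ``max_repeat`` consecutive
    repeats, by seeded rejection sampling."""
    half = n_trials // 2
    base = np.array([0] * half + [1] * (n_trials - half))
    for _ in range(1000):
        perm = rng.permutation(base)
        run, ok = 1, True
        for i in range(1, n_trials):
            run = run + 1 if perm[i] == perm[i - 1] else 1
            if run > max_repeat:
                ok = False
                break
        if ok:
            return perm
    return np.arange(n_trials) % 2  # deterministic fallback


def generate_session(config: SessionConfig, seed) -> Session:
    """Generate one session's observation/event stream (deterministic in
    ``seed``)."""
    rng = np.random.default_rng(seed)
    code = {s: i for i, s in enumerate(VOCAB)}
    null = code[NULL]

    steps_iti = config.steps(config.iti)
    rel_odor = config.steps(config.light_to_odor)
    rel_well = rel_odor + config.steps(config.odor_to_well)
    gap = config.steps(config.bolus_gap)
    off_delay = config.steps(config.light_off_delay)

    codes: list[np.ndarray] = []
    events: list[dict] = []
    t = 0

    def emit_block(block_idx: int, trial_offset: int, t: int) -> int:
        left_cond, right_cond = BLOCK_PLAN[block_idx]
        cond = {"left": left_cond, "right": right_cond}
        sides = _side_sequence(config.trials_per_block, config.max_side_repeat, rng)
        long_delays = iter(titrated_delay_sequence(config, config.trials_per_block))
        high_side = ("left" if cond["left"] in ("short", "big") else "right")
        for k, side_i in enumerate(sides):
            side = SIDES[side_i]
            c = cond[side]
            delay = next(long_delays) if c == "long" else config.short_delay
            n_boli = 2 if c == "big" else 1
            rel_b1 = rel_well + config.steps(delay)
            rel_last = rel_b1 + (gap if n_boli == 2 else 0)
            rel_off = rel_last + off_delay
            n_steps = rel_off + 1 + steps_iti
            trial = np.full(n_steps, null, dtype=np.int64)
            rew = np.zeros(n_steps)
            trial[0] = code["light_on"]
            trial[rel_odor] = code[f"odor_{side}"]
            trial[rel_well] = code["well_entry"]
            trial[rel_b1] = code["reward"]
            rew[rel_b1] = 1.0
            if n_boli == 2:
                trial[rel_b1 + gap] = code["reward"]
                rew[rel_b1 + gap] = 1.0
            trial[rel_off] = code["light_off"]

            common = dict(block=block_idx + 1, trial=trial_offset + k,
                          trial_in_block=k, side=side, condition=c)
            events.append({**common, "event": "light_on", "t": t, "reward": 0.0,
                           "cue_value": ""})
            events.append({**common, "event": "odor", "t": t + rel_odor, "reward": 0.0,
                           "cue_value": "high" if side == high_side else "low"})
            events.append({**common, "event": "well_entry", "t": t + rel_well,
                           "reward": 0.0, "cue_value": ""})
            events.append({**common, "event": "bolus1", "t": t + rel_b1,
                           "reward": 1.0, "cue_value": ""})
            if n_boli == 2:
                events.append({**common, "event": "bolus2", "t": t + rel_b1 + gap,
                               "reward": 1.0, "cue_value": ""})
            # expected-but-absent rewards, per the previous block's schedule
            if block_idx == 1 and c == "long":
                events.append({**common, "event": "omission_timing",
                               "t": t + rel_well + config.steps(config.short_delay),
                               "reward": 0.0, "cue_value": ""})
            if block_idx == 3 and c == "small":
                events.append({**common, "event": "omission_bolus2",
                               "t": t + rel_b1 + gap, "reward": 0.0, "cue_value": ""})
            events.append({**common, "event": "light_off", "t": t + rel_off,
                           "reward": 0.0, "cue_value": ""})
            codes.append(trial)
            rewards.append(rew)
            t += n_steps
        return t

    rewards: list[np.ndarray] = []
    # lead-in inter-trial interval so the session starts between trials
    codes.append(np.full(steps_iti, null, dtype=np.int64))
    rewards.append(np.zeros(steps_iti))
    t = steps_iti
    for b in range(4):
        t = emit_block(b, b * config.trials_per_block, t)

    all_codes = np.concatenate(codes)
    all_rewards = np.concatenate(rewards)
    ev = pd.DataFrame(events)
    trial_start = np.zeros(len(all_codes), dtype=bool)
    trial_start[ev.loc[ev.event == "light_on", "t"].to_numpy()] = True
    return Session(codes=all_codes, rewards=all_rewards, trial_start=trial_start,
                   events=ev, config=config)


# ---------------------------------------------------------------------------
# fixtures for inference tests and spike-count synthesis for fitting
# ---------------------------------------------------------------------------

def make_fixture_hsmm(n_states: int = 3, dwell_max: int = 3, seed=0,
                      n_extra_obs: int = 0, length: int = 8):
    """A small random hidden semi-Markov process plus a sampled stream.

    Each state has a characteristic symbol plus shared access to every
    other symbol and the null symbol (random simplex rows), random
    transitions, and random dwell distributions on 1..dwell_max.  Small
    enough for exhaustive trajectory enumeration.

    Returns ``(space, codes, entries)`` where ``entries`` is the
    ground-truth list of (step, state) entry pairs.
    """
    rng = np.random.default_rng(seed)
    n_obs = n_states + 1 + n_extra_obs
    obs_labels = [f"sym{i}" for i in range(n_obs - 1)] + [NULL]
    T = rng.dirichlet(np.ones(n_states), size=n_states)
    raw_O = rng.dirichlet(np.ones(n_obs), size=n_states) + 1e-3
    # give each state a distinctive symbol and real null mass
    for s in range(n_states):
        raw_O[s, s % (n_obs - 1)] += 2.0
        raw_O[s, -1] += 1.0
    O = normalize_observation_rows(raw_O)
    D = rng.dirichlet(np.ones(dwell_max), size=n_states) + 1e-3
    D /= D.sum(axis=1, keepdims=True)
    space = StateSpace(
        state_labels=[f"s{i}" for i in range(n_states)],
        observation_labels=obs_labels, null_symbol=NULL,
        T=T, O=O, D=D,
    )
    codes, entries = sample_sequence(space, length, rng)
    return space, codes, entries


def sample_sequence(space: StateSpace, length: int, rng,
                    prior: np.ndarray | None = None):
    """Sample an observation stream from the generative process.

    Emission happens on state entry; the stream carries the null symbol
    while the process dwells.  Returns ``(codes, entries)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = space.n_states
    if prior is None:
        prior = np.full(n, 1.0 / n)
    null = space.null_index
    codes = np.empty(length, dtype=np.int64)
    entries = []
    t = 0
    s = rng.choice(n, p=prior)
    while t < length:
        entries.append((t, int(s)))
        codes[t] = rng.choice(space.n_obs, p=space.O[s])
        d = 1 + rng.choice(space.d_max, p=space.D[s])
        for k in range(1, d):
            if t + k < length:
                codes[t + k] = null
        t += d
        s = rng.choice(n, p=space.T[s])
    return codes, entries


def synthesize_spike_counts(rates, window: float = 0.4, seed=0) -> np.ndarray:
    """Poisson spike counts for per-event firing rates (Hz) in a counting
    window (s); deterministic given ``seed``."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(rates * window)
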