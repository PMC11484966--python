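"""Belief-gated temporal-difference learning.

Prediction errors are computed per state and gated by the exit posterior
``beta``: only states the filter believes have just been left contribute.
The reward and the (transition- and observation-weighted) successor value
are discounted by ``exp(-tau * dt * E[d])``, the expected time spent in
the exiting state, so that delayed rewards are worth less.  The total
error over states updates every state value through an eligibility trace
that records visits since the start of the trial, and -- whenever a task
event arrives -- re-centres the exiting states' dwell-time distributions
on the interval that actually elapsed.

The total error maps onto a dopamine-like firing rate around a 3 Hz
baseline with asymmetric gains (5 Hz per unit of positive error, 2 Hz per
unit of negative error), reflecting the weaker representation of negative
errors in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import BeliefFilter
from .spaces import StateSpace

__all__ = [
    "LearnerHyper",
    "LearnerState",
    "TDLearner",
    "ErrorTrace",
    "prediction_error",
    "update_values",
    "update_eligibility",
    "update_dwell_distribution",
    "to_firing_rate",
    "dwell_kernel",
]


@dataclass
class LearnerHyper:
    """Hyperparameters of the learner (rates per second where noted)."""

    tau: float = 0.05          # discount rate, 1/s
    eta_r: float = 0.5         # value learning rate
    gamma: float = 0.95        # eligibility decay per step
    eta_d: float = 0.3         # dwell learning rate
    cv_d: float = 0.05         # dwell kernel coefficient of variation
    dwell_floor: float = 1e-4  # baseline dwell probability D_b
    eta_t: float = 0.3         # block-transition learning rate
    dt: float = 0.1            # step size, s
    baseline_hz: float = 3.0
    k_pos: float = 5.0         # firing gain for positive errors
    k_neg_mag: float = 2.0     # firing gain magnitude for negative errors
    discount_sign: float = -1.0  # -1: true discounting; +1: printed-sign variant
    dwell_amplitude: float = 1.0   # scales E[d]'s modulation of the discount
    kernel_amplitude: float = 1.0  # scales the dwell-update kernel (0 under VS lesion)
    # state-independent dwell (steps) the discount falls back to when the
    # amplitude is reduced: the mean of the uniform baseline distribution.
    # A literal zero dwell would abolish discounting altogether and leave
    # the continuing task's value recursion without a fixed point.
    baseline_dwell_steps: float = 75.5

    def __post_init__(self) -> None:
        for name in ("tau", "eta_r", "gamma", "eta_d", "cv_d", "dwell_floor",
                     "eta_t", "dt", "baseline_hz", "k_pos", "k_neg_mag"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be strictly positive")
        if not self.gamma < 1:
            raise ValueError("gamma must be < 1")
        if self.discount_sign not in (-1.0, 1.0):
            raise ValueError("discount_sign must be +/-1")

    @property
    def gamma_step(self) -> float:
        """Per-step eligibility decay.  ``gamma`` is a per-second rate so
        that credit propagation spans the same real time at any step size;
        the per-step factor is ``gamma ** dt``."""
        return self.gamma ** self.dt


@dataclass
class LearnerState:
    """Mutable learner variables: values, eligibility, hyperparameters."""

    V: np.ndarray
    E: np.ndarray
    hyper: LearnerHyper

    @classmethod
    def zeros(cls, n_states: int, hyper: LearnerHyper | None = None) -> "LearnerState":
        return cls(V=np.zeros(n_states), E=np.zeros(n_states),
                   hyper=hyper or LearnerHyper())


@dataclass
class ErrorTrace:
    """Per-timestep prediction errors and their firing-rate conversion."""

    delta_total: np.ndarray
    firing_rate: np.ndarray
    delta_by_state: np.ndarray | None = None
    event_tags: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def prediction_error(V: np.ndarray, space: StateSpace, beta: np.ndarray,
                     exp_dwell: np.ndarray, r_next: float, o_next: int,
                     hyper: LearnerHyper,
                     trans_obs: np.ndarray | None = None) -> np.ndarray:
    """Vectorized, exit-gated prediction error.

    ``delta[s] = beta[s] * (g_s * r_next + g_s * E[V_succ|s] - V[s])`` with
    ``g_s = exp(sign * tau * dt * E[d_s])`` and the successor value averaged
    over ``T[s] * O[:, o_next]``.
    """
    if trans_obs is None:
        trans_obs = space.T @ space.O[:, o_next]
    ev = np.zeros(len(V))
    np.divide(space.T @ (space.O[:, o_next] * V), trans_obs, out=ev,
              where=trans_obs > 0)
    a = hyper.dwell_amplitude
    eff_dwell = a * exp_dwell + (1.0 - a) * hyper.baseline_dwell_steps
    g = np.exp(hyper.discount_sign * hyper.tau * hyper.dt * eff_dwell)
    return beta * (g * r_next + g * ev - V)


def update_values(V: np.ndarray, E: np.ndarray, delta_total: float,
                  eta_r: float) -> np.ndarray:
    """In-place TD update: every state moves by its eligibility-weighted
    share of the total error."""
    V += eta_r * E * delta_total
    return V


def update_eligibility(E: np.ndarray, beta: np.ndarray, gamma: float,
                       at_trial_start: bool = False) -> np.ndarray:
    """In-place trace update ``E = max(gamma * E, beta)``; zeroed at trial
    start so credit does not leak across trials."""
    if at_trial_start:
        E[:] = 0.0
    np.maximum(gamma * E, beta, out=E)
    return E


def dwell_kernel(elapsed: int, d_max: int, cv: float,
                 amplitude: float = 1.0) -> np.ndarray:
    """Discretized Gaussian dwell kernel: mean ``elapsed`` steps, standard
    deviation ``cv * elapsed``, normalized then scaled by ``amplitude``."""
    if elapsed > d_max:
        elapsed = d_max
    d = np.arange(1, d_max + 1, dtype=float)
    sd = max(cv * elapsed, 1e-9)
    k = np.exp(-0.5 * ((d - elapsed) / sd) ** 2)
    tot = k.sum()
    if tot <= 0:
        k = np.zeros(d_max)
        k[int(np.clip(elapsed, 1, d_max)) - 1] = 1.0
        tot = 1.0
    return amplitude * k / tot


def update_dwell_distribution(D: np.ndarray, state: int, beta_s: float,
                              elapsed: int, hyper: LearnerHyper,
                              kernel: np.ndarray | None = None) -> np.ndarray:
    """In-place update of one dwell row toward a kernel centred on the
    elapsed interval, gated by the exit posterior; floored and renormalized."""
    if beta_s <= 0:
        return D
    if kernel is None:
        kernel = dwell_kernel(elapsed, D.shape[1], hyper.cv_d, hyper.kernel_amplitude)
    row = D[state]
    row += hyper.eta_d * beta_s * (kernel - row)
    np.maximum(row, hyper.dwell_floor, out=row)
    row /= row.sum()
    return D


def to_firing_rate(delta_total, hyper: LearnerHyper | None = None):
    """Convert total prediction error to firing rate (Hz).

    Positive errors add ``k_pos`` Hz per unit; negative errors subtract
    ``k_neg_mag`` Hz per unit of magnitude; rates clip at 0.
    """
    h = hyper or LearnerHyper()
    d = np.asarray(delta_total, dtype=float)
    rate = np.where(d >= 0, h.baseline_hz + h.k_pos * d, h.baseline_hz + h.k_neg_mag * d)
    return np.maximum(rate, 0.0)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

class TDLearner:
    """Couples a belief filter with TD learning over an observation stream.

    The learner owns mutable ``V`` and ``E`` and updates ``space.D`` in
    place for states whose dwell rows are plastic.  Filter caches are
    refreshed automatically after dwell updates.
    """

    def __init__(self, space: StateSpace, hyper: LearnerHyper | None = None,
                 state: LearnerState | None = None,
                 prior: np.ndarray | None = None):
        self.space = space
        self.hyper = hyper or LearnerHyper()
        self.state = state or LearnerState.zeros(space.n_states, self.hyper)
        self._prior = prior
        self.filter: BeliefFilter | None = None

    def begin_session(self, first_obs) -> None:
        """Start a fresh filter (belief resets between sessions; V, E and
        learned dwell distributions persist)."""
        self.filter = BeliefFilter(self.space, prior=self._prior)
        self.filter.begin(first_obs)
        self.state.E[:] = 0.0

    def step(self, o_next: int, r_next: float, at_trial_start: bool = False):
        """Process one observation; returns ``(delta_by_state, delta_total)``."""
        filt = self.filter
        if filt is None:
            raise RuntimeError("begin_session() must be called first")
        res = filt.advance(o_next)
        h = self.hyper
        delta = prediction_error(self.state.V, self.space, res.beta,
                                 res.exp_dwell, r_next, o_next, h,
                                 trans_obs=filt._TO[:, o_next])
        total = float(delta.sum())
        update_eligibility(self.state.E, res.beta, h.gamma_step, at_trial_start)
        update_values(self.state.V, self.state.E, total, h.eta_r)
        if o_next != filt.null_code:
            plastic = self.space.dwell_plastic
            if plastic.any():
                kernel = dwell_kernel(res.elapsed, self.space.d_max, h.cv_d,
                                      h.kernel_amplitude)
                tie_groups = self.space.meta.get("dwell_tie_groups", ())
                tied = {s for g in tie_groups for s in g}
                touched = []
                for s in np.nonzero(plastic & (res.beta > 1e-6))[0]:
                    if int(s) in tied:
                        continue
                    update_dwell_distribution(self.space.D, int(s),
                                              float(res.beta[s]), res.elapsed,
                                              h, kernel=kernel)
                    touched.append(int(s))
                # states the model cannot tell apart share one dwell row
                for group in tie_groups:
                    bg = float(res.beta[list(group)].sum())
                    if bg > 1e-6 and plastic[group[0]]:
                        update_dwell_distribution(self.space.D, group[0], bg,
                                                  res.elapsed, h, kernel=kernel)
                        for s in group[1:]:
                            self.space.D[s] = self.space.D[group[0]]
                        touched.extend(group)
                if touched:
                    filt.refresh_dwell(touched)
        return delta, total

    def run(self, codes: np.ndarray, rewards: np.ndarray,
            trial_start: np.ndarray, keep_by_state: bool = False,
            begin: bool = True) -> ErrorTrace:
        """Run over a full stream (e.g. one session).

        ``codes[0]`` initializes the filter when ``begin`` is true; errors
        are recorded from the second step on (index aligned with ``codes``,
        entry 0 is zero).
        """
        n_t = len(codes)
        delta_total = np.zeros(n_t)
        by_state = np.zeros((n_t, self.space.n_states)) if keep_by_state else None
        if begin:
            self.begin_session(int(codes[0]))
        start = 1 if begin else 0
        for t in range(start, n_t):
            d, tot = self.step(int(codes[t]), float(rewards[t]), bool(trial_start[t]))
            delta_total[t] = tot
            if keep_by_state:
                by_state[t] = d
        return ErrorTrace(delta_total=delta_total,
                          firing_rate=to_firing_rate(delta_total, self.hyper),
                          delta_by_state=by_state)
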