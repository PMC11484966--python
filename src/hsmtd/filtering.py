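"""Belief-state inference for partially observable semi-Markov processes.

The generative model: a hidden state ``s`` is entered, emits one
observation drawn from ``O[s]`` at the entry step, dwells for ``d`` steps
(``d ~ D[s]``) during which the stream carries the null symbol, then
transitions to a successor drawn from ``T[s]``.  Non-null observations are
therefore unambiguous evidence that a transition has just occurred; null
stretches leave the transition times hidden.

The filter tracks, at every step ``t``:

* ``alpha[s]`` -- P(s_t = s and the process exits s at t | o_1..o_t),
  obtained by summing entry weights over all dwell times compatible with
  the time elapsed since the last event,
* ``belief[s]`` -- P(s_t = s | o_1..o_t), the same sum with the dwell
  probability replaced by its survival function,
* ``beta[s]`` -- P(s_t = s and the process exits s at t | o_1..o_{t+1}),
  the exit posterior once the next observation is seen, and
* ``E[d_{s,t}]`` -- the posterior expected dwell time given an exit at t.

Because observations are emitted only on entry, the exit posterior sums
exactly to 1 whenever the next observation is non-null: an event implies a
transition.  The recursion is the exact Bayes filter of the generative
model above, so it can be validated against brute-force trajectory
enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spaces import StateSpace

__all__ = ["BeliefFilter", "BeliefTrace", "run_filter", "NumericalDegeneracyError"]

log = logging.getLogger(__name__)

_UNDERFLOW = 1e-300


class NumericalDegeneracyError(ArithmeticError):
    """Predictive likelihood underflowed; the observation stream is
    essentially impossible under the space.  Rescale probabilities or fix
    the vocabulary."""


@dataclass
class StepResult:
    """Quantities produced by one filter step (observation ``o_{t+1}``)."""

    beta: np.ndarray          # exit posterior at t, given o_{t+1}
    alpha_prev: np.ndarray    # exit prior at t (before seeing o_{t+1})
    exp_dwell: np.ndarray     # E[d_{s,t}] given exit at t (0 where alpha=0)
    elapsed: int              # steps since last non-null observation, at t
    pred_lik: float           # P(o_{t+1} | o_1..o_t)
    belief: np.ndarray        # filtered belief at t+1
    alpha: np.ndarray         # exit prior at t+1
    t0: int                   # steps since last non-null observation, at t+1


@dataclass
class BeliefTrace:
    """Per-timestep record of the filter, exportable as tidy text."""

    alpha: list = field(default_factory=list)
    beta: list = field(default_factory=list)
    belief: list = field(default_factory=list)
    pred_obs_lik: list = field(default_factory=list)
    t0: list = field(default_factory=list)

    def to_frame(self, space: StateSpace, session: int = 0) -> pd.DataFrame:
        rows = []
        n_t = len(self.belief)
        beta = self.beta + [np.full(len(space.state_labels), np.nan)]
        for t in range(n_t):
            for s, label in enumerate(space.state_labels):
                rows.append(
                    {
                        "session": session,
                        "t": t,
                        "state": label,
                        "alpha": self.alpha[t][s],
                        "beta": beta[t][s],
                        "belief": self.belief[t][s],
                    }
                )
        return pd.DataFrame(rows)


class BeliefFilter:
    """Stepwise exact filter over a :class:`StateSpace`.

    Parameters
    ----------
    space:
        The task description.  The filter keeps live views of ``space.T``
        and ``space.D``; call :meth:`refresh_dwell` / :meth:`refresh_T`
        after mutating them (the TD learner does this for you).
    prior:
        Distribution over the state entered at the first step.  Defaults
        to uniform.
    record:
        If true, keep a :class:`BeliefTrace` of every step.
    """

    def __init__(self, space: StateSpace, prior: np.ndarray | None = None,
                 record: bool = False):
        self.space = space
        n, dmax = space.n_states, space.d_max
        self._n = n
        self._dmax = dmax
        self.null_code = space.null_index
        if prior is None:
            prior = np.full(n, 1.0 / n)
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (n,) or abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
            raise ValueError("prior must be a distribution over states")
        self._prior = prior
        # (3, n, dmax): dwell pmf, survival P(d >= k), k * pmf
        self._W = np.empty((3, n, dmax))
        self.refresh_dwell()
        self._TO = np.empty((n, space.n_obs))
        self.refresh_T()
        self._Fbuf = np.zeros((dmax, n))   # entry weights, oldest first
        self._wlen = 0
        self._t = -1
        self._truncated = False
        self.trace = BeliefTrace() if record else None
        self.alpha = np.zeros(n)
        self.belief = np.zeros(n)
        self.exp_dwell = np.zeros(n)
        self._started = False

    def reset(self, prior: np.ndarray | None = None) -> None:
        """Rewind to the pre-stream state (buffers reused)."""
        if prior is not None:
            self._prior = prior
        self._wlen = 0
        self._t = -1
        self._started = False
        if self.trace is not None:
            self.trace = BeliefTrace()

    # -- cache maintenance ---------------------------------------------------
    def refresh_T(self) -> None:
        """Recompute transition caches after ``space.T`` changed."""
        np.matmul(self.space.T, self.space.O, out=self._TO)
        self._Tt = np.ascontiguousarray(self.space.T.T)

    def refresh_dwell(self, states=None) -> None:
        """Recompute dwell caches after ``space.D`` changed."""
        D = self.space.D
        idx = slice(None) if states is None else states
        self._W[0, idx] = D[idx]
        surv = np.cumsum(D[idx][..., ::-1], axis=-1)[..., ::-1]
        self._W[1, idx] = surv
        self._W[2, idx] = D[idx] * np.arange(1, self._dmax + 1)

    # -- stepping ------------------------------------------------------------
    def begin(self, obs) -> None:
        """Process the first observation of a stream."""
        o = obs if isinstance(obs, (int, np.integer)) else self.space.obs_index(obs)
        self._Fbuf[0] = self._prior * self.space.O[:, o]
        self._wlen = 1
        self._t = 0
        W = self._W[:, :, self._wlen - 1::-1]     # (3, n, wlen), age-aligned
        F = self._Fbuf[: self._wlen]              # (wlen, n)
        U = np.einsum("jn,knj->kn", F, W)         # rows: Ualpha, Ubel, Ud
        c = U[1].sum()
        if c < _UNDERFLOW:
            raise NumericalDegeneracyError("first observation impossible under prior")
        F /= c
        self.alpha = U[0] / c
        self.belief = U[1] / c
        with np.errstate(divide="ignore", invalid="ignore"):
            self.exp_dwell = np.where(U[0] > 0, U[2] / np.maximum(U[0], _UNDERFLOW), 0.0)
        self.last_lik = float(c)                  # P(o_1) under the prior
        if self.trace is not None:
            self.trace.alpha.append(self.alpha.copy())
            self.trace.belief.append(self.belief.copy())
            self.trace.t0.append(self._wlen)
        self._started = True

    def advance(self, obs) -> StepResult:
        """Consume the next observation ``o_{t+1}``; return the exit posterior
        at ``t`` together with the updated belief at ``t+1``."""
        if self._t < 0:
            raise RuntimeError("call begin() with the first observation first")
        space = self.space
        o = obs if isinstance(obs, (int, np.integer)) else space.obs_index(obs)
        alpha_prev = self.alpha
        exp_dwell = self.exp_dwell
        elapsed = self._wlen

        b = self._TO[:, o] * alpha_prev               # P(o_{t+1}, exit from s)
        new_F = space.O[:, o] * (self._Tt @ alpha_prev)

        if o != self.null_code:
            # events signal transitions: the dwell window restarts
            self._Fbuf[0] = new_F
            self._wlen = 1
        else:
            if self._wlen == self._dmax:
                if not self._truncated:
                    log.warning(
                        "dwell window exceeded d_max=%d; oldest entries dropped",
                        self._dmax,
                    )
                    self._truncated = True
                self._Fbuf[:-1] = self._Fbuf[1:]
                self._wlen -= 1
            self._Fbuf[self._wlen] = new_F
            self._wlen += 1

        self._t += 1
        # normalizer of the new window IS the predictive likelihood
        W = self._W[:, :, self._wlen - 1::-1]
        F = self._Fbuf[: self._wlen]
        U = np.einsum("jn,knj->kn", F, W)
        c = U[1].sum()
        if c < _UNDERFLOW:
            raise NumericalDegeneracyError(
                f"predictive likelihood underflowed at t={self._t}; "
                "consider rescaling probabilities"
            )
        F /= c
        beta = b / c
        np.minimum(beta, 1.0, out=beta)   # absorb <=1e-12 float slop
        self.alpha = U[0] / c
        self.belief = U[1] / c
        mask = U[0] > 0
        ed = np.zeros(self._n)
        np.divide(U[2], U[0], out=ed, where=mask)
        self.exp_dwell = ed
        self.last_lik = float(c)
        if self.trace is not None:
            self.trace.beta.append(beta.copy())
            self.trace.pred_obs_lik.append(float(c))
            self.trace.alpha.append(self.alpha.copy())
            self.trace.belief.append(self.belief.copy())
            self.trace.t0.append(self._wlen)
        return StepResult(
            beta=beta,
            alpha_prev=alpha_prev,
            exp_dwell=exp_dwell,
            elapsed=elapsed,
            pred_lik=float(c),
            belief=self.belief,
            alpha=self.alpha,
            t0=self._wlen,
        )

    # -- queries -------------------------------------------------------------
    def predictive_distribution(self) -> np.ndarray:
        """P(o_{t+1} = o | o_1..o_t) for every symbol; sums to 1."""
        space = self.space
        p = (space.T @ space.O).T @ self.alpha        # (n_obs,)
        p[self.null_code] += max(0.0, 1.0 - self.alpha.sum())
        return p

    def predictive_obs_likelihood(self, symbol) -> float:
        """P(o_{t+1} = symbol | o_1..o_t) without advancing the filter."""
        o = symbol if isinstance(symbol, (int, np.integer)) else self.space.obs_index(symbol)
        return float(self.predictive_distribution()[o])


def run_filter(space: StateSpace, symbols, prior: np.ndarray | None = None,
               record: bool = True) -> tuple[BeliefFilter, BeliefTrace]:
    """Run the filter over a full symbol stream; returns the filter and trace."""
    filt = BeliefFilter(space, prior=prior, record=record)
    codes = [s if isinstance(s, (int, np.integer)) else space.obs_index(s) for s in symbols]
    filt.begin(codes[0])
    for o in codes[1:]:
        filt.advance(o)
    return filt, filt.trace


def sequence_loglik(space: StateSpace, codes: np.ndarray, prior: np.ndarray) -> float:
    """Log-probability of an observation stream under the space.

    Used for the per-block trial likelihoods that drive block-transition
    learning in the hierarchical model.
    """
    filt = BeliefFilter(space, prior=prior, record=False)
    filt.begin(int(codes[0]))
    total = np.log(filt.last_lik)
    for o in codes[1:]:
        res = filt.advance(int(o))
        total += np.log(res.pred_lik)
    return float(total)
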