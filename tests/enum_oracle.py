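"""Brute-force trajectory-enumeration oracle for the semi-Markov filter.

Enumerates every (state, dwell) segmentation of a short observation stream
under the generative model -- emission on entry, deterministic null while
dwelling -- and sums trajectory weights directly.  Deliberately naive and
independent of the recursive filter it validates.
"""

from __future__ import annotations

import numpy as np


def survival(D: np.ndarray) -> np.ndarray:
    """S[s, d-1] = P(dwell >= d)."""
    return np.cumsum(D[:, ::-1], axis=1)[:, ::-1]


def enumerate_prefix(space, codes, prior=None, tag_step: int | None = None):
    """Unnormalized posterior weights after observing ``codes``.

    Returns ``(Ualpha, Ubel, Ud, Utag)`` where ``Ualpha[s]`` sums weights of
    trajectories whose last segment exits exactly at the final step,
    ``Ubel[s]`` sums occupancy weights (exit at or after the final step),
    ``Ud[s]`` the dwell-weighted exit mass, and ``Utag[s]`` (when
    ``tag_step`` is given) the total trajectory weight among those with a
    segment boundary exactly after step ``tag_step`` exiting from ``s``.
    """
    n = space.n_states
    L = len(codes)
    null = space.null_index
    D, T, O = space.D, space.T, space.O
    S = survival(D)
    dmax = space.d_max
    if prior is None:
        prior = np.full(n, 1.0 / n)
    Ualpha = np.zeros(n)
    Ubel = np.zeros(n)
    Ud = np.zeros(n)
    Utag = np.zeros(n)

    def rec(a: int, s: int, w: float, tag: int | None):
        w = w * O[s, codes[a]]
        if w == 0.0:
            return
        cover = 1
        while a + cover <= L - 1 and codes[a + cover] == null:
            cover += 1
        for d in range(1, min(cover, dmax) + 1):
            end = a + d - 1
            pd = D[s, d - 1]
            if pd == 0.0:
                continue
            if end < L - 1:
                ntag = s if (tag_step is not None and end == tag_step) else tag
                for s2 in range(n):
                    if T[s, s2] > 0:
                        rec(end + 1, s2, w * pd * T[s, s2], ntag)
            elif end == L - 1:
                Ualpha[s] += w * pd
                Ubel[s] += w * pd
                Ud[s] += w * pd * d
                if tag is not None:
                    Utag[tag] += w * pd
                if tag_step is not None and end == tag_step:
                    Utag[s] += w * pd
        if cover >= L - a:
            elapsed = L - a
            if elapsed < dmax:
                w_surv = w * S[s, elapsed]  # P(D >= elapsed + 1)
                Ubel[s] += w_surv
                if tag is not None:
                    Utag[tag] += w_surv

    for s in range(n):
        if prior[s] > 0:
            rec(0, s, prior[s], None)
    return Ualpha, Ubel, Ud, Utag


def oracle_posteriors(space, codes, prior=None):
    """Per-prefix alpha, belief, E[d], beta and predictive likelihoods.

    Returns a dict of arrays indexed by timestep t (0-based): ``alpha[t]``,
    ``belief[t]``, ``exp_dwell[t]``, plus ``beta[t]`` and ``pred_lik[t]``
    for t < L-1 (they condition on the next observation).
    """
    L = len(codes)
    n = space.n_states
    out = {
        "alpha": np.zeros((L, n)),
        "belief": np.zeros((L, n)),
        "exp_dwell": np.zeros((L, n)),
        "beta": np.full((L, n), np.nan),
        "pred_lik": np.full(L, np.nan),
    }
    totals = np.zeros(L)
    for t in range(L):
        Ua, Ub, Ud, _ = enumerate_prefix(space, codes[: t + 1], prior)
        tot = Ub.sum()
        totals[t] = tot
        out["alpha"][t] = Ua / tot
        out["belief"][t] = Ub / tot
        out["exp_dwell"][t] = np.where(Ua > 0, Ud / np.maximum(Ua, 1e-300), 0.0)
    for t in range(L - 1):
        _, Ub2, _, Utag = enumerate_prefix(space, codes[: t + 2], prior, tag_step=t)
        out["beta"][t] = Utag / Ub2.sum()
        out["pred_lik"][t] = Ub2.sum() / totals[t]
    return out
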