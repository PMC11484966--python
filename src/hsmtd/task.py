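"""Task state spaces and simulated circuit lesions.

Two representations of the odor-guided choice task:

* the **flat** space mirrors the animal's physical situation within a
  trial -- ten states (trial start, left/right cue, left/right well,
  left/right first and second reward, inter-trial interval) with learned
  dwell-time distributions; blocks are not represented, so contingency
  changes must be absorbed by relearning values and dwell times;
* the **hierarchical** space clones the trial states into four clusters,
  one per block contingency, with fixed (contingency-appropriate) dwell
  distributions; the only plastic transitions are the upper-level entries
  from the shared inter-trial state into each cluster's trial start, which
  are learned from each trial's observation likelihood under each block
  hypothesis -- a Bayesian prior over "which block am I in".

Lesion transforms corrupt specific pieces of this machinery:

* hippocampal lesion, flat space: cue-to-well transitions blurred to
  0.55 / 0.45, so the model cannot retain which well it chose;
* hippocampal lesion, hierarchical space: block-transition probabilities
  floored at 0.15 after every update, leaving residual uncertainty about
  the current block;
* orbitofrontal lesion (hierarchical): cue-to-well blurring, identical
  well dwell distributions, and first-reward states allowed to transit to
  either the second-reward or inter-trial state in the number blocks;
* ventral-striatal lesion: the expected-dwell discount amplitude and the
  dwell-update kernel are zeroed, so no precise temporal expectation can
  form (dwell rows stay at the uniform baseline).
"""

from __future__ import annotations

import numpy as np

from .generate import BLOCK_PLAN, NULL, VOCAB, SessionConfig
from .learning import LearnerHyper
from .spaces import (DWELL_FLOOR, SpecificationError, StateSpace,
                     gaussian_dwell_row, normalize_observation_rows,
                     uniform_dwell)

__all__ = [
    "build_flat_model", "build_hierarchical_model", "update_block_transitions",
    "apply_hc_lesion_flat", "apply_hc_lesion_hierarchical",
    "apply_ofc_lesion", "apply_vs_lesion", "vs_lesion_dwell_baseline",
]

_CHAR = {  # characteristic observation per trial-state role
    "trial_start": "light_on",
    "left_cue": "odor_left",
    "right_cue": "odor_right",
    "left_well": "well_entry",
    "right_well": "well_entry",
    "left_reward1": "reward",
    "left_reward2": "reward",
    "right_reward1": "reward",
    "right_reward2": "reward",
    "iti": "light_off",
}


def _obs_matrix(roles, char_w=0.95, null_w=0.05, bg_w=1e-4) -> np.ndarray:
    raw = np.full((len(roles), len(VOCAB)), bg_w)
    null_i = VOCAB.index(NULL)
    for i, role in enumerate(roles):
        raw[i, VOCAB.index(_CHAR[role])] = char_w
        raw[i, null_i] = null_w
    return normalize_observation_rows(raw)


def build_flat_model(d_max: int = 150, cue_cross: float = 1e-4) -> StateSpace:
    """The ten-state flat task space with learned dwell distributions.

    Cue states lead to the same-side well with probability ``1 - cue_cross``
    (background ``cue_cross`` to the opposite well); first-reward states
    may lead to a second reward or straight to the inter-trial interval.
    Dwell rows start at the uniform-with-floor baseline and are learned.
    """
    labels = ["trial_start", "left_cue", "right_cue", "left_well", "right_well",
              "left_reward1", "left_reward2", "right_reward1", "right_reward2",
              "iti"]
    ix = {s: i for i, s in enumerate(labels)}
    n = len(labels)
    T = np.zeros((n, n))
    T[ix["trial_start"], ix["left_cue"]] = 0.5
    T[ix["trial_start"], ix["right_cue"]] = 0.5
    T[ix["left_cue"], ix["left_well"]] = 1.0
    T[ix["left_cue"], ix["right_well"]] = cue_cross
    T[ix["right_cue"], ix["right_well"]] = 1.0
    T[ix["right_cue"], ix["left_well"]] = cue_cross
    T[ix["left_well"], ix["left_reward1"]] = 1.0
    T[ix["right_well"], ix["right_reward1"]] = 1.0
    T[ix["left_reward1"], ix["left_reward2"]] = 0.5
    T[ix["left_reward1"], ix["iti"]] = 0.5
    T[ix["right_reward1"], ix["right_reward2"]] = 0.5
    T[ix["right_reward1"], ix["iti"]] = 0.5
    T[ix["left_reward2"], ix["iti"]] = 1.0
    T[ix["right_reward2"], ix["iti"]] = 1.0
    T[ix["iti"], ix["trial_start"]] = 1.0
    T /= T.sum(axis=1, keepdims=True)

    return StateSpace(
        state_labels=labels,
        observation_labels=list(VOCAB),
        null_symbol=NULL,
        T=T,
        O=_obs_matrix(labels),
        D=uniform_dwell(n, d_max),
        level=["lower"] * n,
        dwell_plastic=np.ones(n, dtype=bool),
        meta={"kind": "flat", "index": ix},
    )


def _cluster_roles(block_idx: int) -> list[str]:
    """Lower-level state roles for one block cluster (number blocks carry
    second-reward states on both sides so lesions can open them up)."""
    roles = ["trial_start", "left_cue", "right_cue", "left_well", "right_well",
             "left_reward1", "right_reward1"]
    left, right = BLOCK_PLAN[block_idx]
    if "big" in (left, right) or "small" in (left, right):
        roles += ["left_reward2", "right_reward2"]
    return roles


def build_hierarchical_model(config: SessionConfig | None = None,
                             d_max: int = 150, cv: float = 0.05) -> StateSpace:
    """The hierarchical task space: four block clusters over a shared
    inter-trial state with plastic, initially uniform cluster entries.

    Dwell rows are fixed Gaussians (coefficient of variation ``cv``)
    centred on the mean event timings of the task configuration; the long
    side uses the mean titrated delay.
    """
    config = config or SessionConfig()
    labels: list[str] = []
    roles: list[str] = []
    cluster_of: list[int] = []
    for b in range(4):
        for role in _cluster_roles(b):
            labels.append(f"b{b + 1}_{role}")
            roles.append(role)
            cluster_of.append(b)
    labels.append("iti")
    roles.append("iti")
    cluster_of.append(-1)
    ix = {s: i for i, s in enumerate(labels)}
    n = len(labels)
    iti = ix["iti"]

    T = np.zeros((n, n))
    plastic = np.zeros((n, n), dtype=bool)
    for b in range(4):
        p = f"b{b + 1}_"
        left, right = BLOCK_PLAN[b]
        T[iti, ix[p + "trial_start"]] = 0.25
        plastic[iti, ix[p + "trial_start"]] = True
        T[ix[p + "trial_start"], ix[p + "left_cue"]] = 0.5
        T[ix[p + "trial_start"], ix[p + "right_cue"]] = 0.5
        T[ix[p + "left_cue"], ix[p + "left_well"]] = 1.0
        T[ix[p + "right_cue"], ix[p + "right_well"]] = 1.0
        T[ix[p + "left_well"], ix[p + "left_reward1"]] = 1.0
        T[ix[p + "right_well"], ix[p + "right_reward1"]] = 1.0
        for side, c in (("left", left), ("right", right)):
            r1 = ix[p + f"{side}_reward1"]
            if c == "big":
                T[r1, ix[p + f"{side}_reward2"]] = 1.0
                T[ix[p + f"{side}_reward2"], iti] = 1.0
            else:
                T[r1, iti] = 1.0
                if p + f"{side}_reward2" in ix:   # unreachable under control
                    T[ix[p + f"{side}_reward2"], iti] = 1.0
    T /= T.sum(axis=1, keepdims=True)

    # fixed dwell rows from mean task timings (steps); the long-side well
    # uses the spread of the titrated delays the task actually produces
    mean_long, sd_long = config.long_delay_stats()
    cv_long = max(cv, sd_long / mean_long if mean_long > 0 else cv)
    D = np.empty((n, d_max))
    for i, role in enumerate(roles):
        b = cluster_of[i]
        cv_i = cv
        if role == "iti":
            mean_s = config.iti
        elif role == "trial_start":
            mean_s = config.light_to_odor
        elif role.endswith("cue"):
            mean_s = config.odor_to_well
        elif role.endswith("well"):
            side = role.split("_")[0]
            c = BLOCK_PLAN[b][0 if side == "left" else 1]
            if c == "long":
                mean_s, cv_i = mean_long, cv_long
            else:
                mean_s = config.short_delay
        elif role.endswith("reward1"):
            side = role.split("_")[0]
            c = BLOCK_PLAN[b][0 if side == "left" else 1]
            mean_s = config.bolus_gap if c == "big" else config.light_off_delay
        else:  # reward2
            mean_s = config.light_off_delay
        D[i] = gaussian_dwell_row(mean_s / config.dt, d_max, cv_i)

    level = ["upper" if r == "iti" else "lower" for r in roles]
    return StateSpace(
        state_labels=labels,
        observation_labels=list(VOCAB),
        null_symbol=NULL,
        T=T,
        O=_obs_matrix(roles),
        D=D,
        level=level,
        plastic_transition_mask=plastic,
        dwell_plastic=np.zeros(n, dtype=bool),
        meta={"kind": "hierarchical", "index": ix, "roles": roles,
              "cluster_of": cluster_of, "config": config},
    )


def _require(space: StateSpace, kind: str, what: str) -> None:
    if space.meta.get("kind") != kind:
        raise SpecificationError(f"{what} applies to a {kind} space, "
                                 f"got {space.meta.get('kind')!r}")


def block_entry_probs(space: StateSpace) -> np.ndarray:
    """Current upper-level entries T[iti, trial_start of each block]."""
    _require(space, "hierarchical", "block_entry_probs")
    ix = space.meta["index"]
    iti = ix["iti"]
    return np.array([space.T[iti, ix[f"b{b + 1}_trial_start"]] for b in range(4)])


def update_block_transitions(space: StateSpace, obs_lik_per_block: np.ndarray,
                             eta_t: float) -> np.ndarray:
    """Move the upper-level entries toward the Bayes posterior over blocks.

    ``obs_lik_per_block[n]`` is (proportional to) the probability of the
    completed trial's observation sequence under block ``n``.  The entries
    move a fraction ``eta_t`` toward ``lik * prior / evidence``; if the
    space carries a ``transition_floor`` (hippocampal lesion) the floor is
    re-imposed after every update.  Returns the updated entry vector.
    """
    _require(space, "hierarchical", "update_block_transitions")
    lik = np.asarray(obs_lik_per_block, dtype=float)
    if lik.shape != (4,) or np.any(lik < 0):
        raise ValueError("obs_lik_per_block must be 4 nonnegative likelihoods")
    if not np.any(lik > 0):
        raise ValueError("observation sequence impossible under every block")
    prior = block_entry_probs(space)
    posterior = lik * prior
    posterior /= posterior.sum()
    new = prior + eta_t * (posterior - prior)
    floor = space.meta.get("transition_floor")
    if floor is not None:
        new = np.maximum(new, floor)
    new = new / new.sum()
    ix = space.meta["index"]
    iti = ix["iti"]
    for b in range(4):
        space.T[iti, ix[f"b{b + 1}_trial_start"]] = new[b]
    return new


def _blur_cue_to_well(space: StateSpace, prefix: str, same: float,
                      other: float) -> None:
    ix = space.meta["index"]
    for cue, same_well, other_well in (
        ("left_cue", "left_well", "right_well"),
        ("right_cue", "right_well", "left_well"),
    ):
        row = space.T[ix[prefix + cue]]
        row[:] = 0.0
        row[ix[prefix + same_well]] = same
        row[ix[prefix + other_well]] = other
        row /= row.sum()


def apply_hc_lesion_flat(space: StateSpace, cue_to_same_well: float = 0.55) -> StateSpace:
    """Hippocampal lesion, flat space: cue states lead to the same-side well
    with probability 0.55 and to the opposite well with 0.45."""
    _require(space, "flat", "apply_hc_lesion_flat")
    if not 0.5 <= cue_to_same_well <= 1.0:
        raise ValueError("cue_to_same_well must be in [0.5, 1]")
    out = space.copy()
    _blur_cue_to_well(out, "", cue_to_same_well, 1.0 - cue_to_same_well)
    # the wells (and the states that follow them) can no longer be told
    # apart, so each side pair learns a single shared dwell distribution
    ix = out.meta["index"]
    out.meta["dwell_tie_groups"] = [
        (ix["left_well"], ix["right_well"]),
        (ix["left_reward1"], ix["right_reward1"]),
        (ix["left_reward2"], ix["right_reward2"]),
    ]
    out.meta["lesion"] = "hc_flat"
    return out


def apply_hc_lesion_hierarchical(space: StateSpace,
                                 transition_floor: float = 0.15) -> StateSpace:
    """Hippocampal lesion, hierarchical space: block-entry probabilities are
    floored at ``transition_floor`` now and after every learning update."""
    _require(space, "hierarchical", "apply_hc_lesion_hierarchical")
    if not 0.0 < transition_floor <= 0.25:
        raise ValueError("transition_floor must be in (0, 0.25]")
    out = space.copy()
    out.meta["transition_floor"] = transition_floor
    ix = out.meta["index"]
    iti = ix["iti"]
    entries = [ix[f"b{b + 1}_trial_start"] for b in range(4)]
    row = np.maximum(out.T[iti, entries], transition_floor)
    out.T[iti, entries] = row / row.sum()
    out.meta["lesion"] = "hc_hier"
    return out


def apply_ofc_lesion(space: StateSpace, cue_to_same_well: float = 0.55) -> StateSpace:
    """Orbitofrontal lesion (hierarchical space): within every cluster the
    cue-to-well transitions blur, the two wells share one (averaged) dwell
    row, and in the number blocks the first-reward states may transit to
    either the second-reward or the inter-trial state on both sides."""
    _require(space, "hierarchical", "apply_ofc_lesion")
    out = space.copy()
    ix = out.meta["index"]
    iti = ix["iti"]
    for b in range(4):
        p = f"b{b + 1}_"
        _blur_cue_to_well(out, p, cue_to_same_well, 1.0 - cue_to_same_well)
        lw, rw = ix[p + "left_well"], ix[p + "right_well"]
        avg = 0.5 * (out.D[lw] + out.D[rw])
        out.D[lw] = avg
        out.D[rw] = avg
        if p + "left_reward2" in ix:
            for side in ("left", "right"):
                r1, r2 = ix[p + f"{side}_reward1"], ix[p + f"{side}_reward2"]
                out.T[r1, :] = 0.0
                out.T[r1, r2] = 0.5
                out.T[r1, iti] = 0.5
    out.meta["lesion"] = "ofc"
    return out


def apply_vs_lesion(hyper: LearnerHyper) -> LearnerHyper:
    """Ventral-striatal lesion: zero the expected-dwell amplitude in the
    discount and the dwell-update kernel, so temporal expectations never
    sharpen.  Returns a new hyperparameter set."""
    from dataclasses import replace
    return replace(hyper, dwell_amplitude=0.0, kernel_amplitude=0.0)


def vs_lesion_dwell_baseline(space: StateSpace) -> StateSpace:
    """Reset dwell rows to the uniform-with-floor baseline and freeze them,
    the state a ventral-striatal-lesioned learner remains in forever."""
    out = space.copy()
    out.D = uniform_dwell(out.n_states, out.d_max, DWELL_FLOOR)
    out.dwell_plastic = np.zeros(out.n_states, dtype=bool)
    out.meta["lesion"] = "vs"
    return out
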