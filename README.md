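# hsmtd

Temporal-difference learning over a partially observable semi-Markov task
space, as a model of dopaminergic reward prediction errors — and of what
happens to them when specific brain circuits are removed.

## Who this is for

Computational and systems neuroscientists who want to simulate
reward-prediction-error signals in tasks whose states are hidden and
whose state *durations* carry information: unsignalled block structure,
delayed rewards, omissions.  The package was built around a four-block
odor-guided choice task in which reward timing and reward number change
without warning, and in which hippocampal, orbitofrontal and
ventral-striatal lesions each distort the dopamine signal in a
characteristic way.

## The model in brief

The task is a hidden semi-Markov process: entering state `s` emits one
observation from `O[s]`, the process dwells `d ~ D[s]` steps (the stream
shows a null symbol), then moves to a successor from `T[s]`.  A belief
filter tracks, exactly, the probability `β_{s,t}` of having just left
state `s` given the observations, the filtered belief `P(s_t | o_{1:t})`,
and the expected dwell `E[d_{s,t}]`.  Prediction errors are gated by the
exit posterior and discounted by the expected dwell,

    δ_{s,t} = β_{s,t} ( e^{-τ·Δt·E[d_{s,t}]} r_{t+1}
                        + e^{-τ·Δt·E[d_{s,t}]} E[V_{s_{t+1}}] - V_{s_t} ),

values are updated with the total error through a per-trial eligibility
trace `E_s = max(γ E_s, β_s)`, and dwell distributions are re-centred on
observed intervals.  Total error converts to firing as `3 + 5 δ` Hz
(positive) or `3 - 2 |δ|` Hz (negative).

Two task representations are provided: a **flat** ten-state space that
mirrors the physical trial (and must relearn values whenever a block
changes), and a **hierarchical** space with one cluster of trial states
per block plus plastic upper-level transitions `T_{ITI,b_n}` learned from
each trial's likelihood under every block — a prior over "which block am
I in".  Four lesion transforms corrupt specific pieces: blurred
cue-to-well transitions (hippocampal, flat), a floor on the block
transitions (hippocampal, hierarchical), within-block state ambiguity
(orbitofrontal), and loss of temporal expectations (ventral striatal).
See `docs/methods.md` for the full account.

## Worked example

Contrast a control and a hippocampus-lesioned flat model on the block
where an expected delayed reward becomes immediate (delivery) and an
expected immediate reward becomes delayed (omission):

```python
from hsmtd import ExperimentConfig, SessionConfig, run_experiment
from hsmtd.pipeline import event_response_curve, difference_scores

cfg = ExperimentConfig(session=SessionConfig(trials_per_block=20),
                       n_sims=4, n_sessions=6, exclude_sessions=4)
control = run_experiment("flat", "none", cfg, seeds=[0, 1, 2, 3])
lesion = run_experiment("flat", "hc", cfg, seeds=[0, 1, 2, 3])

for name, res in [("control", control), ("HC lesion", lesion)]:
    delivery = event_response_curve(res, "bolus1", block=2, condition="short")
    omission = event_response_curve(res, "omission_timing", block=2)
    scores = difference_scores(res, "bolus1")
    print(f"{name}:")
    print(f"  unexpected-reward delta, trial 1 -> last-5 mean: "
          f"{delivery.iloc[0]:.2f} -> {delivery.iloc[-5:].mean():.2f}")
    print(f"  omission delta, first-3 mean: {omission.iloc[:3].mean():.2f}")
    print(f"  delivery difference score (early - late firing, Hz): "
          f"{scores[scores.block == 2].score.mean():.2f}")
```

prints

```
control:
  unexpected-reward delta, trial 1 -> last-5 mean: 0.86 -> 0.00
  omission delta, first-3 mean: -0.52
  delivery difference score (early - late firing, Hz): 0.58
HC lesion:
  unexpected-reward delta, trial 1 -> last-5 mean: 0.49 -> 0.38
  omission delta, first-3 mean: -0.04
  delivery difference score (early - late firing, Hz): 0.47
```

The control model signals the unexpected reward strongly on the first
trial (δ = 0.86, about 7 Hz of firing above baseline) and learns it away
within the block, and it dips below baseline when the expected reward
fails to arrive (δ = −0.52).  The lesioned model, unable to retain which
well it chose, reinterprets surprising timing as being in the other well:
its omission response is nearly abolished (−0.04) and its delivery
response is weaker but persists across the block (0.49 → 0.38) — the
signature pattern this lesion is meant to produce.

There is also a command-line interface (`hsmtd generate / simulate /
lesion / analyze / fit`) writing tidy CSV plus a JSON run manifest.

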