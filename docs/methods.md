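# Methods

## The model

`hsmtd` simulates a learning agent performing an odor-guided choice task
in which reward timing and reward number change across four unsignalled
blocks of forced-choice trials.  The agent never observes its task state
directly; it observes discrete events (house light, odor cues, well
entry, reward boli, house light off) separated by stretches in which
nothing happens.  The computational problem is therefore twofold: infer
the hidden state from the event stream, and learn values that predict
reward from states it is only probabilistically sure of.

### Generative model and belief filter

The task is a hidden semi-Markov process.  Entering state `s` emits one
observation from the row `O[s]`; the process then dwells `d ~ D[s]`
steps, during which the stream carries a null symbol, and finally moves
to a successor drawn from `T[s]`.  Task events therefore *always* signal
a transition; transitions may also happen silently (the entry emission
can be null, with probability 0.05).

The filter maintains, exactly, the posterior over (state, entry-time)
pairs within the window since the last event.  From it we read off at
each step `t`:

* `alpha[s,t] = P(s_t = s, exit at t | o_1..o_t)` — the exit *prior*,
  a sum over dwell times of entry weight x dwell probability;
* `belief[s,t] = P(s_t = s | o_1..o_t)` — the same sum with the dwell
  probability replaced by the survival function `P(d >= elapsed)`
  (survival *includes* the exit mass, so `alpha <= belief` holds);
* `beta[s,t] = P(s_t = s, exit at t | o_1..o_{t+1})` — the exit
  *posterior* once the next observation is seen;
* `E[d_{s,t}]` — the expected dwell given an exit at `t` (defined as 0
  when `alpha[s,t] = 0`).

Because emission happens only on entry, the one-step predictive
distribution is `sum_s alpha[s] (T O)[s, o]` plus, for the null symbol
only, the no-transition mass `1 - sum alpha`.  Two useful consequences:
the predictive distribution sums to one over the vocabulary, and on any
non-null observation the exit posterior sums to exactly one — an event
*implies* a transition, which is the modelling assumption rather than a
hard-coded override.  The filter is the exact Bayes filter of this
generative model, which is what lets us validate it to ~1e-14 against
brute-force trajectory enumeration (`tests/enum_oracle.py`).

With all dwells a point mass at one step, every step is an entry and the
recursion collapses to the standard HMM forward filter; this limit is
checked against an independently coded forward recursion.

### Belief-gated TD learning

When observation `o_{t+1}` arrives, each state's prediction error is
gated by its exit posterior:

    delta[s] = beta[s] * ( g_s * r_{t+1} + g_s * E[V_succ | s] - V[s] )
    g_s      = exp( -tau * dt * E[d_{s,t}] )

with the successor value averaged over `T[s,:] * O[:,o_{t+1}]`.  The
total error `sum_s delta[s]` updates every state through an eligibility
trace `E = max(gamma_step * E, beta)`, reset at trial start, and is
converted to a firing rate of `3 + 5*delta` Hz for positive and
`3 - 2*|delta|` Hz for negative errors (clipped at zero) — the
asymmetry reflects the weaker representation of negative errors in
recorded dopamine neurons.

On every event the exiting states' dwell rows move toward a discretized
Gaussian kernel centred on the elapsed interval (sd = CV x elapsed),
gated by `beta`, floored at 1e-4 and renormalized.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `dt` | 0.1 | s | step size; resolves the 0.5 s bolus gap |
| `tau` | 0.05 | 1/s | discount rate on expected dwell |
| `eta_r` | 0.5 | – | value learning rate |
| `gamma` | 0.95 | per second | eligibility decay (per-step factor `gamma**dt`) |
| `eta_d` | 0.3 | – | dwell learning rate |
| `cv_d` | 0.05 | – | dwell kernel coefficient of variation |
| `D_b` | 1e-4 | – | dwell probability floor |
| `eta_t` | 0.3 | – | block-transition learning rate (hierarchical) |
| baseline / k+ / k- | 3 / 5 / 2 | Hz | firing conversion |
| `d_max` | 150 | steps | dwell horizon (15 s; longest delay is 7 s) |

Two unit choices deserve note, since the literature value 0.95 for the
trace decay and 0.05 for the discount rate come without a step size.
Both are treated as *per-second* rates and scaled by `dt`, so that credit
propagation and discounting span the same real time at any
discretization.  The elementary update operations themselves take
per-step factors (so a hand trace with `gamma = 0.95` behaves as
written); only the hyperparameter units are per-second.  A literal
per-0.1-s-step decay of 0.95 would confine credit to ~0.2 of an error
over the 3 s separating cue and reward and make within-block value
adaptation far slower than the modelled firing patterns show.

The discount uses the *negative* exponent (true discounting).  A
positive exponent, which makes delayed rewards more valuable, is
available behind `discount_sign=+1` for comparison.

### Task spaces

The **flat** space has ten states — trial start, left/right cue,
left/right well, left/right first and second reward, inter-trial
interval — with fixed transitions (cue to same-side well at `1 - 1e-4`),
shared `well_entry` and `reward` symbols (so wells and reward states are
mutually ambiguous), and *learned* dwell rows starting from a uniform
baseline.

The **hierarchical** space clones the trial states into four block
clusters over one shared inter-trial state.  Only the upper-level
entries `T[ITI, b_n]` are plastic: after every trial the four clusters'
likelihoods of the trial's observation sequence are computed (one filter
pass over four disjoint cluster copies; the terminal cluster masses are
the likelihoods up to a common factor) and the entries move a fraction
`eta_t` toward the Bayes posterior.  Lower-level dwell rows are fixed
Gaussians on the mean event timings; the long-delay well's row takes its
spread from the titrated delay sequence the task actually produces
(1, 2, ..., 7 s), because a CV-0.05 row centred on the mean would assign
floor probability to most early-block delays and stall block inference.

### Lesions

* **Hippocampal, flat**: cue-to-well transitions blurred to 0.55 / 0.45.
  The wells — and the reward states that follow them — can then no
  longer be told apart, so each side pair learns one shared dwell row
  (updated with the pair's summed exit posterior).  Without this tie the
  two rows diverge through a rich-get-richer loop and the filter
  re-identifies the well from timing alone, undoing the lesion.
* **Hippocampal, hierarchical**: block entries floored at 0.15 after
  every update (then renormalized), leaving residual uncertainty about
  the current block.
* **Orbitofrontal** (hierarchical): cue-to-well blurring in every
  cluster, identical (averaged) well dwell rows, and first-reward states
  allowed to transit to either the second-reward or inter-trial state in
  the number blocks on both sides.
* **Ventral striatal**: the dwell-update kernel amplitude is zero (dwell
  rows stay at the uniform baseline forever) and the expected dwell
  loses its modulation of the discount — the exponent interpolates to a
  fixed state-independent baseline dwell (the uniform distribution's
  mean, 75.5 steps).  Removing the discount altogether would leave the
  continuing task's value recursion without a fixed point (values drift
  upward and every delivery carries a spurious positive error); pinning
  the discount at a timing-blind constant removes the temporal
  information, which is the lesion's point, while values converge.

## Synthetic task generator

The generator emulates the four-block session: block 1 short/long
delays, block 2 reversed, block 3 big/small reward number, block 4
reversed.  Defaults: 60 forced trials per block (equal sides,
pseudorandom order with at most 3 consecutive repeats), light-to-odor
0.5 s, odor-to-well 1.0 s, short delay 0.5 s, long delay titrated from
1 s in 1 s increments to 7 s, bolus gap 0.5 s, light-off 1 s after the
last bolus, inter-trial interval 4 s, `dt` 0.1 s.  The titration
demotion rule (fewer than 8 of the last 10 long-side choices drops the
delay by 1 s, floor 3 s) is implemented but inactive, since free-choice
trials are not simulated and the modelled agent always collects the
reward.  Omissions are encoded as the absence of the reward symbol at
the previously scheduled time; the generator annotates those expected
times for alignment.  Block boundaries carry no distinguishing
observation.

What the generator does **not** emulate: free-choice trials and choice
behavior, reaction-time variability, within-session drifts in timing or
motivation, and counterbalancing of the side-to-contingency assignment
across sessions (left is always well 1).  Passing tests therefore show
that the inference/learning machinery produces the documented
contrast patterns under idealized task statistics — not that it fits any
particular recorded animal.

## Fitting stage

Per-event spike counts (Poisson, 400 ms windows, optionally pooled over
identical units) are fit by maximizing the Poisson likelihood of the
model's predicted event rates over three free parameters per model —
flat: value learning rate, dwell learning rate, lesion cue-to-well
probability; hierarchical: value learning rate, block-transition
learning rate, lesion transition floor.  Predictions are deterministic
given the task seeds (common random numbers), so the objective is smooth
and a seeded multi-start Nelder–Mead within bounds suffices (library
default 16 starts; the validation protocol uses 2 starts with at most 80
evaluations).  Fitting uses a reduced protocol (1 simulation x 2
sessions x 16-trial blocks, no burn-in exclusion) because the learning
dynamics themselves identify the learning rates.  Model comparison uses
the likelihood-ratio statistic `2 (logL_hier - logL_flat)`; the two
models have equal parameter counts and are not nested, so the chi-square
p-value is heuristic and the statistic's sign/size is what the
model-recovery check asserts.

## Validation protocol and problem sizes

The full study conditions — 20 simulations x 30 sessions x 60-trial
blocks, first 10 sessions excluded — are the defaults.  The test suite
and `scripts/acceptance.py` run a scaled protocol chosen once: 20
simulations x 8 sessions x 20-trial blocks with the first 5 sessions
excluded (matched seeds across conditions), and the reduced fitting
protocol above with 100 pooled units and 20 noise replicates for model
recovery.  All contrasts asserted by the acceptance tests are scale-
robust in our exploration except one, documented below.

## Numerical choices

* Probabilities are floored at 1e-300 before division; the filter raises
  a degeneracy error rather than returning NaNs on impossible streams.
* The dwell window truncates at `d_max` with a single logged warning;
  task gaps never exceed ~70 steps against the 150-step horizon.
* Exit posteriors are clipped into [0, 1] only to absorb <=1e-12
  floating-point slop.
* Event responses are summed prediction errors over a 5-step (500 ms)
  window from the event (omissions: from one step before the expected
  time); firing responses are window means.  The window matches the
  400-ms analysis epoch used for spike counts at the 0.1 s step size.
* Belief is initialized as a point mass on the inter-trial state, and
  every session begins with a full inter-trial interval.

## Known limitations

* The late-trial cue-value contrast under the hierarchical hippocampal
  lesion preserves the control's sign but reaches only ~0.35–0.5 of the
  control's magnitude.  This is structural: the 0.15 floor's fixed point
  puts ~0.62 of the prior on the correct block and ~0.13 on each wrong
  one, and two of the three wrong clusters carry sign-reversed cue
  contrasts.  A "preserved to at least half of control" reading is
  therefore borderline at any problem size.
* Values include the full continuing value of future trials (the task
  never ends), so absolute state values sit well above single-trial
  reward magnitudes; all analyses use event-locked error responses,
  which are insensitive to this offset.
* The enumeration oracle and filter share the truncation-at-`d_max`
  convention; dwell distributions with mass beyond the horizon are
  renormalized implicitly.
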