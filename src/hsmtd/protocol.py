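"""Reference simulation protocol and summary metrics.

The full study conditions (20 simulations of 30 sessions with 60-trial
blocks, first 10 sessions excluded) are the generator and experiment
defaults.  For routine validation this module provides a scaled protocol
-- 20 simulations of 8 sessions with 20-trial blocks, first 5 sessions
excluded -- that preserves every qualitative contrast while fitting a
single-CPU budget, together with the summary metrics used to compare
control and lesioned models: per-trial event response curves, early-trial
means, early/late difference scores, and late-trial cue-value contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .generate import SessionConfig
from .learning import LearnerHyper
from .pipeline import (ExperimentConfig, ExperimentResult,
                       cue_value_difference, difference_scores,
                       event_response_curve, run_experiment)

__all__ = [
    "scaled_config", "fit_config", "run_conditions", "early_mean",
    "per_sim_early_mean", "second_bolus_first_trials", "late_cue_ratio",
    "CONDITIONS",
]

#: model/lesion conditions exercised by the lesion-contrast analyses
CONDITIONS = [("flat", "none"), ("flat", "hc"),
              ("hier", "none"), ("hier", "hc"),
              ("hier", "ofc"), ("hier", "vs")]


def scaled_config(trials_per_block: int = 20, n_sims: int = 20,
                  n_sessions: int = 8, exclude_sessions: int = 5) -> ExperimentConfig:
    """The scaled validation protocol (defaults as described above)."""
    return ExperimentConfig(
        session=SessionConfig(trials_per_block=trials_per_block),
        hyper=LearnerHyper(),
        n_sims=n_sims, n_sessions=n_sessions,
        exclude_sessions=exclude_sessions)


def fit_config(trials_per_block: int = 16) -> ExperimentConfig:
    """Reduced protocol for the fitting stage: a single simulation of two
    sessions with no burn-in exclusion (learning-rate parameters are
    identified by the learning dynamics themselves)."""
    return ExperimentConfig(
        session=SessionConfig(trials_per_block=trials_per_block),
        hyper=LearnerHyper(), n_sims=1, n_sessions=2, exclude_sessions=0)


def run_conditions(config: ExperimentConfig, seeds,
                   conditions=CONDITIONS) -> dict[tuple, ExperimentResult]:
    """Run all requested model/lesion conditions on matched seeds."""
    return {(mk, lk): run_experiment(mk, lk, config, seeds=list(seeds))
            for mk, lk in conditions}


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------

def early_mean(result: ExperimentResult, event: str, block: int,
               n: int = 5, condition: str | None = None,
               measure: str = "delta") -> float:
    """Mean response over the first ``n`` trials of a block."""
    curve = event_response_curve(result, event, block, condition=condition,
                                 measure=measure)
    return float(curve.iloc[:n].mean())


def per_sim_early_mean(result: ExperimentResult, event: str, blocks,
                       n: int = 5, condition: str | None = None,
                       measure: str = "delta") -> pd.Series:
    """Per-simulation mean response over the first ``n`` event trials of
    the given block(s); the unit of the sign tests."""
    ev = result.analysis_events()
    sel = ev[(ev.event == event) & (ev.block.isin(np.atleast_1d(blocks)))]
    if condition is not None:
        sel = sel[sel.condition == condition]
    sel = (sel.sort_values("trial_in_block")
              .groupby(["sim", "session", "block"]).head(n))
    return sel.groupby("sim")[measure].mean()


def second_bolus_first_trials(result: ExperimentResult, n: int = 5) -> pd.Series:
    """Per-simulation mean response to the second reward bolus over the
    first ``n`` big-side trials of the first two-bolus block."""
    return per_sim_early_mean(result, "bolus2", blocks=3, n=n)


def late_cue_ratio(lesion: ExperimentResult, control: ExperimentResult,
                   blocks=(2, 4), n: int = 5) -> tuple[float, float, float]:
    """Late-trial high-minus-low cue contrast for lesion and control,
    pooled over blocks; returns (lesion, control, lesion/control)."""
    les = ctl = 0.0
    for b in blocks:
        les += float(cue_value_difference(lesion, b).iloc[-n:].mean())
        ctl += float(cue_value_difference(control, b).iloc[-n:].mean())
    return les, ctl, les / ctl


def attenuation_table(control: ExperimentResult,
                      lesion: ExperimentResult) -> pd.DataFrame:
    """Early/late difference scores for the reward-related events, control
    versus lesion (the learning-related-change comparison)."""
    rows = []
    for event, block in [("bolus1", 2), ("omission_timing", 2),
                         ("omission_bolus2", 4), ("bolus2", 4)]:
        for name, res in [("control", control), ("lesion", lesion)]:
            ds = difference_scores(res, event)
            ds = ds[ds.block == block]
            rows.append({"event": event, "block": block, "group": name,
                         "score": ds.score.mean()})
    return pd.DataFrame(rows)
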