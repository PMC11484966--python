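"""Hidden semi-Markov state spaces.

A :class:`StateSpace` bundles everything the belief filter needs to know
about a task: the hidden states, the transition matrix ``T`` (``T[s, s']``
is the probability that ``s'`` follows ``s``), the observation matrix ``O``
(``O[s, o]`` is the probability that entering state ``s`` emits symbol
``o``), and the per-state dwell-time distributions ``D`` (``D[s, d-1]`` is
the probability of remaining in ``s`` for exactly ``d`` discrete steps).

Observations are emitted once, on entry into a state; while the process
dwells in a state the stream carries the designated null symbol.  Task
events are therefore unambiguous evidence that a transition has just
occurred, while stretches of null observations leave the transition time
hidden and force the filter to reason over dwell times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "StateSpace",
    "normalize_observation_rows",
    "uniform_dwell",
    "gaussian_dwell_row",
]

#: probability floor for dwell distributions (kept non-vanishing at all d)
DWELL_FLOOR = 1e-4

_ROW_TOL = 1e-12


class SpecificationError(ValueError):
    """Raised when a state-space specification is internally inconsistent."""


def normalize_observation_rows(raw_O: np.ndarray, state_labels=None) -> np.ndarray:
    """Normalize each row of a raw observation-weight matrix onto the simplex.

    Raw weights are the scheme used throughout: the characteristic symbol of
    a state carries weight 0.95, the null symbol 0.05, and every other
    symbol a background 1e-4; dividing by the row sum yields proper
    emission probabilities.

    Raises
    ------
    SpecificationError
        If any entry is negative or a row sums to zero; the message names
        the offending state.
    """
    raw_O = np.asarray(raw_O, dtype=float)
    for i, row in enumerate(raw_O):
        name = state_labels[i] if state_labels is not None else f"state {i}"
        if np.any(row < 0):
            raise SpecificationError(f"negative observation weight for {name!r}")
        s = row.sum()
        if s <= 0:
            raise SpecificationError(f"observation weights for {name!r} sum to zero")
    return raw_O / raw_O.sum(axis=1, keepdims=True)


def uniform_dwell(n_states: int, d_max: int, floor: float = DWELL_FLOOR) -> np.ndarray:
    """Uniform-with-floor dwell matrix, the maximally uncertain baseline."""
    D = np.full((n_states, d_max), 1.0 / d_max)
    D = np.maximum(D, floor)
    return D / D.sum(axis=1, keepdims=True)


def gaussian_dwell_row(mean_steps: float, d_max: int, cv: float = 0.05,
                       floor: float = DWELL_FLOOR) -> np.ndarray:
    """Discretized Gaussian dwell distribution centred on ``mean_steps``.

    The standard deviation is ``cv * mean_steps`` (coefficient of variation
    parameterization); the density is sampled at integer dwell times
    1..d_max, floored at ``floor`` and renormalized.  Degenerate widths
    collapse to a point mass on the nearest integer.
    """
    d = np.arange(1, d_max + 1, dtype=float)
    sd = max(cv * mean_steps, 1e-9)
    k = np.exp(-0.5 * ((d - mean_steps) / sd) ** 2)
    if k.sum() <= 0:
        k = np.zeros(d_max)
        k[int(np.clip(round(mean_steps), 1, d_max)) - 1] = 1.0
    k = k / k.sum()
    k = np.maximum(k, floor)
    return k / k.sum()


@dataclass
class StateSpace:
    """A partially observable semi-Markov task description.

    Invariants (checked on construction): every row of ``T``, ``O`` and
    ``D`` lies on the probability simplex, and exactly one observation
    symbol is designated null.
    """

    state_labels: list[str]
    observation_labels: list[str]
    null_symbol: str
    T: np.ndarray
    O: np.ndarray
    D: np.ndarray
    level: list[str] | None = None          # per-state 'lower' / 'upper'
    plastic_transition_mask: np.ndarray | None = None
    dwell_plastic: np.ndarray | None = None  # per-state bool: dwell row learned?
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.ascontiguousarray(self.T, dtype=float)
        self.O = np.ascontiguousarray(self.O, dtype=float)
        self.D = np.ascontiguousarray(self.D, dtype=float)
        n, m = len(self.state_labels), len(self.observation_labels)
        if self.T.shape != (n, n):
            raise SpecificationError(f"T has shape {self.T.shape}, expected {(n, n)}")
        if self.O.shape != (n, m):
            raise SpecificationError(f"O has shape {self.O.shape}, expected ({n}, {m})")
        if self.D.ndim != 2 or self.D.shape[0] != n:
            raise SpecificationError("D must be (n_states, d_max)")
        for name, mat in (("T", self.T), ("O", self.O), ("D", self.D)):
            if np.any(mat < 0):
                raise SpecificationError(f"negative entries in {name}")
            err = np.abs(mat.sum(axis=1) - 1.0).max()
            if err > _ROW_TOL * max(1, mat.shape[1]):
                raise SpecificationError(f"rows of {name} off the simplex (max err {err:.2e})")
        if self.observation_labels.count(self.null_symbol) != 1:
            raise SpecificationError(f"null symbol {self.null_symbol!r} must appear exactly once")
        if self.level is None:
            self.level = ["lower"] * n
        if self.plastic_transition_mask is None:
            self.plastic_transition_mask = np.zeros((n, n), dtype=bool)
        else:
            self.plastic_transition_mask = np.asarray(self.plastic_transition_mask, dtype=bool)
        if self.dwell_plastic is None:
            self.dwell_plastic = np.ones(n, dtype=bool)
        else:
            self.dwell_plastic = np.asarray(self.dwell_plastic, dtype=bool)

    # -- basic introspection -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_obs(self) -> int:
        return len(self.observation_labels)

    @property
    def d_max(self) -> int:
        return self.D.shape[1]

    @property
    def null_index(self) -> int:
        return self.observation_labels.index(self.null_symbol)

    def state_index(self, label: str) -> int:
        try:
            return self.state_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state {label!r}; states are {self.state_labels}") from None

    def obs_index(self, symbol: str) -> int:
        try:
            return self.observation_labels.index(symbol)
        except ValueError:
            raise KeyError(
                f"unknown observation {symbol!r}; vocabulary is {self.observation_labels}"
            ) from None

    def copy(self) -> "StateSpace":
        return replace(
            self,
            T=self.T.copy(),
            O=self.O.copy(),
            D=self.D.copy(),
            level=list(self.level),
            plastic_transition_mask=self.plastic_transition_mask.copy(),
            dwell_plastic=self.dwell_plastic.copy(),
            meta=dict(self.meta),
        )

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "states": list(self.state_labels),
            "observations": list(self.observation_labels),
            "null_symbol": self.null_symbol,
            "T": self.T.tolist(),
            "O": self.O.tolist(),
            "D": self.D.tolist(),
            "level": list(self.level),
            "plastic_mask": self.plastic_transition_mask.astype(int).tolist(),
            "dwell_plastic": self.dwell_plastic.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StateSpace":
        O = np.asarray(d.get("O", d.get("O_raw")), dtype=float)
        if "O_raw" in d and "O" not in d:
            O = normalize_observation_rows(O, d["states"])
        return cls(
            state_labels=list(d["states"]),
            observation_labels=list(d["observations"]),
            null_symbol=d["null_symbol"],
            T=np.asarray(d["T"], dtype=float),
            O=O,
            D=np.asarray(d.get("D", d.get("D_init")), dtype=float),
            level=list(d["level"]) if "level" in d else None,
            plastic_transition_mask=(
                np.asarray(d["plastic_mask"], dtype=bool) if "plastic_mask" in d else None
            ),
            dwell_plastic=(
                np.asarray(d["dwell_plastic"], dtype=bool) if "dwell_plastic" in d else None
            ),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "StateSpace":
        path = Path(path)
        text = path.read_text()
        payload = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(payload)
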