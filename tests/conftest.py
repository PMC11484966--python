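import numpy as np
import pytest

from hsmtd.spaces import StateSpace


@pytest.fixture
def two_state_chain():
    """Deterministic A -> B -> A cycle, unambiguous symbols, dwell 1."""
    return StateSpace(
        state_labels=["A", "B"],
        observation_labels=["a", "b", "null"],
        null_symbol="null",
        T=np.array([[0.0, 1.0], [1.0, 0.0]]),
        O=np.array([[0.95, 0.0, 0.05], [0.0, 0.95, 0.05]]) / 1.0,
        D=np.array([[1.0], [1.0]]),
    )


@pytest.fixture
def single_state_space():
    """One self-transitioning state with the task's characteristic
    0.95 / 0.05 / 1e-4 emission scheme over 7 symbols."""
    from hsmtd.spaces import normalize_observation_rows
    raw = np.full((1, 7), 1e-4)
    raw[0, 0] = 0.95
    raw[0, 6] = 0.05
    return StateSpace(
        state_labels=["s"],
        observation_labels=[f"o{i}" for i in range(6)] + ["null"],
        null_symbol="null",
        T=np.array([[1.0]]),
        O=normalize_observation_rows(raw),
        D=np.array([[1.0]]),
    )
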