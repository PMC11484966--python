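"""Belief-filter correctness: hand-calculable cases, the Markov limit,
and exhaustive-enumeration equivalence on random small processes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enum_oracle import oracle_posteriors
from hsmtd.filtering import BeliefFilter, NumericalDegeneracyError, run_filter
from hsmtd.generate import make_fixture_hsmm
from hsmtd.spaces import StateSpace


def test_forced_transition_concentrates_alpha(two_state_chain):
    # dwell is exactly 1 in A, so one step after A's symbol the process
    # must be exiting A
    filt = BeliefFilter(two_state_chain, prior=np.array([1.0, 0.0]))
    filt.begin("a")
    assert filt.alpha[0] == pytest.approx(1.0, abs=1e-12)
    assert filt.alpha[1] == pytest.approx(0.0, abs=1e-12)


def test_beta_is_one_on_forced_exit(two_state_chain):
    filt = BeliefFilter(two_state_chain, prior=np.array([1.0, 0.0]))
    filt.begin("a")
    res = filt.advance("b")   # B's unambiguous symbol: A must have exited
    assert res.beta[0] == pytest.approx(1.0, abs=1e-9)
    assert res.beta.sum() == pytest.approx(1.0, abs=1e-12)


def test_beta_vanishes_without_hazard():
    # dwell is at least 2, so no exit can have happened after one step
    space = StateSpace(
        state_labels=["A", "B"],
        observation_labels=["a", "b", "null"], null_symbol="null",
        T=np.array([[0.0, 1.0], [1.0, 0.0]]),
        O=np.array([[0.9, 0.0, 0.1], [0.0, 0.9, 0.1]]),
        D=np.array([[0.0, 1.0], [0.0, 1.0]]),
    )
    filt = BeliefFilter(space, prior=np.array([1.0, 0.0]))
    filt.begin("a")
    res = filt.advance("null")
    assert res.beta.max() == pytest.approx(0.0, abs=1e-12)


def test_alpha_equals_renormalized_hazard_during_null_stretch():
    # single state entered at t=0; after k nulls the exit probability is
    # the dwell hazard D[k+1] / P(d >= k+1)
    D = np.array([[0.2, 0.3, 0.4, 0.1]])
    space = StateSpace(
        state_labels=["s"], observation_labels=["x", "null"],
        null_symbol="null", T=np.array([[1.0]]),
        O=np.array([[1.0, 0.0]]), D=D,   # entries always announce themselves
    )
    filt = BeliefFilter(space, prior=np.array([1.0]))
    filt.begin("x")
    assert filt.alpha[0] == pytest.approx(0.2, abs=1e-12)
    filt.advance("null")
    assert filt.alpha[0] == pytest.approx(0.3 / 0.8, abs=1e-12)
    filt.advance("null")
    assert filt.alpha[0] == pytest.approx(0.4 / 0.5, abs=1e-12)


def test_one_state_predictive_likelihood(single_state_space):
    # the single state re-enters itself every step (dwell 1), so the next
    # symbol's probability is its emission probability 0.95 / 1.0005
    filt = BeliefFilter(single_state_space, prior=np.array([1.0]))
    filt.begin("o0")
    assert filt.predictive_obs_likelihood("o0") == pytest.approx(
        0.95 / 1.0005, abs=1e-12)


def test_predictive_distribution_sums_to_one():
    from hsmtd.task import build_flat_model
    space = build_flat_model()
    prior = np.zeros(space.n_states)
    prior[space.state_index("iti")] = 1.0
    filt = BeliefFilter(space, prior=prior)
    filt.begin("light_off")
    for sym in ["null", "null", "light_on", "odor_left", "null"]:
        filt.advance(sym)
        p = filt.predictive_distribution()
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert p.min() > 0


def test_uniform_belief_is_invariant_under_symmetry():
    space = StateSpace(
        state_labels=["L", "R"],
        observation_labels=["x", "null"], null_symbol="null",
        T=np.array([[0.0, 1.0], [1.0, 0.0]]),
        O=np.array([[0.5, 0.5], [0.5, 0.5]]),
        D=np.array([[0.5, 0.5], [0.5, 0.5]]),
    )
    filt = BeliefFilter(space, prior=np.array([0.5, 0.5]))
    filt.begin("null")
    for _ in range(4):
        res = filt.advance("null")
    assert np.allclose(res.belief, [0.5, 0.5], atol=1e-12)


def test_expected_dwell_point_mass_and_uniform():
    # deterministic 3-step dwell: E[d] = 3 at exit; uniform over {1, 2}
    # with equal posterior weight: E[d] = 1.5
    space = StateSpace(
        state_labels=["s"], observation_labels=["x", "null"],
        null_symbol="null", T=np.array([[1.0]]),
        O=np.array([[0.9, 0.1]]),
        D=np.array([[0.0, 0.0, 1.0]]),
    )
    filt = BeliefFilter(space, prior=np.array([1.0]))
    filt.begin("x")
    filt.advance("null")
    filt.advance("null")
    assert filt.alpha[0] == pytest.approx(1.0, abs=1e-12)
    assert filt.exp_dwell[0] == pytest.approx(3.0, abs=1e-12)

    space2 = StateSpace(
        state_labels=["s"], observation_labels=["x", "null"],
        null_symbol="null", T=np.array([[1.0]]),
        O=np.array([[0.5, 0.5]]),
        D=np.array([[0.5, 0.5]]),
    )
    filt2 = BeliefFilter(space2, prior=np.array([1.0]))
    filt2.begin("x")
    res = filt2.advance("x")
    # exits with dwell 1 (entry at t=1) or dwell 2 (entry at t=0), equal mass
    assert res.belief[0] == pytest.approx(1.0, abs=1e-12)
    filt2.advance("null")
    ed = filt2.exp_dwell[0]
    assert 1.0 <= ed <= 2.0


def test_expected_dwell_zero_when_alpha_zero():
    space = StateSpace(
        state_labels=["s"], observation_labels=["x", "null"],
        null_symbol="null", T=np.array([[1.0]]),
        O=np.array([[0.9, 0.1]]),
        D=np.array([[0.0, 1.0]]),
    )
    filt = BeliefFilter(space, prior=np.array([1.0]))
    filt.begin("x")
    assert filt.alpha[0] == 0.0
    assert filt.exp_dwell[0] == 0.0


def _hmm_forward(T, O, prior, codes):
    """Plainly-coded HMM filter: the d=1 point-mass limit reference."""
    f = prior * O[:, codes[0]]
    f /= f.sum()
    out = [f]
    for o in codes[1:]:
        f = O[:, o] * (T.T @ f)
        f /= f.sum()
        out.append(f)
    return np.array(out)


def test_markov_limit_matches_hmm_forward_filter():
    rng = np.random.default_rng(11)
    for _ in range(10):
        n, m = 3, 4
        T = rng.dirichlet(np.ones(n), n)
        O = rng.dirichlet(np.ones(m), n)
        space = StateSpace(
            state_labels=[f"s{i}" for i in range(n)],
            observation_labels=[f"o{i}" for i in range(m - 1)] + ["null"],
            null_symbol="null", T=T, O=O,
            D=np.tile([1.0], (n, 1)),   # point mass at d = 1
        )
        codes = rng.integers(0, m, size=10)
        prior = np.full(n, 1 / n)
        _, trace = run_filter(space, codes, prior=prior)
        ref = _hmm_forward(T, O, prior, codes)
        assert np.abs(np.array(trace.belief) - ref).max() < 1e-10
        # with certain exit every step, alpha coincides with the belief
        assert np.abs(np.array(trace.alpha) - ref).max() < 1e-10


def test_permutation_equivariance():
    space, codes, _ = make_fixture_hsmm(n_states=3, dwell_max=3, seed=5, length=7)
    prior = np.array([0.5, 0.3, 0.2])
    perm = np.array([2, 0, 1])
    inv = np.argsort(perm)
    permuted = StateSpace(
        state_labels=[space.state_labels[i] for i in perm],
        observation_labels=space.observation_labels,
        null_symbol=space.null_symbol,
        T=space.T[np.ix_(perm, perm)], O=space.O[perm], D=space.D[perm],
    )
    _, tr1 = run_filter(space, codes, prior=prior)
    _, tr2 = run_filter(permuted, codes, prior=prior[perm])
    for t in range(len(codes)):
        assert np.allclose(tr1.belief[t], tr2.belief[t][inv], atol=1e-12)
        assert np.allclose(tr1.alpha[t], tr2.alpha[t][inv], atol=1e-12)


def test_oracle_equivalence_sample():
    """Spot-check against exhaustive trajectory enumeration (the full
    100-instance battery runs in the acceptance suite)."""
    for seed in range(8):
        space, codes, _ = make_fixture_hsmm(n_states=3, dwell_max=3,
                                            seed=seed, length=7)
        prior = np.full(3, 1 / 3)
        _, trace = run_filter(space, codes, prior=prior)
        orc = oracle_posteriors(space, codes, prior=prior)
        assert np.abs(np.array(trace.alpha) - orc["alpha"]).max() < 1e-10
        assert np.abs(np.array(trace.belief) - orc["belief"]).max() < 1e-10
        n_beta = len(trace.beta)
        assert np.abs(np.array(trace.beta) - orc["beta"][:n_beta]).max() < 1e-10


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_filter_invariants_on_random_processes(seed):
    """Beliefs stay on the simplex, exit posteriors in [0, 1], and the exit
    prior never exceeds the occupancy posterior."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 5))
    space, codes, _ = make_fixture_hsmm(
        n_states=n, dwell_max=int(rng.integers(2, 5)), seed=seed, length=8)
    filt = BeliefFilter(space, prior=np.full(n, 1 / n))
    filt.begin(int(codes[0]))
    for o in codes[1:]:
        res = filt.advance(int(o))
        assert res.belief.sum() == pytest.approx(1.0, abs=1e-10)
        assert res.beta.min() >= 0.0 and res.beta.max() <= 1.0
        assert np.all(res.alpha <= res.belief + 1e-12)
        assert filt.predictive_distribution().sum() == pytest.approx(1.0, abs=1e-10)


def test_window_truncation_warns_once(caplog):
    space, _, _ = make_fixture_hsmm(n_states=2, dwell_max=2, seed=0, length=4)
    filt = BeliefFilter(space, prior=np.array([0.5, 0.5]))
    with caplog.at_level("WARNING", logger="hsmtd.filtering"):
        filt.begin(space.null_index)
        for _ in range(6):
            filt.advance(space.null_index)
    msgs = [r for r in caplog.records if "d_max" in r.message]
    assert len(msgs) == 1


def test_impossible_stream_raises_degeneracy():
    space = StateSpace(
        state_labels=["s"], observation_labels=["x", "y", "null"],
        null_symbol="null", T=np.array([[1.0]]),
        O=np.array([[1.0, 0.0, 0.0]]),   # never emits y or null
        D=np.array([[1.0]]),
    )
    filt = BeliefFilter(space, prior=np.array([1.0]))
    filt.begin("x")
    with pytest.raises(NumericalDegeneracyError):
        filt.advance("y")
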