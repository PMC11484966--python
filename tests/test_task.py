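"""Task state spaces and lesion transforms."""

import numpy as np
import pytest

from hsmtd.generate import SessionConfig, VOCAB
from hsmtd.learning import LearnerHyper
from hsmtd.spaces import SpecificationError
from hsmtd.task import (apply_hc_lesion_flat, apply_hc_lesion_hierarchical,
                        apply_ofc_lesion, apply_vs_lesion, block_entry_probs,
                        build_flat_model, build_hierarchical_model,
                        update_block_transitions, vs_lesion_dwell_baseline)


@pytest.fixture(scope="module")
def flat():
    return build_flat_model()


@pytest.fixture(scope="module")
def hier():
    return build_hierarchical_model(SessionConfig(trials_per_block=20))


class TestFlatModel:
    def test_ten_states_and_task_vocabulary(self, flat):
        assert flat.n_states == 10
        assert flat.observation_labels == VOCAB
        assert flat.null_symbol == "null"

    def test_rows_on_simplex(self, flat):
        for mat in (flat.T, flat.O, flat.D):
            assert np.abs(mat.sum(axis=1) - 1.0).max() < 1e-12

    def test_characteristic_emissions(self, flat):
        # each state emits its own event with 0.95 / 1.0005
        i = flat.state_index("left_cue")
        assert flat.O[i, flat.obs_index("odor_left")] == pytest.approx(0.95 / 1.0005)
        assert flat.O[i, flat.null_index] == pytest.approx(0.05 / 1.0005)

    def test_all_dwell_rows_plastic(self, flat):
        assert flat.dwell_plastic.all()


class TestFlatHCLesion:
    def test_cue_rows_blurred_to_55_45(self, flat):
        les = apply_hc_lesion_flat(flat)
        lc = les.state_index("left_cue")
        assert les.T[lc, les.state_index("left_well")] == pytest.approx(0.55)
        assert les.T[lc, les.state_index("right_well")] == pytest.approx(0.45)
        rc = les.state_index("right_cue")
        assert les.T[rc, les.state_index("right_well")] == pytest.approx(0.55)

    def test_unrelated_rows_bit_identical(self, flat):
        les = apply_hc_lesion_flat(flat)
        cue_rows = [flat.state_index("left_cue"), flat.state_index("right_cue")]
        keep = [i for i in range(flat.n_states) if i not in cue_rows]
        assert np.array_equal(les.T[keep], flat.T[keep])
        assert np.array_equal(les.O, flat.O)

    def test_idempotent(self, flat):
        once = apply_hc_lesion_flat(flat)
        twice = apply_hc_lesion_flat(once)
        assert np.array_equal(once.T, twice.T)

    def test_rejects_hierarchical_space(self, hier):
        with pytest.raises(SpecificationError, match="flat"):
            apply_hc_lesion_flat(hier)


class TestHierarchicalModel:
    def test_plastic_mask_marks_only_upper_entries(self, hier):
        iti = hier.state_index("iti")
        mask = hier.plastic_transition_mask
        assert mask[iti].sum() == 4
        assert mask.sum() == 4
        assert hier.level[iti] == "upper"

    def test_block_entries_uniform_and_normalized(self, hier):
        p = block_entry_probs(hier)
        assert np.allclose(p, 0.25)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_lower_level_dwell_rows_fixed(self, hier):
        assert not hier.dwell_plastic.any()

    def test_short_well_dwell_centred_on_short_delay(self, hier):
        cfg = hier.meta["config"]
        i = hier.state_index("b1_left_well")   # left is short in block 1
        assert hier.D[i].argmax() == cfg.steps(cfg.short_delay) - 1


class TestBlockTransitionLearning:
    def test_equal_likelihoods_are_a_fixed_point(self, hier):
        space = hier.copy()
        new = update_block_transitions(space, np.ones(4), eta_t=0.3)
        assert np.allclose(new, 0.25, atol=1e-12)

    def test_full_learning_rate_reaches_bayes_posterior(self, hier):
        space = hier.copy()
        lik = np.array([0.8, 0.1, 0.05, 0.05])
        new = update_block_transitions(space, lik, eta_t=1.0)
        assert np.allclose(new, lik * 0.25 / (lik * 0.25).sum(), atol=1e-12)

    def test_partial_step_is_convex_combination(self, hier):
        space = hier.copy()
        lik = np.array([0.8, 0.1, 0.05, 0.05])
        post = lik * 0.25 / (lik * 0.25).sum()
        new = update_block_transitions(space, lik, eta_t=0.3)
        assert np.abs(new - (0.7 * 0.25 + 0.3 * post)).max() < 1e-12

    def test_impossible_sequence_rejected(self, hier):
        with pytest.raises(ValueError, match="impossible"):
            update_block_transitions(hier.copy(), np.zeros(4), eta_t=0.3)

    def test_experienced_block_gains_mass(self, hier):
        space = hier.copy()
        for _ in range(3):
            update_block_transitions(space, np.array([0.9, 0.05, 0.03, 0.02]),
                                     eta_t=0.3)
        assert block_entry_probs(space)[0] > 0.25


class TestHierHCLesion:
    def test_floor_applied_and_renormalized(self, hier):
        space = hier.copy()
        ix = space.meta["index"]
        iti = ix["iti"]
        entries = [ix[f"b{b}_trial_start"] for b in (1, 2, 3, 4)]
        space.T[iti, entries] = [0.9, 0.05, 0.03, 0.02]
        les = apply_hc_lesion_hierarchical(space)
        row = np.maximum([0.9, 0.05, 0.03, 0.02], 0.15)
        np.testing.assert_allclose(block_entry_probs(les), row / row.sum(),
                                   atol=1e-12)

    def test_uniform_row_unchanged(self, hier):
        les = apply_hc_lesion_hierarchical(hier)
        assert np.allclose(block_entry_probs(les), 0.25, atol=1e-12)

    def test_floor_persists_through_learning(self, hier):
        les = apply_hc_lesion_hierarchical(hier)
        for _ in range(50):
            update_block_transitions(les, np.array([1.0, 1e-6, 1e-6, 1e-6]),
                                     eta_t=0.5)
        p = block_entry_probs(les)
        assert p.min() >= 0.15 / (1 + 3 * 0.15)   # floor then renormalize
        assert p[0] < 0.75

    def test_invalid_floor_rejected(self, hier):
        with pytest.raises(ValueError):
            apply_hc_lesion_hierarchical(hier, transition_floor=0.3)


class TestOFCLesion:
    def test_well_dwell_rows_identical(self, hier):
        les = apply_ofc_lesion(hier)
        for b in (1, 2, 3, 4):
            lw = les.state_index(f"b{b}_left_well")
            rw = les.state_index(f"b{b}_right_well")
            assert np.array_equal(les.D[lw], les.D[rw])

    def test_reward1_gains_two_successors_in_number_blocks(self, hier):
        les = apply_ofc_lesion(hier)
        for b in (3, 4):
            for side in ("left", "right"):
                row = les.T[les.state_index(f"b{b}_{side}_reward1")]
                assert np.count_nonzero(row) == 2
                assert row[les.state_index(f"b{b}_{side}_reward2")] == 0.5
                assert row[les.state_index("iti")] == 0.5

    def test_cue_rows_blurred_in_every_cluster(self, hier):
        les = apply_ofc_lesion(hier)
        for b in (1, 2, 3, 4):
            lc = les.state_index(f"b{b}_left_cue")
            assert les.T[lc, les.state_index(f"b{b}_right_well")] == \
                pytest.approx(0.45)

    def test_rejects_flat_space(self, flat):
        with pytest.raises(SpecificationError, match="hierarchical"):
            apply_ofc_lesion(flat)


class TestVSLesion:
    def test_hyperparameters_zeroed(self):
        h = apply_vs_lesion(LearnerHyper())
        assert h.dwell_amplitude == 0.0
        assert h.kernel_amplitude == 0.0

    def test_discount_becomes_timing_blind(self):
        from hsmtd.learning import prediction_error
        from hsmtd.spaces import StateSpace
        space = StateSpace(
            state_labels=["a", "b"], observation_labels=["x", "null"],
            null_symbol="null",
            T=np.array([[0.0, 1.0], [1.0, 0.0]]),
            O=np.array([[1.0, 0.0], [1.0, 0.0]]),
            D=np.array([[1.0], [1.0]]),
        )
        h = apply_vs_lesion(LearnerHyper())
        d_short = prediction_error(np.zeros(2), space, np.array([1.0, 0]),
                                   np.array([2.0, 0]), 1.0, 0, h)
        d_long = prediction_error(np.zeros(2), space, np.array([1.0, 0]),
                                  np.array([60.0, 0]), 1.0, 0, h)
        assert d_short[0] == pytest.approx(d_long[0], abs=1e-15)

    def test_dwell_rows_frozen_at_baseline(self, hier):
        space = vs_lesion_dwell_baseline(hier)
        assert not space.dwell_plastic.any()
        assert np.abs(space.D - space.D[0]).max() < 1e-12  # all rows uniform
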