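"""Energy hand values, mean-field behavior and the exhaustive oracle."""

import numpy as np
import pytest

from scseseg.crf import (
    CrfConfig,
    UnaryField,
    exhaustive_map,
    mean_field_refine,
    pairwise_kernel,
    total_energy,
    unary_from_probability,
)
from scseseg.errors import InstanceTooLargeError, SelfPairError
from scseseg.types import LabelMap, ProbabilityMap, Volume


def _uniform_volume(shape, value=0.5):
    return Volume(np.full(shape, value), id="u")


def _random_instance(rng, shape, ncls=2):
    """Random unaries ~ U(0,1) and random intensities."""
    unary = UnaryField(rng.random((ncls,) + shape))
    vol = Volume(rng.random(shape), id="r")
    return unary, vol


def _pm_from_unary(unary):
    e = np.exp(-unary.potentials)
    return ProbabilityMap(e / e.sum(axis=0, keepdims=True))


class TestUnary:
    def test_certain_probability_has_zero_cost(self):
        pm = ProbabilityMap(np.stack([np.ones((1, 1, 1)), np.zeros((1, 1, 1))]))
        psi = unary_from_probability(pm, clamp=50.0).potentials
        assert psi[0, 0, 0, 0] == 0.0
        assert psi[1, 0, 0, 0] == 50.0  # -log 0 clamped

    def test_exp_minus_one_probability_costs_one(self):
        p = np.full((2, 1, 1, 1), 0.0)
        p[0] = np.exp(-1.0)
        p[1] = 1.0 - np.exp(-1.0)
        psi = unary_from_probability(ProbabilityMap(p)).potentials
        assert psi[0, 0, 0, 0] == pytest.approx(1.0, abs=1e-12)


class TestPairwiseKernel:
    CFG = CrfConfig(omega1=1.0, omega2=1.0, sigma_alpha=1.0, sigma_beta=1.0, sigma_gamma=1.0)

    def test_zero_weights_give_zero(self):
        vol = _uniform_volume((2, 1, 1))
        cfg = CrfConfig(omega1=0.0, omega2=0.0)
        assert pairwise_kernel((0, 0, 0), (1, 0, 0), vol, cfg) == 0.0

    def test_unit_neighbors_equal_intensity_hand_value(self):
        # two voxels one apart, equal intensity: e^-0.5 + e^-0.5
        vol = _uniform_volume((2, 1, 1))
        k = pairwise_kernel((0, 0, 0), (1, 0, 0), vol, self.CFG)
        assert k == pytest.approx(2.0 * np.exp(-0.5), abs=1e-6)
        assert k == pytest.approx(1.21306, abs=1e-5)

    def test_symmetry_on_random_pairs(self, rng):
        vol = Volume(rng.random((4, 4, 4)), id="v")
        cfg = CrfConfig()
        for _ in range(100):
            i = tuple(rng.integers(0, 4, 3))
            j = tuple(rng.integers(0, 4, 3))
            if i == j:
                continue
            assert pairwise_kernel(i, j, vol, cfg) == pytest.approx(
                pairwise_kernel(j, i, vol, cfg), rel=1e-12
            )

    def test_self_pair_rejected(self):
        with pytest.raises(SelfPairError):
            pairwise_kernel((1, 1, 1), (1, 1, 1), _uniform_volume((3, 3, 3)), CrfConfig())


class TestTotalEnergy:
    def test_single_voxel_energy_is_selected_unary(self):
        unary = UnaryField(np.array([0.3, 0.8]).reshape(2, 1, 1, 1))
        vol = _uniform_volume((1, 1, 1))
        labels = LabelMap(np.zeros((1, 1, 1), dtype=np.int64), num_classes=2)
        assert total_energy(labels, unary, vol, CrfConfig()) == pytest.approx(0.3)

    def test_equal_labels_incur_no_pairwise_cost(self):
        unary = UnaryField(np.array([[0.2, 0.4], [0.7, 0.1]]).reshape(2, 2, 1, 1))
        vol = _uniform_volume((2, 1, 1))
        labels = LabelMap(np.zeros((2, 1, 1), dtype=np.int64), num_classes=2)
        assert total_energy(labels, unary, vol, CrfConfig()) == pytest.approx(0.2 + 0.4)

    def test_differing_labels_pay_the_kernel_hand_value(self):
        unary = UnaryField(np.zeros((2, 2, 1, 1)))
        vol = _uniform_volume((2, 1, 1))
        labels = LabelMap(np.array([0, 1]).reshape(2, 1, 1), num_classes=2)
        cfg = TestPairwiseKernel.CFG
        assert total_energy(labels, unary, vol, cfg) == pytest.approx(1.21306, abs=1e-5)

    def test_decoupled_energy_equals_sum_of_selected_unaries(self, rng):
        cfg = CrfConfig(omega1=0.0, omega2=0.0)
        for _ in range(10):
            unary, vol = _random_instance(rng, (2, 2, 2))
            labels = LabelMap(rng.integers(0, 2, (2, 2, 2)), num_classes=2)
            uflat = unary.potentials.reshape(2, -1)
            expected = uflat[labels.labels.reshape(-1), np.arange(8)].sum()
            assert total_energy(labels, unary, vol, cfg) == pytest.approx(expected)


class TestMeanField:
    def test_no_coupling_returns_unary_argmax(self, rng):
        unary, vol = _random_instance(rng, (2, 2, 2))
        pm = _pm_from_unary(unary)
        cfg = CrfConfig(omega1=0.0, omega2=0.0, iterations=5)
        _, labels = mean_field_refine(pm, vol, cfg)
        np.testing.assert_array_equal(labels.labels, np.argmax(pm.probs, axis=0))

    def test_uniform_distribution_is_a_fixed_point(self):
        shape = (2, 2, 2)
        pm = ProbabilityMap(np.full((2,) + shape, 0.5))
        vol = _uniform_volume(shape)
        refined, _ = mean_field_refine(pm, vol, CrfConfig(iterations=5))
        np.testing.assert_allclose(refined.probs, 0.5, atol=1e-12)

    def test_q_stays_normalized_and_shape_preserved(self, rng):
        unary, vol = _random_instance(rng, (2, 3, 2), ncls=3)
        pm = _pm_from_unary(unary)
        refined, labels = mean_field_refine(pm, vol, CrfConfig(iterations=7))
        assert refined.probs.shape == pm.probs.shape
        assert labels.num_classes == 3
        np.testing.assert_allclose(refined.probs.sum(axis=0), 1.0, atol=1e-9)

    def test_refinement_rarely_increases_energy(self, rng_seed=0):
        # mean-field should beat the unary argmax on most random instances
        rng = np.random.default_rng(rng_seed)
        cfg = CrfConfig(iterations=5)
        wins = 0
        for _ in range(100):
            unary, vol = _random_instance(rng, (2, 2, 3))
            pm = _pm_from_unary(unary)
            _, refined = mean_field_refine(pm, vol, cfg)
            argmax = LabelMap(np.argmin(unary.potentials, axis=0), num_classes=2)
            e_ref = total_energy(refined, unary, vol, cfg)
            e_arg = total_energy(argmax, unary, vol, cfg)
            wins += e_ref <= e_arg + 1e-9
        assert wins >= 90

    def test_dense_limit_guard_directs_to_truncated_mode(self, rng):
        shape = (32, 32, 32)
        pm = ProbabilityMap(np.full((2,) + shape, 0.5))
        vol = Volume(rng.random(shape), id="big")
        with pytest.raises(InstanceTooLargeError, match="neighborhood_radius"):
            mean_field_refine(pm, vol, CrfConfig())

    def test_truncated_mode_matches_dense_on_small_instance(self, rng):
        # with a radius covering the whole grid the truncated message
        # equals the dense one
        unary, vol = _random_instance(rng, (2, 2, 2))
        pm = _pm_from_unary(unary)
        dense, _ = mean_field_refine(pm, vol, CrfConfig(iterations=3))
        trunc, _ = mean_field_refine(
            pm, vol, CrfConfig(iterations=3, neighborhood_radius=2)
        )
        np.testing.assert_allclose(dense.probs, trunc.probs, atol=1e-9)


class TestExhaustiveOracle:
    def test_decoupled_instance_reduces_to_argmax(self, rng):
        unary, vol = _random_instance(rng, (2, 2, 1))
        cfg = CrfConfig(omega1=0.0, omega2=0.0)
        labels = exhaustive_map(unary, vol, cfg)
        np.testing.assert_array_equal(labels.labels, np.argmin(unary.potentials, axis=0))

    def test_single_voxel_three_class_hand_case(self):
        unary = UnaryField(np.array([0.5, 0.1, 0.9]).reshape(3, 1, 1, 1))
        labels = exhaustive_map(unary, _uniform_volume((1, 1, 1)), CrfConfig())
        assert labels.labels[0, 0, 0] == 1

    def test_tie_break_is_lexicographically_smallest(self):
        # identical unaries, no coupling: the all-zeros labeling wins
        unary = UnaryField(np.zeros((2, 2, 1, 1)))
        cfg = CrfConfig(omega1=0.0, omega2=0.0)
        labels = exhaustive_map(unary, _uniform_volume((2, 1, 1)), cfg)
        np.testing.assert_array_equal(labels.labels, 0)

    def test_global_optimum_dominates_mean_field(self, rng):
        cfg = CrfConfig(iterations=5)
        for _ in range(20):
            unary, vol = _random_instance(rng, (2, 2, 2))
            pm = _pm_from_unary(unary)
            _, mf_labels = mean_field_refine(pm, vol, cfg)
            best = exhaustive_map(unary, vol, cfg)
            assert total_energy(best, unary, vol, cfg) <= total_energy(
                mf_labels, unary, vol, cfg
            ) + 1e-9

    def test_oversized_instance_rejected(self, rng):
        unary, vol = _random_instance(rng, (3, 3, 3))
        with pytest.raises(InstanceTooLargeError):
            exhaustive_map(unary, vol, CrfConfig())
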