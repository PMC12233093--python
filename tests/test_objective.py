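"""Discriminator, contrastive/regularization losses, schedule, ablation loss."""

import math

import numpy as np
import pytest

from jestr.objective import (
    ObjectiveConfig,
    ce_dotproduct_loss,
    contrastive_loss,
    discriminator,
    regularization_loss,
    schedule_weights,
    total_loss,
)


def brute_force_infonce(spec, mol, tau):
    """Scalar-arithmetic oracle for the batch contrastive loss."""
    k = len(spec)

    def h(a, b):
        return math.exp(
            float(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b)) / tau
        )

    total = 0.0
    for n in range(k):
        denom = sum(h(spec[n], mol[m]) for m in range(k))
        total += -math.log(h(spec[n], mol[n]) / denom)
    return total / k


class TestDiscriminator:
    def test_identical_unit_vectors(self):
        v = np.array([1.0, 0.0, 0.0])
        assert discriminator(v, v, 1.0) == pytest.approx(math.e)

    def test_orthogonal(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert discriminator(a, b, 0.1) == pytest.approx(1.0)

    def test_antiparallel(self):
        a = np.array([2.0, 0.0])
        assert discriminator(a, -a, 0.5) == pytest.approx(math.exp(-2.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert discriminator(a, b, 0.2) == pytest.approx(
            discriminator(3.7 * a, 0.01 * b, 0.2)
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            discriminator(np.zeros(3), np.ones(3), 1.0)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            discriminator(np.ones(3), np.ones(3), 0.0)


class TestContrastiveLoss:
    def test_k1_is_zero(self):
        v = np.array([[0.3, -0.7]])
        assert contrastive_loss(v, v, 0.07) == pytest.approx(0.0, abs=1e-12)

    def test_identical_molecules_give_log_k(self):
        spec = np.eye(3)
        mol = np.ones((3, 3))
        for tau in (0.07, 0.5, 2.0):
            assert contrastive_loss(spec, mol, tau) == pytest.approx(math.log(3))

    def test_two_pair_orthonormal_case(self):
        spec = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = -math.log(math.e / (math.e + 1.0))  # ~0.31326 per term
        assert contrastive_loss(spec, spec, 1.0) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k, d = int(rng.integers(2, 8)), int(rng.integers(2, 6))
            spec, mol = rng.normal(size=(k, d)), rng.normal(size=(k, d))
            tau = float(rng.uniform(0.05, 2.0))
            assert contrastive_loss(spec, mol, tau) == pytest.approx(
                brute_force_infonce(spec, mol, tau), rel=1e-9
            )

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(1, 6))
            spec, mol = rng.normal(size=(k, 4)), rng.normal(size=(k, 4))
            assert contrastive_loss(spec, mol, 0.3) >= -1e-12

    def test_scale_invariance_of_single_embedding(self):
        rng = np.random.default_rng(5)
        spec, mol = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        scaled = mol.copy()
        scaled[2] *= 41.0
        assert contrastive_loss(spec, mol, 0.1) == pytest.approx(
            contrastive_loss(spec, scaled, 0.1), rel=1e-9
        )

    def test_sharpness_monotone_in_inverse_tau(self):
        """Smaller tau widens the loss gap of a mismatched batch over a
        matched one."""
        spec = np.array([[1.0, 0.2], [0.1, 1.0], [-0.5, 0.8]])
        matched = spec.copy()
        mismatched = spec[[1, 0, 2]]
        gaps = []
        for tau in (1.0, 0.5, 0.2, 0.1):
            gaps.append(
                contrastive_loss(spec, mismatched, tau)
                - contrastive_loss(spec, matched, tau)
            )
        assert all(b > a for a, b in zip(gaps, gaps[1:]))

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.ones((2, 3)), np.ones((3, 3)), 0.1)


class TestRegularizationLoss:
    def test_parallel_orthogonal_antiparallel(self):
        spec = np.array([[1.0, 0.0], [0.0, 2.0]])
        parallel = np.array([[[2.0, 0.0]], [[0.0, 0.5]]])
        assert regularization_loss(spec, parallel) == pytest.approx(1.0)
        ortho = np.array([[[0.0, 1.0]], [[3.0, 0.0]]])
        assert regularization_loss(spec, ortho) == pytest.approx(0.0, abs=1e-9)
        anti = -parallel
        assert regularization_loss(spec, anti) == pytest.approx(-1.0)

    def test_mean_over_spectra_and_candidates(self):
        spec = np.array([[1.0, 0.0]])
        cands = np.array([[[1.0, 0.0], [0.0, 1.0]]])  # cos 1 and 0
        assert regularization_loss(spec, cands) == pytest.approx(0.5)

    def test_empty_candidate_block_rejected(self):
        with pytest.raises(ValueError):
            regularization_loss(np.ones((2, 3)), np.ones((2, 0, 3)))

    def test_owner_layout_matches_block_layout(self):
        rng = np.random.default_rng(6)
        spec = rng.normal(size=(3, 4))
        cands = rng.normal(size=(3, 5, 4))
        flat = cands.reshape(15, 4)
        owners = np.repeat(np.arange(3), 5)
        assert regularization_loss(spec, cands) == pytest.approx(
            regularization_loss(spec, flat, owners=owners)
        )


class TestSchedule:
    def test_paper_examples_100_epochs(self):
        cfg = ObjectiveConfig()
        assert schedule_weights(50, 100, cfg) == (1.0, 0.0)
        assert schedule_weights(97, 100, cfg) == (1.0, 0.0)
        assert schedule_weights(98, 100, cfg) == (0.9, 0.1)

    @pytest.mark.parametrize("total", [3, 10, 33, 34, 50, 100, 365])
    def test_two_regimes_and_weights_sum_to_one(self, total):
        cfg = ObjectiveConfig()
        betas = [schedule_weights(e, total, cfg)[1] for e in range(1, total + 1)]
        switches = sum(1 for a, b in zip(betas, betas[1:]) if a != b)
        assert switches == 1
        assert betas[-1] == cfg.reg_weight  # final phase never empty
        for e in range(1, total + 1):
            a, b = schedule_weights(e, total, cfg)
            assert a + b == pytest.approx(1.0)

    def test_total_loss_combination(self):
        cfg = ObjectiveConfig()
        val, a, b = total_loss(2.0, 0.5, 98, 100, cfg)
        assert (a, b) == (0.9, 0.1)
        assert val == pytest.approx(0.9 * 2.0 + 0.1 * 0.5)
        val, a, b = total_loss(2.0, 123.0, 50, 100, cfg)
        assert val == pytest.approx(2.0) and b == 0.0

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            schedule_weights(0, 10, ObjectiveConfig())


class TestCeDotProduct:
    def test_k1_zero_and_identical_logk(self):
        v = np.array([[0.5, 0.5]])
        assert ce_dotproduct_loss(v, v) == pytest.approx(0.0, abs=1e-12)
        assert ce_dotproduct_loss(np.eye(3), np.ones((3, 3))) == pytest.approx(
            math.log(3)
        )

    def test_equals_infonce_on_unit_vectors_at_tau_1(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            k, d = int(rng.integers(2, 7)), int(rng.integers(2, 8))
            spec = rng.normal(size=(k, d))
            mol = rng.normal(size=(k, d))
            spec /= np.linalg.norm(spec, axis=1, keepdims=True)
            mol /= np.linalg.norm(mol, axis=1, keepdims=True)
            assert ce_dotproduct_loss(spec, mol) == pytest.approx(
                contrastive_loss(spec, mol, 1.0), rel=1e-6
            )

    def test_not_scale_invariant_unlike_cosine_form(self):
        """Rescaling one embedding changes the dot-product loss but not the
        cosine loss — the normalization asymmetry between the two objectives."""
        rng = np.random.default_rng(8)
        spec, mol = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        scaled = mol.copy()
        scaled[1] *= 10.0
        assert ce_dotproduct_loss(spec, mol) != pytest.approx(
            ce_dotproduct_loss(spec, scaled), rel=1e-3
        )
        assert contrastive_loss(spec, mol, 1.0) == pytest.approx(
            contrastive_loss(spec, scaled, 1.0), rel=1e-9
        )
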