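import numpy as np
import pytest

from avpseg.nn import (SMOOTH_EPS, Tensor, boundary_weight_map,
                       boundary_weighted_dice_loss, cross_entropy_loss,
                       deep_supervision_loss, dice_loss, downsample_labels,
                       one_hot)


def _probs_from_labels(labels, num_classes=10):
    return Tensor(one_hot(labels, num_classes), requires_grad=True)


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[1:3, 1:3, 1:3] = 3
        probs = _probs_from_labels(labels)
        assert float(dice_loss(probs, one_hot(labels, 10)).data) <= 1e-4

    def test_uniform_prediction_matches_scalar_oracle(self):
        # 4^3 grid, single foreground class, uniform prediction 1/10
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[:2] = 1
        target = one_hot(labels, 10)
        probs = Tensor(np.full((10, 4, 4, 4), 0.1, dtype=np.float32))
        got = float(dice_loss(probs, target).data)

        # independent scalar recomputation by direct summation
        n = 64
        n_fg = 32
        dices = []
        for c in range(1, 10):
            t_sum = n_fg if c == 1 else 0
            inter = 0.1 * t_sum
            dices.append((2 * inter + SMOOTH_EPS)
                         / (0.1 * n + t_sum + SMOOTH_EPS))
        expected = 1.0 - float(np.mean(dices))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_class_permutation_invariance(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(6, 6, 6)).astype(np.uint8)
        scores = rng.random((10, 6, 6, 6)).astype(np.float32)
        probs = scores / scores.sum(axis=0, keepdims=True)
        base = float(dice_loss(Tensor(probs), one_hot(labels, 10)).data)

        # swap foreground classes 1 and 3 consistently
        perm = np.arange(10)
        perm[1], perm[3] = 3, 1
        labels_p = perm[labels].astype(np.uint8)
        probs_p = probs[np.argsort(perm)]
        permuted = float(dice_loss(Tensor(probs_p),
                                   one_hot(labels_p, 10)).data)
        assert permuted == pytest.approx(base, abs=1e-6)

    def test_unnormalized_probabilities_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        bad = Tensor(np.full((10, 4, 4, 4), 0.2, dtype=np.float32))
        with pytest.raises(ValueError, match="normalized"):
            dice_loss(bad, one_hot(labels, 10))

    def test_translation_consistency(self):
        rng = np.random.default_rng(1)
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[3:6, 3:6, 3:6] = 2
        scores = rng.random((10, 10, 10, 10)).astype(np.float32)
        probs = scores / scores.sum(axis=0, keepdims=True)
        base = float(dice_loss(Tensor(probs), one_hot(labels, 10)).data)
        shifted = float(dice_loss(
            Tensor(np.roll(probs, (1, 1, 1), axis=(1, 2, 3))),
            one_hot(np.roll(labels, (1, 1, 1), axis=(0, 1, 2)), 10)).data)
        assert abs(base - shifted) < 1e-6


class TestBoundaryWeightMap:
    def test_uniform_map_all_ones(self):
        w = boundary_weight_map(np.zeros((6, 6, 6), dtype=np.uint8), 5.0, 2.0)
        assert np.array_equal(w, np.ones((6, 6, 6), dtype=np.float32))

    def test_boundary_voxel_gets_w_max(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[:4] = 1
        w = boundary_weight_map(labels, w_max=5.0, tau=2.0)
        assert w[3, 4, 4] == pytest.approx(5.0)
        assert w[4, 4, 4] == pytest.approx(5.0)

    def test_two_block_map_matches_brute_force(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[:3] = 1
        labels[5:, 5:, :] = 2
        w_max, tau = 4.0, 1.5
        got = boundary_weight_map(labels, w_max, tau)

        # exhaustive oracle: boundary voxels via 6-neighbor scan, then
        # all-pairs Euclidean distances
        shape = labels.shape
        boundary = []
        for idx in np.ndindex(shape):
            for ax in range(3):
                for d in (-1, 1):
                    nb = list(idx)
                    nb[ax] += d
                    if 0 <= nb[ax] < shape[ax] and \
                            labels[tuple(nb)] != labels[idx]:
                        boundary.append(idx)
                        break
                else:
                    continue
                break
        boundary = np.array(boundary, dtype=float)
        for idx in np.ndindex(shape):
            d = np.sqrt(((boundary - np.array(idx)) ** 2).sum(axis=1)).min()
            expected = 1.0 + (w_max - 1.0) * np.exp(-d / tau)
            assert got[idx] == pytest.approx(expected, abs=1e-5)

    def test_monotone_decay_from_boundary(self):
        labels = np.zeros((12, 6, 6), dtype=np.uint8)
        labels[:6] = 1
        w = boundary_weight_map(labels, 5.0, 2.0)
        profile = w[6:, 3, 3]
        assert np.all(np.diff(profile) <= 1e-9)

    def test_invalid_params_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            boundary_weight_map(labels, w_max=0.5)
        with pytest.raises(ValueError):
            boundary_weight_map(labels, tau=0.0)


class TestBoundaryWeightedDice:
    def test_unit_weights_reduce_to_dice(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, size=(6, 6, 6)).astype(np.uint8)
        scores = rng.random((10, 6, 6, 6)).astype(np.float32)
        probs = scores / scores.sum(axis=0, keepdims=True)
        target = one_hot(labels, 10)
        w = np.ones((6, 6, 6), dtype=np.float32)
        a = float(boundary_weighted_dice_loss(Tensor(probs), target, w).data)
        b = float(dice_loss(Tensor(probs), target).data)
        assert a == pytest.approx(b, abs=1e-9)

    def test_boundary_error_costs_more_than_interior(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[2:8, 2:8, 2:8] = 1
        target = one_hot(labels, 10)
        w = boundary_weight_map(labels, w_max=5.0, tau=2.0)

        def loss_with_error_at(vox):
            pred = target.copy().astype(np.float32)
            pred[:, vox[0], vox[1], vox[2]] = 0.0
            pred[2, vox[0], vox[1], vox[2]] = 1.0  # wrong class
            return float(boundary_weighted_dice_loss(
                Tensor(pred), target, w).data)

        boundary_err = loss_with_error_at((2, 5, 5))   # on the cube surface
        interior_err = loss_with_error_at((5, 5, 5))   # deep inside
        assert boundary_err > interior_err

    def test_perfect_prediction_small_regardless_of_weights(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[2:4] = 4
        target = one_hot(labels, 10)
        w = boundary_weight_map(labels, w_max=10.0, tau=1.0)
        loss = boundary_weighted_dice_loss(Tensor(target.copy()), target, w)
        assert float(loss.data) <= 1e-4


class TestDeepSupervision:
    def _setup(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, size=(8, 8, 8)).astype(np.uint8)
        target = one_hot(labels, 10)
        aux_target = one_hot(downsample_labels(labels), 10)
        scores = rng.random((10, 8, 8, 8)).astype(np.float32)
        probs = scores / scores.sum(axis=0, keepdims=True)
        aux_scores = rng.random((10, 4, 4, 4)).astype(np.float32)
        aux_probs = aux_scores / aux_scores.sum(axis=0, keepdims=True)
        main = dice_loss(Tensor(probs), target)
        aux = dice_loss(Tensor(aux_probs), aux_target)
        return main, aux

    def test_zero_weight_recovers_main(self):
        main, aux = self._setup()
        total = deep_supervision_loss(main, aux, 0.0)
        assert float(total.data) == float(main.data)

    def test_total_matches_hand_computed_sum(self):
        main, aux = self._setup()
        lam = 0.4
        total = deep_supervision_loss(main, aux, lam)
        # scalar tensors are float32, so compare at float32 resolution
        assert float(total.data) == pytest.approx(
            float(main.data) + lam * float(aux.data), abs=1e-6)

    def test_perfect_predictions_bounded(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[1:3] = 1
        target = one_hot(labels, 10)
        aux_t = one_hot(downsample_labels(labels), 10)
        main = dice_loss(Tensor(target.copy()), target)
        aux = dice_loss(Tensor(aux_t.copy()), aux_t)
        total = deep_supervision_loss(main, aux, 0.4)
        assert float(total.data) <= 1.4e-4


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[0] = 2
        target = one_hot(labels, 10)
        loss = cross_entropy_loss(Tensor(target.copy()), target)
        assert float(loss.data) < 1e-5

    def test_matches_scalar_formula(self):
        labels = np.zeros((2, 2, 2), dtype=np.uint8)
        labels[0, 0, 0] = 1
        target = one_hot(labels, 10)
        probs = np.full((10, 2, 2, 2), 0.1, dtype=np.float32)
        loss = cross_entropy_loss(Tensor(probs), target, fg_weight=1.0)
        assert float(loss.data) == pytest.approx(-np.log(0.1 + 1e-7),
                                                 rel=1e-5)
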