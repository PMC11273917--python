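"""GAN objective and training-loop tests: closed-form losses, schedule,
reduction identities, checkpointing, inference contracts."""

import math

import numpy as np
import pytest

from pfstain import pfgan, synthetic_data as sd
from pfstain.pfgan import LossWeights, TrainConfig
from pfstain.pfgan.losses import patchnce_loss, patchnce_loss_pairwise, pf_loss
from pfstain.pfgan.train import NumericalError, _check_finite, total_loss
from pfstain.pfgan.losses import LossBreakdown


TOY = dict(batch_size=4, seed=0, ngf=8, ndf=8, n_blocks=2, n_layers_d=2,
           nce_dim=32, n_nce_patches=32)


@pytest.fixture(scope="module")
def tiny_set():
    return sd.make_unpaired_training_set(8, 8, 0.5, seed=5, patch_size=32)


class TestPfLoss:
    def test_perfect_predictions_give_zero(self):
        assert pf_loss(np.array([0.0, 1.0, 1.0]), np.array([0, 1, 1])).item() == 0.0

    def test_hand_computed_mean_l1(self):
        loss = pf_loss(np.array([0.3, 0.9]), np.array([1, 1]))
        assert loss.item() == pytest.approx((0.7 + 0.1) / 2)

    def test_maximal_uncertainty_fixed_point(self):
        preds = np.full(7, 0.5)
        labels = np.array([0, 1, 0, 1, 1, 0, 0])
        assert pf_loss(preds, labels).item() == pytest.approx(0.5)

    def test_bounded_and_permutation_invariant(self, rng):
        preds = rng.random(10)
        labels = rng.integers(0, 2, 10)
        loss = pf_loss(preds, labels).item()
        assert 0.0 <= loss <= 1.0
        perm = rng.permutation(10)
        assert pf_loss(preds[perm], labels[perm]).item() == pytest.approx(loss)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            pf_loss(np.array([0.5]), np.array([2]))


class TestPatchNCE:
    def test_single_negative_closed_form(self):
        q = np.array([[1.0, 0.0]])
        pos = np.array([[1.0, 0.0]])       # similarity +1
        neg = np.array([[[-1.0, 0.0]]])    # similarity -1
        loss = patchnce_loss(q, pos, neg, tau=1.0).item()
        assert loss == pytest.approx(-math.log(math.e / (math.e + math.exp(-1))), abs=1e-6)
        assert loss == pytest.approx(0.126928, abs=1e-6)

    @pytest.mark.parametrize("k", [1, 4, 15])
    def test_uninformative_limit_is_log_k_plus_one(self, k):
        q = np.array([[1.0, 0.0]])
        pos = np.array([[1.0, 0.0]])
        negs = np.tile(np.array([[[1.0, 0.0]]]), (1, k, 1))
        assert patchnce_loss(q, pos, negs, tau=0.5).item() == pytest.approx(
            math.log(k + 1), abs=1e-9
        )

    def test_strictly_decreasing_as_negative_similarity_drops(self):
        q = pos = np.array([[1.0, 0.0]])
        losses = []
        for sim in (0.9, 0.5, 0.0, -0.5, -0.9):
            neg = np.array([[[sim, math.sqrt(1 - sim**2)]]])
            losses.append(patchnce_loss(q, pos, neg, tau=0.3).item())
        assert losses == sorted(losses, reverse=True)

    def test_increasing_positive_similarity_decreases_loss(self):
        neg = np.array([[[0.0, 1.0]]])
        losses = []
        for sim in (0.2, 0.6, 0.99):
            q = np.array([[1.0, 0.0]])
            pos = np.array([[sim, math.sqrt(1 - sim**2)]])
            losses.append(patchnce_loss(q, pos, neg, tau=0.3).item())
        assert losses == sorted(losses, reverse=True)

    def test_zero_norm_feature_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            patchnce_loss(np.zeros((1, 2)), np.ones((1, 2)), np.ones((1, 1, 2)))

    def test_pairwise_form_equals_explicit_negatives(self, rng):
        n, s, d = 2, 6, 4
        z = rng.normal(size=(n * s, d))
        q = z / np.linalg.norm(z, axis=1, keepdims=True)
        z2 = rng.normal(size=(n * s, d))
        k = z2 / np.linalg.norm(z2, axis=1, keepdims=True)
        fast = patchnce_loss_pairwise(q, k, n, tau=0.07).item()
        # explicit route: negatives are the other s-1 keys of the same image
        base = np.arange(s)
        neg_local = np.stack([np.delete(base, j) for j in range(s)])
        neg_idx = np.repeat(np.arange(n) * s, s).reshape(n * s, 1) + np.tile(neg_local, (n, 1))
        slow = patchnce_loss(q, k, k[neg_idx], tau=0.07).item()
        assert fast == pytest.approx(slow, abs=1e-10)


class TestSchedule:
    def test_initial_final_and_midpoint_values(self):
        cfg = TrainConfig(epochs=200, decay_start=100)
        assert pfgan.lr_at_epoch(cfg, 0) == pytest.approx(2e-4)
        assert pfgan.lr_at_epoch(cfg, 150) == pytest.approx(1e-4)
        assert pfgan.lr_at_epoch(cfg, 200) == 0.0

    def test_non_increasing_and_continuous_at_decay_start(self):
        cfg = TrainConfig(epochs=100)
        values = [pfgan.lr_at_epoch(cfg, e) for e in range(101)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[cfg.decay_from] == pytest.approx(cfg.lr)
        step = values[cfg.decay_from] - values[cfg.decay_from + 1]
        assert step == pytest.approx(cfg.lr / (cfg.epochs - cfg.decay_from))

    def test_epoch_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            pfgan.lr_at_epoch(TrainConfig(epochs=10), 11)


class TestTotalLoss:
    def test_reduces_to_cut_objective_without_pf(self, tiny_set):
        cfg = TrainConfig(epochs=1, **TOY)
        models = pfgan.build_models(cfg)
        rng = np.random.default_rng(3)
        total, bd, _ = total_loss(
            models, tiny_set.source_patches[:2], tiny_set.target_patches[:2],
            None, LossWeights(lambda_pf=0.0), cfg, rng,
        )
        assert total.item() == pytest.approx(bd.gan + bd.nce_x + bd.nce_y, abs=1e-10)
        assert math.isnan(bd.pf)

    def test_components_sum_to_total(self, tiny_set):
        cfg = TrainConfig(epochs=1, **TOY)
        models = pfgan.build_models(cfg)
        rng = np.random.default_rng(3)
        total, bd, _ = total_loss(
            models, tiny_set.source_patches[:2], tiny_set.target_patches[:2],
            tiny_set.target_labels[:2], LossWeights(), cfg, rng,
        )
        assert total.item() == pytest.approx(bd.gan + bd.nce_x + bd.nce_y + bd.pf, abs=1e-10)

    def test_missing_labels_with_pf_enabled_raises(self, tiny_set):
        cfg = TrainConfig(epochs=1, **TOY)
        models = pfgan.build_models(cfg)
        with pytest.raises(ValueError, match="labels"):
            total_loss(models, tiny_set.source_patches[:2], tiny_set.target_patches[:2],
                       None, LossWeights(), cfg, np.random.default_rng(0))

    def test_non_finite_component_aborts_with_name(self):
        bad = LossBreakdown(gan=float("nan"), nce_x=1.0, nce_y=1.0, pf=0.1, total=float("nan"))
        with pytest.raises(NumericalError, match="gan"):
            _check_finite(bad, 0.5)


class TestTrainLoop:
    def test_zero_epoch_returns_initialized_state(self, tiny_set):
        cfg = TrainConfig(epochs=0, **TOY)
        state = pfgan.train(tiny_set.source_patches, tiny_set.target_patches,
                            tiny_set.target_labels, cfg)
        assert state.epoch == 0 and state.history == []

    def test_history_reproducible_under_shared_seed(self, tiny_set):
        cfg = TrainConfig(epochs=1, **TOY)
        runs = [
            pfgan.train(tiny_set.source_patches, tiny_set.target_patches,
                        tiny_set.target_labels, cfg)
            for _ in range(2)
        ]
        assert runs[0].history == runs[1].history

    def test_checkpoint_round_trip_bit_compatible(self, tiny_set, tmp_path):
        cfg = TrainConfig(epochs=0, **TOY)
        state = pfgan.train(tiny_set.source_patches, tiny_set.target_patches,
                            tiny_set.target_labels, cfg)
        path = tmp_path / "ckpt.npz"
        pfgan.save_checkpoint(state, path)
        loaded = pfgan.load_checkpoint(path)
        a = pfgan.stain(tiny_set.source_patches[0], state)
        b = pfgan.stain(tiny_set.source_patches[0], loaded)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def init_state():
    cfg = TrainConfig(epochs=0, **TOY)
    return pfgan.TrainState(pfgan.build_models(cfg), cfg, LossWeights())


class TestStain:
    def test_deterministic_inference(self, init_state, tiny_set):
        a = pfgan.stain(tiny_set.source_patches[0], init_state)
        b = pfgan.stain(tiny_set.source_patches[0], init_state)
        assert np.array_equal(a, b)

    def test_output_shape_and_range(self, init_state, tiny_set):
        out = pfgan.stain(tiny_set.source_patches[0], init_state)
        assert out.shape == tiny_set.source_patches[0].shape
        assert out.dtype == np.uint8

    def test_incompatible_size_names_divisibility(self, init_state):
        patch = np.zeros((30, 30, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="divisible by 4"):
            pfgan.stain(patch, init_state)
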