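"""Loss semantics and the training loop's bookkeeping contracts."""

import numpy as np
import pytest

from osteoseg.model import ModelConfig, SegOutput, SegmentationNet
from osteoseg.fusion import FusionConfig
from osteoseg.nn.tensor import Tensor
from osteoseg.phantom import PhantomSpec, generate_dataset
from osteoseg.train import (TrainConfig, evaluate_model, segmentation_loss,
                            soft_dice_loss, train_model)


def _logits(p):
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return np.log(p / (1 - p))


def _out(mask_logits, edge_logits=None):
    return SegOutput(mask_logits=Tensor(mask_logits),
                     edge_logits=None if edge_logits is None else Tensor(edge_logits))


def test_perfect_saturated_prediction_drives_loss_to_zero(rng):
    truth = (rng.random((1, 8, 8, 1)) > 0.5).astype(float)
    logits = np.where(truth > 0, 40.0, -40.0)
    loss = segmentation_loss(_out(logits), truth, weights=(1, 1, 0))
    assert float(loss.data) < 1e-3


def test_soft_dice_zero_for_exact_probability_match(rng):
    truth = (rng.random((1, 8, 8, 1)) > 0.5).astype(float)
    loss = soft_dice_loss(Tensor(_logits(truth)), truth)
    assert float(loss.data) == pytest.approx(0.0, abs=1e-4)


def test_uniform_half_probabilities_give_ln2_bce(rng):
    truth = (rng.random((2, 8, 8, 1)) > 0.3).astype(float)
    logits = np.zeros((2, 8, 8, 1))
    loss = segmentation_loss(_out(logits), truth, weights=(0, 1, 0))
    assert float(loss.data) == pytest.approx(np.log(2), rel=1e-6)


def test_edge_term_requires_target_and_contributes(rng):
    truth = (rng.random((1, 8, 8, 1)) > 0.5).astype(float)
    edge = (rng.random((1, 8, 8, 1)) > 0.8).astype(float)
    out = _out(np.zeros((1, 8, 8, 1)), np.zeros((1, 8, 8, 1)))
    with pytest.raises(ValueError, match="edge"):
        segmentation_loss(out, truth, None, weights=(1, 1, 0.5))
    full = segmentation_loss(out, truth, edge, weights=(0, 0, 0.5))
    assert float(full.data) == pytest.approx(0.5 * np.log(2), rel=1e-6)


def test_loss_non_increasing_as_probabilities_approach_truth(rng):
    truth = (rng.random((1, 8, 8, 1)) > 0.5).astype(float)
    noise = rng.random((1, 8, 8, 1))
    losses = []
    for t in (0.0, 0.3, 0.6, 0.9):
        p = (1 - t) * noise + t * truth
        losses.append(float(soft_dice_loss(Tensor(_logits(p)), truth).data))
    assert all(a >= b - 1e-9 for a, b in zip(losses, losses[1:]))


def test_loss_rejects_shape_mismatch(rng):
    with pytest.raises(ValueError, match="shape"):
        segmentation_loss(_out(np.zeros((1, 8, 8, 1))),
                          np.zeros((1, 4, 4)), weights=(1, 0, 0))


def _tiny_net(seed=0):
    cfg = ModelConfig(base_channels=2, input_size=(16, 16),
                      fusion=FusionConfig(n_layers=1, pairing="adjacent"),
                      seed=seed)
    return SegmentationNet(cfg)


def _tiny_samples(n=6):
    spec = PhantomSpec(size=(16, 16), seed=3, tumor_radius_frac=(0.15, 0.3))
    return generate_dataset(spec, n, slices_per_patient=2)


def test_history_covers_every_epoch_and_loss_decreases():
    samples = _tiny_samples()
    model = _tiny_net()
    cfg = TrainConfig(lr=3e-3, epochs=6, batch_size=3, seed=0)
    model, history = train_model(model, samples[:4], samples[4:], cfg)
    assert len(history) == 6
    assert "val_dsc" in history.columns
    assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]


def test_two_runs_same_seed_reach_identical_final_loss():
    samples = _tiny_samples()
    finals = []
    for _ in range(2):
        model = _tiny_net(seed=1)
        cfg = TrainConfig(lr=1e-3, epochs=2, batch_size=2, seed=7)
        _, history = train_model(model, samples[:4], [], cfg)
        finals.append(history["train_loss"].iloc[-1])
    assert finals[0] == finals[1]


def test_max_steps_caps_optimizer_updates():
    samples = _tiny_samples()
    model = _tiny_net()
    cfg = TrainConfig(lr=1e-3, epochs=50, batch_size=2, max_steps=3, seed=0)
    _, history = train_model(model, samples[:4], [], cfg)
    assert history["step"].iloc[-1] == 3


def test_empty_train_partition_rejected():
    with pytest.raises(ValueError, match="empty"):
        train_model(_tiny_net(), [], _tiny_samples(2), TrainConfig(epochs=1))


def test_evaluate_model_perfect_oracle_scores_one():
    samples = _tiny_samples(4)

    class Oracle:
        config = type("C", (), {"shape_flow_enabled": False})()

        def predict(self, images, batch_size=4):
            return np.stack([s.mask for s in samples[: len(images)]])

    table = evaluate_model(Oracle(), samples)
    mean = table[table["sample"] == "mean"].iloc[0]
    assert mean["dsc"] == pytest.approx(1.0)


def test_evaluate_model_constant_background_has_zero_recall():
    samples = _tiny_samples(4)

    class AllBackground:
        def predict(self, images, batch_size=4):
            return np.zeros((len(images), 16, 16), dtype=np.uint8)

    table = evaluate_model(AllBackground(), samples)
    mean = table[table["sample"] == "mean"].iloc[0]
    assert mean["recall"] == 0.0


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lr=0.0)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
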