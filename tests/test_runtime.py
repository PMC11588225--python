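"""Dataset I/O, training-loop behaviour, evaluation and prediction."""

import numpy as np
import pytest

import imageio.v3 as iio
from lesionseg.autograd import Tensor
from lesionseg.network import NetworkConfig, build_network
from lesionseg.objectives import confusion
from lesionseg.runtime import (TrainConfig, evaluate, load_dataset, predict,
                               summarize, train)
from lesionseg.synthetic import SceneParams, generate_sample, save_dataset

TINY_NET = NetworkConfig(input_size=(32, 32))
SCENE32 = SceneParams(image_size=(32, 32), hair_count=2)


def make_samples(n, seed=0, params=SCENE32):
    return [generate_sample(params, seed + i) for i in range(n)]


class _MaskEchoNet:
    """Evaluation stub whose prediction is the first image channel.

    Feeding it samples whose image channels replicate the mask makes the
    prediction exactly equal the ground truth, giving a closed-form oracle
    for the evaluation loop.
    """

    training = False
    cfg = TINY_NET

    def eval(self):
        return self

    def train(self):
        return self

    def forward(self, images):
        return Tensor(images.data[:, :1])


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def test_save_load_roundtrip_is_exact(tmp_path):
    samples = make_samples(3)
    save_dataset({"train": samples}, tmp_path)
    report = load_dataset(tmp_path)
    assert len(report.samples) == 3 and not report.missing_masks
    for orig, loaded in zip(samples, report.samples):
        np.testing.assert_array_equal(loaded.mask, orig.mask)
        quantised = np.round(orig.image * 255) / 255.0
        np.testing.assert_allclose(loaded.image, quantised, atol=1e-12)


def test_image_without_mask_is_flagged_not_dropped_silently(tmp_path):
    save_dataset({"train": make_samples(1)}, tmp_path)
    iio.imwrite(tmp_path / "orphan.png", np.zeros((8, 8, 3), dtype=np.uint8))
    with pytest.warns(UserWarning, match="without a mask"):
        report = load_dataset(tmp_path)
    assert report.missing_masks == ["orphan.png"]
    assert len(report.samples) == 1


def test_grayscale_255_mask_binarised_and_nonbinary_mask_warns(tmp_path):
    iio.imwrite(tmp_path / "a.png", np.full((8, 8, 3), 128, dtype=np.uint8))
    iio.imwrite(tmp_path / "a_mask.png",
                np.array([[0, 255]] * 4 + [[255, 0]] * 4, dtype=np.uint8)
                .repeat(4, axis=1))
    report = load_dataset(tmp_path)
    assert set(np.unique(report.samples[0].mask)) == {0, 1}

    iio.imwrite(tmp_path / "a_mask.png", np.full((8, 8), 100, dtype=np.uint8))
    with pytest.warns(UserWarning, match="not binary"):
        report = load_dataset(tmp_path)
    assert set(np.unique(report.samples[0].mask)) == {0}


def test_load_dataset_resizes_to_input_size(tmp_path):
    save_dataset({"train": make_samples(1)}, tmp_path)
    report = load_dataset(tmp_path, input_size=(16, 16))
    assert report.samples[0].image.shape == (3, 16, 16)
    assert set(np.unique(report.samples[0].mask)) <= {0, 1}


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def test_training_is_deterministic_and_loss_finite(float32_mode):
    samples = make_samples(4)
    cfg = TrainConfig(epochs=3, batch_size=2, initial_lr=1e-3, seed=5)
    histories = []
    for _ in range(2):
        net = build_network(TINY_NET, seed=5)
        histories.append(train(net, samples, samples[:2], cfg))
    assert histories[0].train_loss == histories[1].train_loss
    assert histories[0].val_loss == histories[1].val_loss
    assert all(np.isfinite(histories[0].train_loss))
    assert len(histories[0].train_loss) == 3


def test_plateau_decay_halves_learning_rate_exactly(float32_mode):
    samples = make_samples(2)
    # a vanishing learning rate cannot improve the validation loss, so the
    # plateau rule must fire after `decay_patience_epochs` stale epochs
    cfg = TrainConfig(epochs=4, batch_size=2, initial_lr=1e-20,
                      lr_decay_factor=0.5, decay_patience_epochs=1, seed=0)
    net = build_network(TINY_NET, seed=0)
    history = train(net, samples, samples, cfg)
    assert history.lr[1] == cfg.initial_lr          # decay fires after epoch 2
    assert history.lr[2] == pytest.approx(cfg.initial_lr * 0.5)
    assert all(b <= a for a, b in zip(history.lr, history.lr[1:]))


def test_empty_sets_and_nonfinite_loss_rejected(float32_mode):
    net = build_network(TINY_NET, seed=0)
    cfg = TrainConfig(epochs=1)
    with pytest.raises(ValueError):
        train(net, [], make_samples(1), cfg)
    with pytest.raises(ValueError):
        evaluate(net, [], cfg)
    # poison the segmentation head so the NaN first appears in the loss
    net.head.weight.data[...] = np.nan
    with pytest.raises(RuntimeError, match="non-finite"):
        train(net, make_samples(2), make_samples(1), cfg)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def test_ground_truth_prediction_scores_perfectly():
    samples = make_samples(3)
    echo_samples = [
        type(s)(image=np.stack([s.mask] * 3).astype(float), mask=s.mask,
                meta=s.meta)
        for s in samples]
    result = evaluate(_MaskEchoNet(), echo_samples, TrainConfig())
    assert result.macro_mean.iou == 1.0 and result.macro_mean.dsc == 1.0
    assert result.macro_std.iou == 0.0
    assert result.micro.iou == 1.0


def test_macro_mean_matches_hand_average(float32_mode):
    samples = make_samples(3)
    net = build_network(TINY_NET, seed=1)
    cfg = TrainConfig()
    result = evaluate(net, samples, cfg)
    net.eval()
    ious = []
    for s in samples:
        pred = net.forward(Tensor(s.image[None])).data[0, 0]
        ious.append(
            __import__("lesionseg.objectives", fromlist=["metrics"]).metrics(
                confusion(pred, s.mask, cfg.threshold)).iou)
    assert result.macro_mean.iou == pytest.approx(np.nanmean(ious), abs=1e-9)
    assert 0.0 <= result.macro_mean.iou <= 1.0


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predict_writes_binary_png_at_original_resolution(tmp_path, float32_mode):
    sample = generate_sample(SceneParams(image_size=(48, 48), hair_count=1), 9)
    save_dataset({"test": [sample]}, tmp_path)
    net = build_network(TINY_NET, seed=2)
    out = tmp_path / "pred.png"
    mask = predict(net, tmp_path / "sample_0000.png", out, TrainConfig())
    written = iio.imread(out)
    assert written.shape == (48, 48)
    assert set(np.unique(written)) <= {0, 255}
    np.testing.assert_array_equal(written, mask * 255)


def test_predict_consistent_with_evaluate_confusion(tmp_path, float32_mode):
    params = SceneParams(image_size=(32, 32), hair_count=1)
    sample = generate_sample(params, 17)
    save_dataset({"test": [sample]}, tmp_path)
    net = build_network(TINY_NET, seed=4)
    cfg = TrainConfig()
    mask = predict(net, tmp_path / "sample_0000.png", tmp_path / "out.png", cfg)
    # the freshly written prediction has no mask of its own; that warning is
    # expected here
    with pytest.warns(UserWarning, match="without a mask"):
        loaded = load_dataset(tmp_path).samples[0]
    result = evaluate(net, [loaded], cfg)
    # the count of predicted-positive pixels must agree between both paths
    _, report = result.per_image[0]
    c = confusion(mask.astype(float), loaded.mask, cfg.threshold)
    assert c.tp + c.fp == int(mask.sum())
    assert report == __import__("lesionseg.objectives", fromlist=["metrics"]).metrics(c)

    with pytest.raises(FileNotFoundError):
        predict(net, tmp_path / "nope.png", tmp_path / "x.png", cfg)


# ---------------------------------------------------------------------------
# complexity summary
# ---------------------------------------------------------------------------

def test_summarize_named_variants_and_unknown_name():
    base = summarize("baseline", input_size=(64, 64))
    full = summarize("full", input_size=(64, 64))
    assert full.param_count > base.param_count
    with pytest.raises(ValueError, match="unknown variant"):
        summarize("step-99")
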