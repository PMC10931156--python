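"""Dense-block classifier: architecture arithmetic, training mechanics,
evaluation metrics and Grad-CAM."""

import numpy as np
import pytest

from optonose.nn import (
    ModelConfig,
    TrainConfig,
    build_model,
    evaluate,
    grad_cam,
    preprocess_images,
    report_from_predictions,
    softmax_cross_entropy,
    split_dataset,
    train,
)
from optonose.nn.train import TrainState


TINY = ModelConfig(input_side=16)


def _toy_batch(rng, n=20, side=16, classes=10):
    x = rng.normal(size=(n, 3, side, side)).astype(np.float32)
    y = np.concatenate([np.arange(classes)] * (n // classes))
    return x, y[:n]


# --- architecture ------------------------------------------------------

def test_dense_block_adds_96_channels(rng):
    # 3 layers x growth 32 concatenated onto the input
    from optonose.nn.model import DenseBlock

    block = DenseBlock(40, 3, 32, 3, rng, name="b")
    x = rng.normal(size=(2, 40, 8, 8)).astype(np.float32)
    y = block.forward(x, train=True)
    assert y.shape == (2, 40 + 96, 8, 8)
    assert block.cout == 136


def test_transition_halves_spatial_side(rng):
    from optonose.nn.model import Transition

    t = Transition(64, 0.5, rng, name="t")
    x = rng.normal(size=(2, 64, 16, 16)).astype(np.float32)
    y = t.forward(x, train=True)
    assert y.shape == (2, 32, 8, 8)


def test_channel_trace_follows_dense_concatenation_arithmetic():
    model = build_model(ModelConfig(), seed=0)
    # stem 32; +96 per block; transitions floor(c/2)
    assert model.channel_trace() == [32, 128, 64, 160, 80, 176, 88, 184, 92, 188]


def test_parameter_count_is_seed_invariant():
    a = build_model(ModelConfig(), seed=0)
    b = build_model(ModelConfig(), seed=99)
    assert a.n_parameters() == b.n_parameters()


def test_full_scale_forward_emits_10_scores(rng):
    model = build_model(ModelConfig(input_side=255), seed=0)
    x = rng.normal(size=(1, 3, 255, 255)).astype(np.float32)
    assert model.forward(x, train=False).shape == (1, 10)


def test_empty_spp_levels_rejected():
    with pytest.raises(ValueError, match="spp_levels"):
        ModelConfig(spp_levels=())


# --- training mechanics ------------------------------------------------

def test_initial_balanced_cross_entropy_is_ln_k(rng):
    model = build_model(TINY, seed=0)
    x, y = _toy_batch(rng, n=40)
    loss, _, _ = softmax_cross_entropy(model.forward(x, train=True), y)
    assert loss == pytest.approx(np.log(10), rel=0.05)


def test_zero_epoch_training_is_a_no_op(rng):
    model = build_model(TINY, seed=0)
    before = {p.name: p.value.copy() for p in model.params()}
    x, y = _toy_batch(rng)
    state = train(model, x, y, TrainConfig(epochs=0, seed=0))
    assert state.history.empty
    for p in model.params():
        assert np.array_equal(p.value, before[p.name])


def test_missing_class_raises_with_class_listed(rng):
    model = build_model(TINY, seed=0)
    x, y = _toy_batch(rng)
    y = np.where(y == 7, 6, y)
    with pytest.raises(ValueError, match=r"\[7\]"):
        train(model, x, y, TrainConfig(epochs=1, seed=0))


def test_identical_seeds_give_identical_training(rng):
    x, y = _toy_batch(rng, n=20)
    histories = []
    for _ in range(2):
        model = build_model(TINY, seed=3)
        state = train(model, x, y, TrainConfig(epochs=2, seed=5, batch_size=8))
        histories.append(state.history)
    assert histories[0].equals(histories[1])


def test_training_is_resumable(rng):
    x, y = _toy_batch(rng, n=20)
    model = build_model(TINY, seed=3)
    cfg = TrainConfig(epochs=2, seed=5, batch_size=8)
    st = train(model, x, y, cfg, epochs=1)
    st = train(model, x, y, cfg, state=st, epochs=1)
    assert st.epochs_done == 2
    assert list(st.history["epoch"]) == [0, 1]


def test_lr_schedule_is_nonincreasing():
    cfg = TrainConfig(epochs=20)
    lrs = [cfg.lr_at(e) for e in range(20)]
    assert all(b <= a for a, b in zip(lrs, lrs[1:]))
    assert lrs[0] == 0.01 and lrs[-1] == 0.001


# --- splitting ---------------------------------------------------------

@pytest.mark.parametrize("n,expected_train", [(20, 17), (21, 18), (40, 34)])
def test_split_ratio_rounds_toward_train(n, expected_train):
    labels = split_dataset(n, (17, 3), seed=0)
    assert (labels == "train").sum() == expected_train
    assert (labels == "val").sum() == n - expected_train


def test_split_is_seed_deterministic():
    assert np.array_equal(split_dataset(50, (17, 3), seed=4),
                          split_dataset(50, (17, 3), seed=4))
    assert not np.array_equal(split_dataset(50, (17, 3), seed=4),
                              split_dataset(50, (17, 3), seed=5))


# --- evaluation metrics ------------------------------------------------

def test_perfect_predictor_scores_100_and_f1_1(rng):
    y = rng.integers(0, 10, 50)
    rep = report_from_predictions(y, y, tuple(str(i) for i in range(10)))
    assert rep.accuracy == 100.0
    # only classes present have support; absent classes score 0 by the
    # p + r = 0 convention, so restrict to present classes
    present = np.unique(y)
    assert np.allclose(rep.f1_per_class[present], 1.0)


def test_single_class_predictor_on_balanced_data_scores_10pct():
    y = np.repeat(np.arange(10), 5)
    pred = np.zeros_like(y)
    rep = report_from_predictions(y, pred, tuple(str(i) for i in range(10)))
    assert rep.accuracy == pytest.approx(10.0)


def test_macro_f1_equals_mean_recall_when_p_equals_r():
    # symmetric confusion: every class has p = r, so F1 = p = r per class
    confusion = np.full((4, 4), 2, dtype=int) + np.diag([10, 10, 10, 10])
    from optonose.nn.train import EvalReport

    rep = EvalReport(confusion=confusion, classes=("a", "b", "c", "d"))
    assert np.allclose(rep.precision, rep.recall)
    assert rep.macro_f1 == pytest.approx(rep.recall.mean())


def test_f1_zero_when_class_never_predicted_nor_present():
    confusion = np.zeros((3, 3), dtype=int)
    confusion[0, 0] = 5
    confusion[1, 0] = 3  # class 1 never predicted correctly; class 2 absent
    from optonose.nn.train import EvalReport

    rep = EvalReport(confusion=confusion, classes=("a", "b", "c"))
    assert rep.f1_per_class[1] == 0.0 and rep.f1_per_class[2] == 0.0


def test_report_matches_sklearn_on_random_confusions(rng):
    from sklearn.metrics import f1_score, precision_score, recall_score

    for _ in range(20):
        y = rng.integers(0, 5, 60)
        pred = rng.integers(0, 5, 60)
        rep = report_from_predictions(y, pred, tuple("abcde"))
        labels = list(range(5))
        assert np.allclose(rep.precision,
                           precision_score(y, pred, labels=labels, average=None,
                                           zero_division=0))
        assert np.allclose(rep.recall,
                           recall_score(y, pred, labels=labels, average=None,
                                        zero_division=0))
        assert rep.macro_f1 == pytest.approx(
            f1_score(y, pred, labels=labels, average="macro", zero_division=0))


def test_evaluate_empty_split_rejected(rng):
    model = build_model(TINY, seed=0)
    with pytest.raises(ValueError, match="empty"):
        evaluate(model, np.empty((0, 3, 16, 16), np.float32), np.empty(0, int), ("a",))


# --- Grad-CAM ----------------------------------------------------------

def test_gradcam_extent_and_nonnegativity(rng):
    model = build_model(TINY, seed=0)
    img = rng.normal(size=(3, 16, 16)).astype(np.float32)
    cam = grad_cam(model, img, target_class=3)
    assert cam.shape == (16, 16)
    assert (cam >= 0).all() and np.isfinite(cam).all()


def test_gradcam_on_zero_input_is_finite(rng):
    model = build_model(TINY, seed=0)
    cam = grad_cam(model, np.zeros((3, 16, 16), np.float32), target_class=0)
    assert np.isfinite(cam).all()


def test_gradcam_rejects_bad_class(rng):
    model = build_model(TINY, seed=0)
    img = rng.normal(size=(3, 16, 16)).astype(np.float32)
    with pytest.raises(ValueError, match="class index"):
        grad_cam(model, img, target_class=10)
    with pytest.raises(ValueError, match="one"):
        grad_cam(model, img[None], target_class=0)


def test_gradcam_localizes_planted_responsive_dyes():
    # two-class toy in which only three adjacent dyes respond to the gas:
    # at least 60 % of the top-decile relevance mass must fall on their tiles
    from dataclasses import replace

    from optonose.nn.train import predict
    from optonose.synth import DyeSpec, make_dye_library, random_scene, render_array_image

    base = make_dye_library(3)
    planted = {0, 1, 5}
    lib = []
    for d in base:
        sens = {}
        for voc, (shift, k) in d.sensitivity.items():
            if voc == "ethanol" and d.dye_id in planted:
                sens[voc] = (np.array([70.0, -60.0, 50.0]), 40.0)
            else:
                sens[voc] = (np.zeros(3), k)
        lib.append(DyeSpec(d.dye_id, d.name, d.dye_class, d.baseline_rgb, sens))

    scene_rng = np.random.default_rng(0)
    imgs, labels = [], []
    for i in range(160):
        gas = {} if i % 2 == 0 else {"ethanol": 300.0}
        imgs.append(render_array_image(lib, gas, random_scene(scene_rng, "easy"),
                                       seed=1000 + i, side=80))
        labels.append(i % 2)
    x = preprocess_images(imgs, side=40)
    y = np.array(labels)
    cfg = ModelConfig(num_dense_blocks=2, layers_per_block=2, growth_rate=8,
                      stem_channels=8, spp_levels=(1, 2), num_classes=2, input_side=40)
    model = build_model(cfg, seed=1)
    train(model, x, y, TrainConfig(epochs=10, seed=2, batch_size=8))
    assert (predict(model, x) == y).mean() == 1.0

    pitch = 0.5 * (1 - 0.24) * 80 / 6  # tile half-width in input pixels
    yy, xx = np.mgrid[0:40, 0:40]
    fracs = []
    for pos in [i for i in range(160) if labels[i] == 1][:4]:
        cam = grad_cam(model, x[pos], 1)
        centers = imgs[pos].spot_centers * 0.5
        mask = np.zeros((40, 40), bool)
        for sid in planted:
            r, c = centers[sid]
            mask |= (np.abs(yy - r) <= pitch / 2) & (np.abs(xx - c) <= pitch / 2)
        top = cam >= np.quantile(cam, 0.9)
        fracs.append(cam[top & mask].sum() / max(cam[top].sum(), 1e-9))
    assert np.mean(fracs) >= 0.6


def test_preprocess_shapes_and_full_scale(blank_image):
    x = preprocess_images([blank_image], side=32)
    assert x.shape == (1, 3, 32, 32) and x.dtype == np.float32
    assert x.min() >= -0.5 and x.max() <= 0.5
    xp = preprocess_images([blank_image], full_scale=True)
    assert xp.shape == (1, 3, 255, 255)
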