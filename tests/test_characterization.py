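"""Characterizer: slice selection, cropping, head isolation, gradient
routing, and evidence fusion."""

import numpy as np
import pytest

from lirads_auto import nn
from lirads_auto.characterization import (
    CharConfig,
    CharSample,
    CharTrainParams,
    LesionCrop,
    build_characterizer,
    crop_resize,
    predict_features,
    select_representative_slice,
    train_multitask,
)


def test_select_representative_slice():
    stack = np.zeros((3, 6, 6), dtype=np.uint8)
    stack[0, :1, :5] = 1   # area 5
    stack[1, :4, :5] = 1   # area 20
    stack[2, :1, :7] = 1   # area 6 (clipped to 6 cols)
    assert select_representative_slice(stack) == 1
    tie = np.zeros((2, 3, 3), dtype=np.uint8)
    tie[0, 0, :] = 1
    tie[1, 0, :] = 1
    assert select_representative_slice(tie) == 0  # ties -> lowest index
    with pytest.raises(ValueError, match="no lesion"):
        select_representative_slice(np.zeros((3, 4, 4), dtype=np.uint8))


def test_crop_resize_shape_and_margin():
    rng = np.random.default_rng(0)
    img = rng.normal(size=(512, 512))
    comp = np.zeros((512, 512), dtype=bool)
    comp[230:280, 230:280] = True  # 50-px blob
    out = crop_resize(img, comp, out_size=224)
    assert out.shape == (224, 224)
    assert out.std() == pytest.approx(1.0)
    # margin 0.2 on a 100-px box -> 120-px box: with out_size=120 the resize
    # is the identity, so a row-ramp image stays an exact linear ramp
    ramp = np.tile(np.arange(512.0)[:, None], (1, 512))
    comp = np.zeros((512, 512), dtype=bool)
    comp[200:300, 200:300] = True
    out = crop_resize(ramp, comp, margin=0.2, out_size=120)
    diffs = np.diff(out[:, 0])
    assert np.allclose(diffs, diffs[0])  # uniform step = un-resized crop
    # constant image crops to a constant
    const = crop_resize(np.ones((64, 64)), np.eye(64, dtype=bool), out_size=32)
    np.testing.assert_allclose(const, 0.0, atol=1e-12)
    # 1-px component still crops
    single = np.zeros((32, 32), dtype=bool)
    single[5, 5] = True
    assert crop_resize(rng.normal(size=(32, 32)), single, out_size=16).shape == (16, 16)


def test_phase_indicator_consistency():
    img = np.zeros((8, 8))
    LesionCrop(image=img, phase_indicator=0, lesion_id="L", source_phase="arterial")
    LesionCrop(image=img, phase_indicator=1, lesion_id="L", source_phase="delayed")
    with pytest.raises(ValueError):
        LesionCrop(image=img, phase_indicator=1, lesion_id="L", source_phase="arterial")


def test_heads_are_parameter_disjoint():
    model = build_characterizer(CharConfig(input_size=8, widths=(4,), hidden=8))
    x = np.random.default_rng(1).normal(size=(2, 1, 8, 8))
    before = model.forward(x).copy()
    for p in model.head_params("washout"):
        p.value[...] = 0.0
    after = model.forward(x)
    assert not np.allclose(before[:, 1], after[:, 1])
    np.testing.assert_array_equal(before[:, 0], after[:, 0])
    np.testing.assert_array_equal(before[:, 2], after[:, 2])


def _snapshot(params):
    return [p.value.copy() for p in params]


def _make_samples(rng, n, x_value):
    out = []
    for _ in range(n):
        img = rng.normal(size=(8, 8))
        if x_value == 0:
            labels = {"aphe": int(rng.random() < 0.5)}
        else:
            labels = {"washout": int(rng.random() < 0.5),
                      "capsule": int(rng.random() < 0.5)}
        out.append(CharSample(image=img, x=x_value, labels=labels))
    return out


def test_gradient_routing_head_isolation():
    """An arterial-only step leaves washout/capsule heads bit-identical (and
    symmetrically for a PV/delayed-only step and the APHE head); the backbone
    moves in both cases."""
    rng = np.random.default_rng(2)
    cfg = CharConfig(input_size=8, widths=(4,), hidden=8)
    params = CharTrainParams(steps=1, batch_size=4, seed=0)

    model = build_characterizer(cfg)
    wash_before = _snapshot(model.head_params("washout"))
    caps_before = _snapshot(model.head_params("capsule"))
    backbone_before = _snapshot(model.backbone.params())
    train_multitask(model, _make_samples(rng, 4, x_value=0), params)
    for before, p in zip(wash_before + caps_before,
                         model.head_params("washout") + model.head_params("capsule")):
        np.testing.assert_array_equal(before, p.value)
    assert any((b != p.value).any() for b, p in zip(backbone_before, model.backbone.params()))

    model = build_characterizer(cfg)
    aphe_before = _snapshot(model.head_params("aphe"))
    train_multitask(model, _make_samples(rng, 4, x_value=1), params)
    for before, p in zip(aphe_before, model.head_params("aphe")):
        np.testing.assert_array_equal(before, p.value)


def test_gradient_routing_random_mixtures():
    """Head isolation holds for arbitrary batch compositions: heads only move
    when some sample routes to them."""
    rng = np.random.default_rng(3)
    cfg = CharConfig(input_size=8, widths=(4,), hidden=8)
    for trial in range(3):
        xs = rng.integers(0, 2, size=6)
        samples = [
            _make_samples(rng, 1, x_value=int(x))[0] for x in xs
        ]
        model = build_characterizer(cfg)
        before = {f: _snapshot(model.head_params(f)) for f in ("aphe", "washout", "capsule")}
        train_multitask(model, samples,
                        CharTrainParams(steps=1, batch_size=6, seed=trial))
        routed = {"aphe": (xs == 0).any(), "washout": (xs == 1).any(),
                  "capsule": (xs == 1).any()}
        for f in before:
            changed = any((b != p.value).any()
                          for b, p in zip(before[f], model.head_params(f)))
            assert changed == routed[f], (trial, f, xs)


def test_training_rejects_contradictory_labels():
    sample = CharSample(image=np.zeros((8, 8)), x=0, labels={"washout": 1})
    model = build_characterizer(CharConfig(input_size=8, widths=(4,), hidden=8))
    with pytest.raises(ValueError, match="washout"):
        train_multitask(model, [sample], CharTrainParams(steps=1))
    with pytest.raises(ValueError, match="all three"):
        train_multitask(model, [CharSample(image=np.zeros((8, 8)), x=0,
                                           labels={"aphe": 1})],
                        CharTrainParams(steps=1), adaptive=False)


class _StubModel:
    """Returns fixed per-feature probabilities keyed by the crop's mean value."""

    def __init__(self, table):
        self.table = table

    def forward(self, x):
        keys = np.round(x.mean(axis=(1, 2, 3))).astype(int)
        return np.stack([self.table[int(k)] for k in keys])


def _crop(value, phase):
    return LesionCrop(
        image=np.full((8, 8), float(value)),
        phase_indicator=0 if phase == "arterial" else 1,
        lesion_id="L0",
        source_phase=phase,
    )


def test_predict_features_fusion_threshold_and_errors():
    table = {
        0: np.array([0.9, 0.0, 0.0]),   # arterial crop
        1: np.array([0.0, 0.4, 0.8]),   # portal venous crop
        2: np.array([0.0, 0.7, 0.5]),   # delayed crop
    }
    model = _StubModel(table)
    crops = [_crop(0, "arterial"), _crop(1, "portal_venous"), _crop(2, "delayed")]
    prof = predict_features(model, crops, size_mm=15.0)
    assert prof.p_aphe == pytest.approx(0.9)
    assert prof.p_washout == pytest.approx(0.7)   # max over PV=0.4, delayed=0.7
    assert prof.p_capsule == pytest.approx(0.8)
    assert (prof.B1, prof.B2, prof.B3) == (True, True, True)
    # order of PV/delayed crops does not matter
    prof2 = predict_features(model, [crops[0], crops[2], crops[1]], size_mm=15.0)
    assert (prof2.p_washout, prof2.p_capsule) == (prof.p_washout, prof.p_capsule)
    # exact threshold counts as a call (>= convention)
    table[2] = np.array([0.0, 0.5, 0.5])
    table[1] = np.array([0.0, 0.1, 0.1])
    prof3 = predict_features(model, crops, size_mm=15.0)
    assert prof3.B2 and prof3.B3
    # thresholding example p = (0.9, 0.2, 0.8) -> calls (1, 0, 1)
    table[1] = np.array([0.0, 0.2, 0.8])
    table[2] = np.array([0.0, 0.1, 0.1])
    prof4 = predict_features(model, crops, size_mm=15.0)
    assert (prof4.B1, prof4.B2, prof4.B3) == (True, False, True)
    with pytest.raises(ValueError, match="arterial"):
        predict_features(model, crops[1:], size_mm=15.0)
    with pytest.raises(ValueError, match="portal"):
        predict_features(model, crops[:1], size_mm=15.0)
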