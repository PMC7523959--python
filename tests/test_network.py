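"""Detector assembly: pyramid, fusion, RoI align, RPN decoding, losses."""

import numpy as np
import pytest

from fpfseg.core import ImagePair, InstanceSet
from fpfseg.network import (
    Detector,
    ModelConfig,
    assign_pyramid_level,
    decode_boxes,
    encode_boxes,
    fuse_pyramids,
    micro_config,
    nms,
    paste_mask,
)
from fpfseg.nn import SGD, Tensor, bce_with_logits, roi_align


def blank_pair(size=128):
    return ImagePair(nucleus=np.zeros((size, size), np.float32),
                     cell=np.zeros((size, size), np.float32))


@pytest.fixture(scope="module")
def cell_model():
    return Detector(micro_config(seed=3))


@pytest.fixture(scope="module")
def scene_pair(micro_scene):
    return micro_scene.image_pair


class TestPyramid:
    def test_level_shapes_and_width(self, cell_model):
        pyr = cell_model.pyramid(blank_pair(256))
        for lev, size in zip(("P2", "P3", "P4", "P5", "P6"), (64, 32, 16, 8, 4)):
            assert pyr[lev].data.shape == (1, 128, size, size)

    def test_zero_input_zero_free_pyramid_is_finite(self, cell_model):
        pyr = cell_model.pyramid(blank_pair(128))
        for lev in pyr:
            assert np.isfinite(pyr[lev].data).all()


class TestFusion:
    def test_add_with_zero_nucleus_is_identity(self):
        rng = np.random.default_rng(0)
        cell = {f"P{i}": Tensor(rng.standard_normal((1, 8, 16, 16)).astype(np.float32))
                for i in range(2, 7)}
        zero = {f"P{i}": Tensor(np.zeros((1, 8, 16, 16), np.float32)) for i in range(2, 7)}
        fused = fuse_pyramids(cell, zero, "add")
        for lev in cell:
            assert np.array_equal(fused[lev].data, cell[lev].data)

    def test_concat_doubles_width(self):
        cell = {f"P{i}": Tensor(np.ones((1, 8, 4, 4), np.float32)) for i in range(2, 7)}
        fused = fuse_pyramids(cell, cell, "concat", projections=None)
        assert all(fused[lev].data.shape[1] == 16 for lev in fused)

    def test_spatial_mismatch_rejected(self):
        a = {f"P{i}": Tensor(np.ones((1, 8, 4, 4), np.float32)) for i in range(2, 7)}
        b = {f"P{i}": Tensor(np.ones((1, 8, 5, 5), np.float32)) for i in range(2, 7)}
        with pytest.raises(ValueError):
            fuse_pyramids(a, b, "add")

    def test_fpf_add_equals_cell_only_logits(self, micro_scene):
        """With an all-zero nucleus pyramid and add-merge, the fused model's
        RPN logits equal those of a cell-only model with identical weights."""
        nucleus = Detector(micro_config(seed=7, input_channel="nucleus"), prefix="nucleus")
        # zero every FPN parameter of the nucleus branch -> zero pyramid
        for p in nucleus.fpn.parameters():
            p.data = np.zeros_like(p.data)
        fpf = Detector(micro_config(seed=5, variant="fpf", merge_mode="add"),
                       nucleus_model=nucleus)
        plain = Detector(micro_config(seed=5))
        pair = micro_scene.image_pair
        o1, r1, _, _ = fpf.rpn_forward(fpf.pyramid(pair))
        o2, r2, _, _ = plain.rpn_forward(plain.pyramid(pair))
        assert np.allclose(o1.data, o2.data, atol=1e-5)
        assert np.allclose(r1.data, r2.data, atol=1e-5)

    def test_nucleus_branch_frozen_through_training_step(self, micro_scene):
        nucleus = Detector(micro_config(seed=1, input_channel="nucleus"), prefix="nucleus")
        model = Detector(micro_config(seed=2, variant="fpf", merge_mode="concat"),
                         nucleus_model=nucleus)
        before = {p.name: p.data.copy() for p in nucleus.parameters()}
        cell_before = {p.name: p.data.copy() for p in model.parameters()
                       if p.name.startswith("cell")}
        opt = SGD(model.parameters(), lr=1e-3, momentum=0.9)
        rng = np.random.default_rng(0)
        for _ in range(2):
            model.zero_grad()
            bundle = model.loss_step(micro_scene.image_pair, micro_scene.cell_truth, rng=rng)
            bundle.total.backward()
            opt.step()
        after = {p.name: p.data for p in nucleus.parameters()}
        assert all(np.array_equal(before[k], after[k]) for k in before)
        changed = sum(
            not np.array_equal(cell_before[p.name], p.data)
            for p in model.parameters() if p.name.startswith("cell")
        )
        assert changed > 0


class TestLevelAssignment:
    @pytest.mark.parametrize("box,expected", [
        ((0, 0, 224, 224), 4),
        ((0, 0, 112, 112), 3),
        ((0, 0, 1000, 1000), 5),
        ((0, 0, 8, 8), 2),
        ((5, 5, 5, 9), 2),          # degenerate, zero area
    ])
    def test_formula(self, box, expected):
        assert assign_pyramid_level(np.array(box, float)) == expected


class TestRoIAlign:
    def test_constant_map(self):
        feat = Tensor(np.full((1, 3, 20, 20), 2.5, np.float32))
        out = roi_align(feat, np.array([[2.0, 3.0, 14.0, 17.0]]), 7)
        assert out.data.shape == (1, 3, 7, 7)
        assert np.allclose(out.data, 2.5)

    def test_linear_ramp_closed_form(self):
        yy, xx = np.mgrid[0:32, 0:32]
        plane = (1.5 * yy - 0.7 * xx + 3.0).astype(np.float32)
        feat = Tensor(plane[None, None])
        box = np.array([[4.0, 6.0, 20.0, 30.0]])
        out = roi_align(feat, box, 4).data[0, 0]
        bh, bw = (30 - 6) / 4, (20 - 4) / 4
        ys = 6 + (np.arange(4) + 0.5) * bh - 0.5
        xs = 4 + (np.arange(4) + 0.5) * bw - 0.5
        expected = 1.5 * ys[:, None] - 0.7 * xs[None, :] + 3.0
        assert np.allclose(out, expected, atol=1e-4)

    def test_output_sizes_for_heads(self):
        feat = Tensor(np.zeros((1, 2, 16, 16), np.float32))
        assert roi_align(feat, np.array([[0.0, 0.0, 8.0, 8.0]]), 7).data.shape[-2:] == (7, 7)
        assert roi_align(feat, np.array([[0.0, 0.0, 8.0, 8.0]]), 14).data.shape[-2:] == (14, 14)

    def test_non_positive_box_rejected(self):
        feat = Tensor(np.zeros((1, 1, 8, 8), np.float32))
        with pytest.raises(ValueError):
            roi_align(feat, np.array([[4.0, 2.0, 4.0, 6.0]]), 7)


class TestRPN:
    def test_anchor_encode_decode_round_trip(self):
        rng = np.random.default_rng(0)
        anchors = np.stack([
            rng.uniform(0, 50, 20), rng.uniform(0, 50, 20),
            rng.uniform(60, 120, 20), rng.uniform(60, 120, 20)], axis=1)
        gt = anchors + rng.uniform(-5, 5, anchors.shape)
        decoded = decode_boxes(encode_boxes(gt, anchors), anchors)
        assert np.abs(decoded - gt).max() < 1e-4

    def test_untrained_proposals_deterministic(self, cell_model, scene_pair):
        from fpfseg.network import rpn_propose

        a = rpn_propose(cell_model, scene_pair)
        b = rpn_propose(cell_model, scene_pair)
        assert np.array_equal(a, b)

    def test_nms_suppresses_overlaps(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [20, 20, 30, 30]], float)
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.5)
        assert list(keep) == [0, 2]


class TestLosses:
    def test_perfect_mask_logits_vanish(self):
        target = np.zeros((1, 4, 4), np.float32)
        target[0, :2] = 1.0
        logits = Tensor(np.where(target > 0, 30.0, -30.0).astype(np.float32))
        assert float(bce_with_logits(logits, target).data) < 1e-8

    def test_bce_ln2_closed_form(self):
        loss = bce_with_logits(Tensor(np.zeros((2, 2), np.float32)),
                               np.array([[1, 0], [0, 1]], np.float32))
        assert float(loss.data) == pytest.approx(np.log(2), rel=1e-6)

    def test_loss_bundle_weighting(self, cell_model, micro_scene):
        bundle = cell_model.loss_step(micro_scene.image_pair, micro_scene.cell_truth,
                                      rng=np.random.default_rng(0))
        f = bundle.as_floats()
        expected = (f["rpn_cls"] + 2 * f["rpn_box"] + f["cls"]
                    + 2 * f["box"] + 2 * f["mask"])
        assert f["total"] == pytest.approx(expected, rel=1e-6)
        assert float(bundle.total.data) == pytest.approx(expected, rel=1e-5)


class TestPredict:
    def test_blank_input_smoke(self, cell_model):
        dets = cell_model.predict(blank_pair(128))
        assert len(dets) <= 100

    def test_inference_deterministic(self, cell_model, scene_pair):
        a = cell_model.predict(scene_pair)
        b = cell_model.predict(scene_pair)
        assert len(a) == len(b)
        assert np.array_equal(a.boxes, b.boxes)
        for ma, mb in zip(a.masks, b.masks):
            assert np.array_equal(ma, mb)

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ImagePair(nucleus=np.zeros((64, 64)), cell=np.zeros((64, 32)))


class TestPasteMask:
    def test_area_preserved_within_rounding(self):
        rng = np.random.default_rng(2)
        prob = rng.random((28, 28)).astype(np.float32)
        box = np.array([10.0, 12.0, 66.0, 68.0])
        pasted = paste_mask(prob, box, (96, 96))
        box_area_frac = (prob >= 0.5).mean()
        pasted_frac = pasted.sum() / (56 * 56)
        assert abs(pasted_frac - box_area_frac) < 0.1

    def test_paste_confined_to_box(self):
        prob = np.ones((28, 28), np.float32)
        pasted = paste_mask(prob, np.array([4.0, 6.0, 12.0, 14.0]), (32, 32))
        ys, xs = np.nonzero(pasted)
        assert ys.min() >= 6 and ys.max() < 14 and xs.min() >= 4 and xs.max() < 12
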