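"""Segmentation and focus detection against generator truth and constructed
fixtures."""

import numpy as np
import pandas as pd
import pytest

from lymphofoci.segmentation import (DiffuseConfig, FociConfig, ImageField,
                                     SegmentationConfig, detect_foci,
                                     diffuse_metrics, project_zstack,
                                     segment_nuclei)
from lymphofoci.synthetic import (TABLE1_PARAMS, RenderParams,
                                  compose_nucleus_truths, render_if_image)
from conftest import single_nucleus_truth


class TestProjectZstack:
    def test_single_frame_identity(self):
        f = np.random.default_rng(0).uniform(size=(16, 16))
        np.testing.assert_array_equal(project_zstack([f]), f)

    def test_zero_frame_is_ignored(self):
        f = np.random.default_rng(1).uniform(size=(8, 8))
        np.testing.assert_array_equal(project_zstack([f, np.zeros((8, 8))]), f)

    def test_elementwise_maximum_oracle(self):
        rng = np.random.default_rng(2)
        stack = rng.uniform(size=(5, 12, 12))
        out = project_zstack(list(stack))
        for y in range(12):
            for x in range(12):
                assert out[y, x] == max(stack[:, y, x])

    def test_empty_and_ragged_stacks_raise(self):
        with pytest.raises(ValueError):
            project_zstack([])
        with pytest.raises(ValueError):
            project_zstack([np.zeros((4, 4)), np.zeros((5, 4))])


class TestSegmentNuclei:
    def test_recovers_fifty_rendered_nuclei(self, render_params):
        truth = compose_nucleus_truths("c", TABLE1_PARAMS["GC"], 15.0, 50,
                                       seed=21)
        channels, rendered = render_if_image(truth, render_params, seed=22)
        field = ImageField(channels, render_params.pixel_size)
        masks = segment_nuclei(field)
        assert len(masks) == 50
        centers = rendered.nuclei[
            ["center_y_px", "center_x_px"]].to_numpy() * render_params.pixel_size
        for m in masks:
            d = np.hypot(*(centers - np.asarray(m.centroid_um)).T)
            assert d.min() <= 1.0

    def test_blank_dapi_warns_and_returns_empty(self):
        field = ImageField({"DAPI": np.zeros((64, 64))}, 0.1)
        with pytest.warns(UserWarning, match="blank"):
            assert segment_nuclei(field) == []

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((200, 200))
        yy, xx = np.mgrid[0:200, 0:200]
        img[(yy - 100) ** 2 + (xx - 80) ** 2 <= 26**2] = 100.0
        img[(yy - 100) ** 2 + (xx - 134) ** 2 <= 26**2] = 100.0   # touching
        field = ImageField({"DAPI": img}, 0.1)
        masks = segment_nuclei(field)
        assert len(masks) == 2

    def test_min_area_and_border_filters(self):
        img = np.zeros((200, 200))
        yy, xx = np.mgrid[0:200, 0:200]
        img[(yy - 100) ** 2 + (xx - 100) ** 2 <= 25**2] = 100.0  # keep
        img[(yy - 40) ** 2 + (xx - 40) ** 2 <= 8**2] = 100.0     # too small
        img[(yy - 5) ** 2 + (xx - 150) ** 2 <= 25**2] = 100.0    # on border
        field = ImageField({"DAPI": img}, 0.1)
        masks = segment_nuclei(field)
        assert len(masks) == 1
        assert abs(masks[0].centroid_um[0] - 10.0) < 0.5


class TestDetectFoci:
    def test_three_half_micron_foci(self, small_render_params):
        truth = single_nucleus_truth("highDDR", [0.5, 0.5, 0.5])
        channels, _ = render_if_image(truth, small_render_params, seed=101)
        field = ImageField(channels, small_render_params.pixel_size)
        foci = detect_foci(field, segment_nuclei(field))
        assert len(foci) == 3
        for f in foci:
            assert 0.35 <= f.diameter_um <= 0.65

    def test_focus_free_nucleus_has_no_detections(self, small_render_params):
        channels, _ = render_if_image(single_nucleus_truth("stable", []),
                                      small_render_params, seed=102)
        field = ImageField(channels, small_render_params.pixel_size)
        assert detect_foci(field, segment_nuclei(field)) == []

    def test_large_focus_crosses_micron_boundary(self, small_render_params):
        channels, _ = render_if_image(single_nucleus_truth("largeFocus", [1.4]),
                                      small_render_params, seed=103)
        field = ImageField(channels, small_render_params.pixel_size)
        foci = detect_foci(field, segment_nuclei(field))
        assert max(f.diameter_um for f in foci) >= 1.0

    def test_every_focus_centroid_inside_its_nucleus(
            self, rendered_field_with_truth):
        field, _ = rendered_field_with_truth
        masks = segment_nuclei(field)
        by_id = {m.nucleus_id: m for m in masks}
        foci = detect_foci(field, masks)
        assert foci
        for f in foci:
            m = by_id[f.nucleus_id]
            y, x = (c / field.pixel_size for c in f.centroid_um)
            assert m.contains_px(y, x)

    def test_translation_equivariance(self, small_render_params):
        truth = single_nucleus_truth("highDDR", [0.5, 0.6, 0.7])
        channels, _ = render_if_image(truth, small_render_params, seed=104)
        dy, dx = 7, 5
        shifted = {k: np.roll(v, (dy, dx), axis=(0, 1))
                   for k, v in channels.items()}
        px = small_render_params.pixel_size
        f0 = ImageField(channels, px)
        f1 = ImageField(shifted, px)
        d0 = sorted((f.centroid_um for f in detect_foci(f0, segment_nuclei(f0))))
        d1 = sorted((f.centroid_um for f in detect_foci(f1, segment_nuclei(f1))))
        assert len(d0) == len(d1) == 3
        for (y0, x0), (y1, x1) in zip(d0, d1):
            assert abs(y1 - y0 - dy * px) < 1e-9
            assert abs(x1 - x0 - dx * px) < 1e-9

    def test_intensity_scaling_invariance(self, small_render_params):
        truth = single_nucleus_truth("highDDR", [0.4, 0.5, 0.6, 0.7])
        channels, _ = render_if_image(truth, small_render_params, seed=105)
        px = small_render_params.pixel_size
        f0 = ImageField(channels, px)
        f2 = ImageField({k: 2.0 * v for k, v in channels.items()}, px)
        n0 = len(detect_foci(f0, segment_nuclei(f0)))
        n2 = len(detect_foci(f2, segment_nuclei(f2)))
        assert n0 >= 3
        assert n0 == n2

    def test_missing_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            ImageField({"53BP1": np.zeros((8, 8))}, pixel_size=0.0)


class TestDiffuseMetrics:
    @staticmethod
    def _one_mask(field):
        masks = segment_nuclei(field)
        assert len(masks) == 1
        return masks[0]

    def test_uniform_zero_signal(self):
        dapi = np.zeros((96, 96))
        yy, xx = np.mgrid[0:96, 0:96]
        dapi[(yy - 48) ** 2 + (xx - 48) ** 2 <= 28**2] = 100.0
        field = ImageField({"DAPI": dapi, "53BP1": np.zeros((96, 96))}, 0.1)
        cov, het = diffuse_metrics(field, self._one_mask(field))
        assert cov == 0.0 and het == 0.0

    def test_saturated_nucleus(self):
        dapi = np.zeros((96, 96))
        yy, xx = np.mgrid[0:96, 0:96]
        inside = (yy - 48) ** 2 + (xx - 48) ** 2 <= 28**2
        dapi[inside] = 100.0
        sig = np.zeros((96, 96))
        sig[inside] = 250.0
        field = ImageField({"DAPI": dapi, "53BP1": sig}, 0.1)
        cov, het = diffuse_metrics(field, self._one_mask(field))
        assert cov == 1.0 and het == pytest.approx(0.0, abs=1e-12)

    def test_rendered_diffuse_nucleus_exceeds_coverage_floor(
            self, small_render_params):
        for seed in range(5):
            channels, _ = render_if_image(single_nucleus_truth("diffuse", []),
                                          small_render_params, seed=seed)
            field = ImageField(channels, small_render_params.pixel_size)
            cov, het = diffuse_metrics(field, self._one_mask(field))
            assert cov >= small_render_params.diffuse_coverage
            assert het >= 0.3
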