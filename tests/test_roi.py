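"""Mean images, smoothing, kernel extraction, sensitivity and digitization."""

from __future__ import annotations

import numpy as np
import pytest

from elefoot.errors import DigitizationError, GeometryError
from elefoot.pressure_io import PlateSpec
from elefoot.register import PeakPressureImage, TemplateImage, peak_pressure_image
from elefoot.roi import (
    ROI_NAMES,
    ROISet,
    digitize_rois,
    extract_roi_peak,
    mean_image,
    sensitivity_table,
    smooth_gaussian,
)

SPEC = PlateSpec(n_cols=20, n_rows=24, width_m=0.275, length_m=0.318, freq_hz=100)


def _img(values) -> PeakPressureImage:
    return PeakPressureImage(values=np.asarray(values, float), spec=SPEC)


def _kernel_weight_00() -> float:
    """Normalized centre weight of the 3x3 sigma-1 kernel, computed directly."""
    total = sum(
        np.exp(-(dr * dr + dc * dc) / 2.0) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
    )
    return 1.0 / total


class TestMeanImage:
    def test_identical_images_unchanged(self):
        img = _img(np.random.default_rng(0).uniform(0, 50, SPEC.shape))
        out = mean_image([img, img, img])
        assert np.allclose(out.values, img.values)

    def test_two_values_average(self):
        a = _img(np.zeros(SPEC.shape))
        b = _img(np.full(SPEC.shape, 100.0))
        assert np.allclose(mean_image([a, b]).values, 50.0)

    def test_matches_direct_loop(self):
        rng = np.random.default_rng(1)
        imgs = [_img(rng.uniform(0, 300, SPEC.shape)) for _ in range(5)]
        out = mean_image(imgs)
        for r in range(0, 24, 7):
            for c in range(0, 20, 5):
                assert out.values[r, c] == pytest.approx(
                    sum(i.values[r, c] for i in imgs) / 5
                )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_image([])


class TestSmoothGaussian:
    def test_sigma_zero_is_identity(self):
        img = _img(np.random.default_rng(2).uniform(0, 50, SPEC.shape))
        assert np.array_equal(smooth_gaussian(img, 0.0).values, img.values)

    def test_constant_preserved(self):
        img = _img(np.full(SPEC.shape, 42.0))
        assert np.allclose(smooth_gaussian(img, 2.0).values, 42.0)

    def test_impulse_matches_direct_convolution(self):
        values = np.zeros(SPEC.shape)
        values[12, 10] = 1.0
        out = smooth_gaussian(_img(values), 1.0)
        # direct truncated-kernel oracle (radius 4, as scipy truncates at 4 sigma)
        ax = np.arange(-4, 5)
        k1 = np.exp(-(ax**2) / 2.0)
        k1 /= k1.sum()
        k2 = np.outer(k1, k1)
        assert out.values[12, 10] == pytest.approx(k2[4, 4], rel=1e-6)
        assert out.values[12, 11] == pytest.approx(k2[4, 5], rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(_img(np.zeros(SPEC.shape)), -1.0)


class TestExtractRoiPeak:
    def test_constant_image_returns_constant(self):
        img = _img(np.full(SPEC.shape, 37.5))
        for point in [(5, 5), (12, 10), (22, 18)]:
            assert extract_roi_peak(img, point) == pytest.approx(37.5)

    def test_isolated_centre_value_weighted_by_w00(self):
        values = np.zeros(SPEC.shape)
        values[12, 10] = 200.0
        assert extract_roi_peak(_img(values), (12, 10)) == pytest.approx(
            200.0 * _kernel_weight_00()
        )

    def test_matches_bruteforce_weighted_sum(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 300, SPEC.shape)
        img = _img(values)
        w = np.array(
            [
                [np.exp(-(dr * dr + dc * dc) / 2.0) for dc in (-1, 0, 1)]
                for dr in (-1, 0, 1)
            ]
        )
        w /= w.sum()
        for r, c in [(3, 3), (12, 10), (20, 15)]:
            expected = sum(
                w[dr + 1, dc + 1] * values[r + dr, c + dc]
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
            )
            assert extract_roi_peak(img, (r, c)) == pytest.approx(expected)

    def test_bounded_by_window_extremes(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 300, SPEC.shape)
        img = _img(values)
        v = extract_roi_peak(img, (10, 10))
        window = values[9:12, 9:12]
        assert window.min() <= v <= window.max()

    def test_border_window_rejected(self):
        img = _img(np.zeros(SPEC.shape))
        with pytest.raises(GeometryError):
            extract_roi_peak(img, (0, 5))


@pytest.fixture
def centre_rois() -> ROISet:
    pts = {
        "roi1": (18, 6),
        "roi2": (19, 8),
        "roi3": (20, 10),
        "roi4": (19, 12),
        "roi5": (18, 14),
        "roi6": (12, 10),
        "roi7": (5, 10),
    }
    return ROISet(foot_label="FR", points=pts)


class TestSensitivityTable:
    def test_constant_image_all_35_equal(self, centre_rois):
        img = _img(np.full(SPEC.shape, 64.0))
        table = sensitivity_table(img, centre_rois)
        assert len(table) == 35
        assert np.allclose(table["peak_pressure_kpa"], 64.0)
        assert table["primary"].sum() == 7

    def test_linear_gradient_shifts_left_right_only(self, centre_rois):
        cols = np.arange(SPEC.n_cols, dtype=float)
        img = _img(np.tile(3.0 * cols, (SPEC.n_rows, 1)))  # 3 kPa per column
        table = sensitivity_table(img, centre_rois).set_index(
            ["roi", "sensitivity_position"]
        )
        for roi in ROI_NAMES:
            centre = table.loc[(roi, "centre"), "peak_pressure_kpa"]
            assert table.loc[(roi, "right"), "peak_pressure_kpa"] == pytest.approx(
                centre + 3.0
            )
            assert table.loc[(roi, "left"), "peak_pressure_kpa"] == pytest.approx(
                centre - 3.0
            )
            assert table.loc[(roi, "up"), "peak_pressure_kpa"] == pytest.approx(centre)
            assert table.loc[(roi, "down"), "peak_pressure_kpa"] == pytest.approx(centre)

    def test_five_position_mean_equals_bruteforce(self, centre_rois):
        rng = np.random.default_rng(5)
        img = _img(rng.uniform(0, 200, SPEC.shape))
        table = sensitivity_table(img, centre_rois)
        for roi in ROI_NAMES:
            sub = table[table["roi"] == roi]["peak_pressure_kpa"]
            assert sub.mean() == pytest.approx(float(np.mean(sub.to_numpy())))


class TestDigitizeRois:
    def test_manual_points_returned_verbatim(self, centre_rois):
        img = _img(np.full(SPEC.shape, 10.0))
        tmpl = TemplateImage(image=img, foot_label="FR")
        out = digitize_rois(tmpl, mode="manual", manual_points=centre_rois.points)
        assert out.points == centre_rois.points

    def test_auto_recovers_generator_loci(self, quiet_trial, quiet_steps):
        _, truth = quiet_trial
        by_onset = {int(min(t for t, _, _ in s.mask)): s for s in truth.steps}
        for step in quiet_steps:
            st = by_onset[step.onset_frame]
            img = peak_pressure_image(step, st.label)
            rois = digitize_rois(TemplateImage(image=img, foot_label=st.label))
            for name in ROI_NAMES:
                tr, tc = st.roi_cells[name]
                r, c = rois.points[name]
                assert max(abs(r - tr), abs(c - tc)) <= 1, (st.label, name)

    def test_mirrored_sides_reverse_digit_ordering(self, quiet_trial, quiet_steps):
        """Digit i is medial: larger column for FL, smaller for FR (+y travel)."""
        _, truth = quiet_trial
        by_onset = {int(min(t for t, _, _ in s.mask)): s for s in truth.steps}
        cols = {}
        for step in quiet_steps:
            st = by_onset[step.onset_frame]
            img = peak_pressure_image(step, st.label)
            rois = digitize_rois(TemplateImage(image=img, foot_label=st.label))
            cols[st.label] = (rois.points["roi1"][1], rois.points["roi5"][1])
        assert cols["FR"][0] < cols["FR"][1]
        assert cols["FL"][0] > cols["FL"][1]

    def test_featureless_template_fails_loudly(self):
        values = np.zeros(SPEC.shape)
        values[10:14, 8:12] = 50.0  # one blob, no five digit maxima
        tmpl = TemplateImage(image=_img(values), foot_label="FR")
        with pytest.raises(DigitizationError):
            digitize_rois(tmpl, mode="auto")
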