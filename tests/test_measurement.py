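"""Centroid measurement and aberration-shift extraction."""

import numpy as np
import pytest

from chromaxial import (
    BeadROI,
    ChannelStack,
    DataError,
    MultiChannelStack,
    compute_centroid,
    measure_batch,
    measure_sample,
    samples_from_frame,
    samples_to_frame,
)
from conftest import brute_force_centroid


def _stack_of(v, dx=1.0, dy=1.0, dz=2.0, z0=0.0, cid="473"):
    return ChannelStack(np.asarray(v, dtype=float), dx, dy, dz, cid, z0=z0)


def _full_roi(v, label="t"):
    nz, ny, nx = np.asarray(v).shape
    return BeadROI(0, nx, 0, ny, 0, nz, label=label)


class TestComputeCentroid:
    def test_point_mass_column(self):
        # a 3-frame column of intensity 100 survives the z median filter;
        # its centroid sits at the middle frame's physical position
        v = np.zeros((12, 21, 21))
        v[3:6, 10, 10] = 100.0
        c = compute_centroid(_stack_of(v, dz=2.0, z0=0.0), _full_roi(v))
        assert c.z == pytest.approx(8.0, abs=1e-12)
        assert c.x == pytest.approx(10.0, abs=1e-12)
        assert c.y == pytest.approx(10.0, abs=1e-12)
        assert c.total_weight == pytest.approx(300.0)

    def test_symmetric_field_centres_on_voxel(self):
        zz, yy, xx = np.mgrid[0:11, 0:17, 0:17].astype(float)
        v = 5000.0 * np.exp(-((zz - 5) ** 2 / 8 + (yy - 8) ** 2 / 4 + (xx - 8) ** 2 / 4))
        c = compute_centroid(_stack_of(v, dx=0.5, dy=0.5, dz=2.0), _full_roi(v))
        assert c.z == pytest.approx(5 * 2.0, abs=1e-9)
        assert c.y == pytest.approx(8 * 0.5, abs=1e-9)
        assert c.x == pytest.approx(8 * 0.5, abs=1e-9)

    def test_matches_brute_force_on_hand_sized_roi(self):
        rng = np.random.default_rng(7)
        v = rng.integers(0, 50, size=(5, 4, 4)).astype(float)
        v[2, 1, 2] = 5000.0
        v[2, 2, 2] = 4000.0
        v[3, 1, 2] = 4500.0
        st = _stack_of(v, dx=0.4, dy=0.6, dz=1.5, z0=2.0)
        c = compute_centroid(st, _full_roi(v))
        ref = brute_force_centroid(v, 0.4, 0.6, 1.5, 2.0, 0, 0, 0)
        assert c.x == pytest.approx(ref[0], abs=1e-9)
        assert c.y == pytest.approx(ref[1], abs=1e-9)
        assert c.z == pytest.approx(ref[2], abs=1e-9)

    @pytest.mark.parametrize("shift", [(1, 0, 0), (0, 2, 0), (0, 0, 3), (2, 1, 1)])
    def test_translation_equivariance(self, shift):
        dz_sh, dy_sh, dx_sh = shift
        zz, yy, xx = np.mgrid[0:15, 0:15, 0:15].astype(float)
        v = 9000.0 * np.exp(-((zz - 5.3) ** 2 / 10 + (yy - 5.1) ** 2 / 3 + (xx - 5.6) ** 2 / 3))
        moved = np.roll(v, shift, axis=(0, 1, 2))
        st = dict(dx=0.5, dy=0.7, dz=2.0)
        c0 = compute_centroid(_stack_of(v, **st), _full_roi(v))
        c1 = compute_centroid(_stack_of(moved, **st), _full_roi(moved))
        assert c1.z - c0.z == pytest.approx(dz_sh * 2.0, abs=1e-9)
        assert c1.y - c0.y == pytest.approx(dy_sh * 0.7, abs=1e-9)
        assert c1.x - c0.x == pytest.approx(dx_sh * 0.5, abs=1e-9)

    def test_invariant_under_positive_intensity_scaling(self):
        zz, yy, xx = np.mgrid[0:9, 0:9, 0:9].astype(float)
        v = 100.0 * np.exp(-((zz - 4.2) ** 2 + (yy - 4.4) ** 2 + (xx - 3.9) ** 2) / 6)
        c0 = compute_centroid(_stack_of(v), _full_roi(v))
        c1 = compute_centroid(_stack_of(v * 37.5), _full_roi(v))
        assert (c1.x, c1.y, c1.z) == pytest.approx((c0.x, c0.y, c0.z), abs=1e-12)

    def test_subthreshold_noise_leaves_centroid_unchanged(self):
        zz, yy, xx = np.mgrid[0:15, 0:15, 0:15].astype(float)
        v = 1e6 * np.exp(-((zz - 7.2) ** 2 / 18 + (yy - 7.5) ** 2 / 4 + (xx - 6.9) ** 2 / 4))
        rng = np.random.default_rng(2)
        noise = rng.integers(-5, 6, v.shape).astype(float)
        noisy = v + np.where(v < 1000, noise, 0.0)
        c0 = compute_centroid(_stack_of(v), _full_roi(v))
        c1 = compute_centroid(_stack_of(noisy), _full_roi(noisy))
        assert (c1.x, c1.y, c1.z) == (c0.x, c0.y, c0.z)

    def test_threshold_fallback_flagged_and_exhaustion_errors(self):
        # a broad dim plateau: mean + 10 SD over-excludes, ladder kicks in
        zz, yy, xx = np.mgrid[0:11, 0:11, 0:11].astype(float)
        broad = 100.0 * np.exp(-((zz - 5) ** 2 + (yy - 5) ** 2 + (xx - 5) ** 2) / 40)
        c = compute_centroid(_stack_of(broad), _full_roi(broad))
        assert any(f.startswith("threshold_fallback") for f in c.flags)
        with pytest.raises(DataError, match="no object"):
            compute_centroid(_stack_of(np.zeros((5, 5, 5))), _full_roi(np.zeros((5, 5, 5))))

    def test_roi_needs_three_frames(self):
        v = np.ones((5, 5, 5))
        with pytest.raises(DataError, match="median"):
            compute_centroid(_stack_of(v), BeadROI(0, 5, 0, 5, 1, 3, label="thin"))

    def test_truncated_object_flagged(self):
        zz, yy, xx = np.mgrid[0:9, 0:11, 0:11].astype(float)
        v = 9000.0 * np.exp(-((zz - 0.5) ** 2 / 12 + (yy - 5) ** 2 / 3 + (xx - 5) ** 2 / 3))
        c = compute_centroid(_stack_of(v), _full_roi(v))
        assert "possibly_truncated" in c.flags


class TestMeasureSample:
    def _pair(self, v_ref, v_tgt, dz=2.0):
        return MultiChannelStack(
            channels=(
                ChannelStack(np.asarray(v_ref, float), 1, 1, dz, "473"),
                ChannelStack(np.asarray(v_tgt, float), 1, 1, dz, "559"),
            ),
            reference_channel="473",
        )

    def test_identical_channels_give_zero_shifts(self):
        zz, yy, xx = np.mgrid[0:11, 0:11, 0:11].astype(float)
        v = 8000.0 * np.exp(-((zz - 5.2) ** 2 / 9 + (yy - 5) ** 2 / 3 + (xx - 5) ** 2 / 3))
        s = measure_sample(self._pair(v, v.copy()), _full_roi(v))
        assert s.shifts["473"] == (0.0, 0.0, 0.0)
        assert s.shifts["559"] == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_pure_frame_translation_measures_exact_shift(self):
        zz, yy, xx = np.mgrid[0:20, 0:13, 0:13].astype(float)
        v = 8000.0 * np.exp(-((zz - 8.4) ** 2 / 9 + (yy - 6) ** 2 / 3 + (xx - 6) ** 2 / 3))
        shifted = np.roll(v, 3, axis=0)  # +3 frames at dz = 2 um
        s = measure_sample(self._pair(v, shifted), _full_roi(v))
        dx, dy, dzs = s.shifts["559"]
        assert dzs == pytest.approx(6.0, abs=1e-9)
        assert dx == pytest.approx(0.0, abs=1e-9)
        assert dy == pytest.approx(0.0, abs=1e-9)
        # absolute depth carries the thresholded-centroid truncation error;
        # only the inter-channel *difference* is exact under pure translation
        assert s.depth == pytest.approx(8.4 * 2.0, abs=0.3)

    def test_phantom_shift_recovered_within_half_frame(self, small_phantom):
        spec, stack, truth, rois = small_phantom
        tt = truth[truth.channel == "559"].set_index("label")
        for roi in rois[:6]:
            s = measure_sample(stack, roi)
            assert s.shifts["559"][2] == pytest.approx(
                tt.loc[roi.label, "dz_um"], abs=spec.dz / 2
            )


class TestBatchAndTables:
    def test_batch_collects_failures_without_aborting(self, small_phantom):
        _, stack, _, rois = small_phantom
        nz = stack.shape[0]
        bad = BeadROI(0, 4, 0, 4, nz - 2, nz, label="too_thin")
        samples, failures = measure_batch(stack, rois + [bad])
        assert len(samples) == len(rois)
        assert [label for label, _ in failures] == ["too_thin"]
        assert "median" in failures[0][1]

    def test_empty_roi_list_gives_empty_table(self, small_phantom):
        _, stack, _, _ = small_phantom
        samples, failures = measure_batch(stack, [])
        df = samples_to_frame(samples)
        assert df.empty and not failures
        assert list(df.columns)[:4] == ["label", "source", "depth_um", "channel"]

    def test_table_round_trip(self, small_phantom):
        _, stack, _, rois = small_phantom
        samples, _ = measure_batch(stack, rois, source="bead")
        df = samples_to_frame(samples)
        back = samples_from_frame(df, reference_channel="473")
        assert len(back) == len(samples)
        for s0, s1 in zip(samples, back):
            assert s0.label == s1.label
            assert s1.depth == pytest.approx(s0.depth)
            assert s1.shifts["559"] == pytest.approx(s0.shifts["559"])
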