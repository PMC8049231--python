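"""Trace synthesis: waveform closure, beads, QC runs, rasterization."""

import numpy as np
import pandas as pd
import pytest

from mechanosep import (
    FrameDescriptor,
    rasterize_frame,
    synthesize_bead_run,
    synthesize_trace,
    synthesize_traces,
)
from mechanosep.config import AcquisitionParams, BEAD_DIAMETER_UM
from mechanosep.imaging_metrics import detect_cells


def _cell(d, ar, veir, cid="c0"):
    return {"cell_id": cid, "size": d, "true_ar": ar, "true_veir": veir,
            "intensity": 10.0, "subject_id": "s0"}


class TestWaveform:
    def test_bead_is_rigid_sphere(self, noisefree_acq, rng):
        cell = {"cell_id": "b0", "size": BEAD_DIAMETER_UM, "true_ar": 1.0,
                "true_veir": 0.0, "true_type": "bead"}
        tr = synthesize_trace(cell, noisefree_acq, rng)
        assert tr.is_bead
        for f in tr.frames:
            assert f.major_axis == pytest.approx(BEAD_DIAMETER_UM)
            assert f.minor_axis == pytest.approx(BEAD_DIAMETER_UM)

    def test_area_preserving_peak(self, noisefree_acq, rng):
        """Stretch to AR 2.55 at rest diameter 8.7 peaks at d*sqrt(AR)."""
        d, ar = 8.7, 2.55
        veir = d * (np.sqrt(ar) - 1) + 1.0
        tr = synthesize_trace(_cell(d, ar, veir), noisefree_acq, rng)
        peak = max(f.major_axis for f in tr.frames)
        assert peak == pytest.approx(d * np.sqrt(ar), abs=1e-9)
        assert peak == pytest.approx(13.9, abs=0.01)
        # area preserved at the peak
        pk = max(tr.frames, key=lambda f: f.major_axis)
        assert pk.major_axis * pk.minor_axis == pytest.approx(d * d)

    def test_excursion_equals_veir_exactly(self, noisefree_acq, rng):
        for d, ar, veir in [(8.5, 2.55, 6.73), (9.8, 3.42, 10.41), (7.0, 2.0, 5.0)]:
            tr = synthesize_trace(_cell(d, ar, veir), noisefree_acq, rng)
            axial = [f.major_axis if f.orientation < np.pi / 4 else f.minor_axis
                     for f in tr.frames]
            assert max(axial) - min(axial) == pytest.approx(veir, abs=1e-9)

    def test_infeasible_veir_raises_with_cell_id(self, noisefree_acq, rng):
        d, ar = 9.0, 3.0
        too_small = d * (np.sqrt(ar) - 1) - 0.5
        with pytest.raises(ValueError, match="cellX"):
            synthesize_trace(_cell(d, ar, too_small, cid="cellX"),
                             noisefree_acq, rng)

    def test_frame_counts_in_range(self, small_high_acuity, default_acq):
        _, cells = small_high_acuity
        batch = synthesize_traces(cells.head(500), default_acq,
                                  np.random.default_rng(0))
        assert batch.n_frames.min() >= default_acq.min_frames
        assert batch.n_frames.max() <= default_acq.max_frames

    def test_determinism(self, small_high_acuity, default_acq):
        _, cells = small_high_acuity
        b1 = synthesize_traces(cells.head(100), default_acq, np.random.default_rng(5))
        b2 = synthesize_traces(cells.head(100), default_acq, np.random.default_rng(5))
        np.testing.assert_array_equal(b1.major, b2.major)
        np.testing.assert_array_equal(b1.x, b2.x)

    def test_long_format_roundtrip(self, small_high_acuity, default_acq):
        from mechanosep.event_sim import batch_from_frame
        _, cells = small_high_acuity
        sub = cells.head(50)
        b = synthesize_traces(sub, default_acq, np.random.default_rng(5))
        df = b.to_frame()
        assert set(df.columns) == {"cell_id", "t", "x", "y", "major", "minor",
                                   "orientation", "is_bead"}
        b2 = batch_from_frame(df, meta=sub[["cell_id", "subject_id", "intensity"]])
        np.testing.assert_allclose(
            np.sort(np.nanmax(b.major, axis=1)),
            np.sort(np.nanmax(b2.major, axis=1)))


class TestBeadRun:
    def test_unclogged_straight(self, default_acq):
        b = synthesize_bead_run(100, default_acq, clogged=False,
                                rng=np.random.default_rng(0))
        dev = np.nanmax(np.abs(b.y - b.y[:, :1]), axis=1)
        assert (dev < 1.0).all()

    def test_clogged_deflects_at_least_30pct(self, default_acq):
        b = synthesize_bead_run(100, default_acq, clogged=True,
                                rng=np.random.default_rng(0))
        dev = np.nanmax(np.abs(b.y - b.y[:, :1]), axis=1)
        assert (dev > 1.0).sum() >= 30
        speeds = np.nanmean(np.diff(b.x, axis=1), axis=1)
        slow = speeds < 0.76 * default_acq.nominal_speed_um_per_frame
        assert slow.sum() >= 30

    def test_speed_distribution_calibrated(self, default_acq):
        """Monte-Carlo: mean bead speed within 2% of nominal when unclogged."""
        b = synthesize_bead_run(1000, default_acq, clogged=False,
                                rng=np.random.default_rng(1))
        speeds = np.nanmean(np.diff(b.x, axis=1), axis=1)
        nominal = default_acq.nominal_speed_um_per_frame
        assert abs(speeds.mean() - nominal) < 0.02 * nominal


class TestRasterize:
    def test_circle_moments_within_2pct(self, default_acq):
        f = FrameDescriptor(t=0, x=default_acq.junction_position_um, y=0.0,
                            major_axis=BEAD_DIAMETER_UM,
                            minor_axis=BEAD_DIAMETER_UM, orientation=0.0)
        img = rasterize_frame(f, default_acq)
        dets = detect_cells(img, default_acq)
        assert len(dets) == 1
        assert dets[0].major_axis == pytest.approx(BEAD_DIAMETER_UM, rel=0.02)
        assert dets[0].minor_axis == pytest.approx(BEAD_DIAMETER_UM, rel=0.02)

    def test_background_only_when_blank(self, default_acq):
        img = np.full((default_acq.image_size_px,) * 2, 0.05)
        assert detect_cells(img, default_acq) == []

    def test_rasterize_deterministic(self, default_acq):
        f = FrameDescriptor(t=0, x=default_acq.junction_position_um, y=0.0,
                            major_axis=10.0, minor_axis=5.0, orientation=0.0)
        img1 = rasterize_frame(f, default_acq, rng=np.random.default_rng(3),
                               shot_noise_scale=0.01)
        img2 = rasterize_frame(f, default_acq, rng=np.random.default_rng(3),
                               shot_noise_scale=0.01)
        np.testing.assert_array_equal(img1, img2)

    def test_out_of_bounds_raises(self, default_acq):
        f = FrameDescriptor(t=7, x=default_acq.junction_position_um + 100, y=0.0,
                            major_axis=10.0, minor_axis=5.0, orientation=0.0)
        with pytest.raises(ValueError, match="t=7"):
            rasterize_frame(f, default_acq)
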