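"""Metric estimators, frame linking, and run QC."""

import numpy as np
import pandas as pd
import pytest

from mechanosep import (
    estimate_ar,
    estimate_rest_size,
    estimate_veir,
    extract_events,
    link_frames_to_events,
    rasterize_frame,
    run_qc,
    synthesize_bead_run,
    synthesize_trace,
    synthesize_traces,
    detect_cells,
)
from mechanosep.config import AcquisitionParams, QcThresholds, BEAD_DIAMETER_UM
from mechanosep.event_sim import EventTrace, FrameDescriptor


def _trace(d, ar, veir, acq, seed=0, **kw):
    cell = {"cell_id": "c", "size": d, "true_ar": ar, "true_veir": veir,
            "intensity": 5.0, **kw}
    return synthesize_trace(cell, acq, np.random.default_rng(seed))


class TestEstimators:
    def test_noisefree_closure_on_cohort(self, small_high_acuity, noisefree_acq):
        """Generator -> estimator round trip is exact without noise."""
        _, cells = small_high_acuity
        sub = cells.sample(1500, random_state=0)
        batch = synthesize_traces(sub, noisefree_acq, np.random.default_rng(0))
        ev = extract_events(batch).merge(sub, on="cell_id")
        np.testing.assert_allclose(ev["ar"], ev["true_ar"], atol=1e-9)
        np.testing.assert_allclose(ev["veir"], ev["true_veir"], atol=1e-9)
        np.testing.assert_allclose(ev["size_x"], ev["size_y"], atol=1e-9)

    def test_ar_is_peak_axis_ratio(self, noisefree_acq):
        # peak axes (15.9, 5.08) <=> d = sqrt(15.9*5.08), AR = 15.9/5.08
        d = float(np.sqrt(15.9 * 5.08))
        ar = 15.9 / 5.08
        tr = _trace(d, ar, d * (np.sqrt(ar) - 1) + 1.5, noisefree_acq)
        assert estimate_ar(tr) == pytest.approx(3.13, abs=0.01)

    def test_bead_ar_one_veir_zero(self, default_acq):
        tr = _trace(BEAD_DIAMETER_UM, 1.0, 0.0, default_acq, true_type="bead")
        assert estimate_ar(tr) < 1.1
        # the excursion of pure smoothed noise over 10-15 frames is an
        # extreme-value range statistic: ~2.1x the per-frame noise SD
        assert estimate_veir(tr) < 2.5 * default_acq.descriptor_noise_sd_um

    def test_noisy_recovery_bias(self, default_acq):
        """Monte-Carlo over 1,000 identical cells at default noise: mean AR
        within 2% and mean VEIR within 3% of truth."""
        d, ar, veir = 8.5, 2.55, 6.73
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(1000)],
            "subject_id": "s", "size": d, "true_ar": ar, "true_veir": veir,
            "intensity": 5.0})
        batch = synthesize_traces(cells, default_acq, np.random.default_rng(2))
        ev = extract_events(batch)
        assert ev["ar"].mean() == pytest.approx(ar, rel=0.02)
        assert ev["veir"].mean() == pytest.approx(veir, rel=0.03)
        assert ev["size"].mean() == pytest.approx(d, rel=0.02)

    def test_time_shift_invariance(self, noisefree_acq):
        tr = _trace(8.5, 2.5, 6.5, noisefree_acq)
        shifted = EventTrace(cell_id=tr.cell_id, frames=[
            FrameDescriptor(t=f.t + 17, x=f.x, y=f.y, major_axis=f.major_axis,
                            minor_axis=f.minor_axis, orientation=f.orientation)
            for f in tr.frames])
        assert estimate_ar(shifted) == estimate_ar(tr)
        assert estimate_veir(shifted) == estimate_veir(tr)

    def test_short_trace_rejected(self, noisefree_acq):
        tr = _trace(8.5, 2.5, 6.5, noisefree_acq)
        stub = EventTrace(cell_id="s", frames=tr.frames[:4])
        with pytest.raises(ValueError, match="frames"):
            estimate_ar(stub)

    def test_degenerate_minor_axis_errors(self):
        frames = [FrameDescriptor(t=i, x=0, y=0, major_axis=5.0,
                                  minor_axis=1e-9, orientation=0.0)
                  for i in range(6)]
        with pytest.raises(ValueError, match="minor"):
            estimate_ar(EventTrace(cell_id="bad", frames=frames))


class TestImagePath:
    def test_single_ellipse_detected_within_2pct(self, default_acq):
        f = FrameDescriptor(t=0, x=default_acq.junction_position_um, y=0.0,
                            major_axis=13.9, minor_axis=5.4, orientation=0.0)
        dets = detect_cells(rasterize_frame(f, default_acq), default_acq)
        assert len(dets) == 1
        assert dets[0].major_axis == pytest.approx(13.9, rel=0.02)
        assert dets[0].minor_axis == pytest.approx(5.4, rel=0.02)

    def test_two_separated_ellipses(self, default_acq):
        j = default_acq.junction_position_um
        img = np.full((default_acq.image_size_px,) * 2, 0.05)
        for dx, dy in ((-15, -15), (15, 15)):
            f = FrameDescriptor(t=0, x=j + dx, y=dy, major_axis=8.0,
                                minor_axis=6.0, orientation=0.0)
            img = np.maximum(img, rasterize_frame(f, default_acq))
        assert len(detect_cells(img, default_acq)) == 2

    def test_descriptor_and_image_paths_agree(self, noisefree_acq):
        """The two front ends recover AR/VEIR within 5% of each other."""
        tr = _trace(8.5, 2.8, 7.5, noisefree_acq)
        measured = []
        for f in tr.frames:
            centered = FrameDescriptor(
                t=f.t, x=noisefree_acq.junction_position_um, y=0.0,
                major_axis=f.major_axis, minor_axis=f.minor_axis,
                orientation=f.orientation)
            det = detect_cells(rasterize_frame(centered, noisefree_acq),
                               noisefree_acq)
            assert len(det) == 1
            measured.append(FrameDescriptor(
                t=f.t, x=f.x, y=f.y, major_axis=det[0].major_axis,
                minor_axis=det[0].minor_axis, orientation=det[0].orientation))
        img_trace = EventTrace(cell_id="img", frames=measured)
        assert estimate_ar(img_trace) == pytest.approx(estimate_ar(tr), rel=0.05)
        assert estimate_veir(img_trace) == pytest.approx(estimate_veir(tr), rel=0.05)


class TestLinking:
    def _stream(self, acq, n_cells=20, spacing=3, length=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n_frames = spacing * n_cells + length
        dets = [[] for _ in range(n_frames)]
        for k in range(n_cells):
            for i in range(length):
                t = spacing * k + i
                dets[t].append(FrameDescriptor(
                    t=t, x=i * acq.nominal_speed_um_per_frame + noise * rng.standard_normal(),
                    y=0.5 * k % 3, major_axis=9.0, minor_axis=7.0, orientation=0.0))
        return dets

    def test_single_cell_trace(self, default_acq):
        dets = self._stream(default_acq, n_cells=1, length=12)
        traces = link_frames_to_events(dets, default_acq)
        assert len(traces) == 1
        assert len(traces[0].frames) == 12

    def test_interleaved_cells_separate(self, default_acq):
        traces = link_frames_to_events(self._stream(default_acq, n_cells=2),
                                       default_acq)
        assert len(traces) == 2

    def test_stream_recovery_rate(self, default_acq):
        """>= 99% of ground-truth traces recovered at default density."""
        traces = link_frames_to_events(
            self._stream(default_acq, n_cells=50, noise=0.1), default_acq)
        full = [t for t in traces if len(t.frames) == 12]
        assert len(full) >= 0.99 * 50


class TestRunQC:
    def test_clean_run_accepted(self, default_acq):
        beads = synthesize_bead_run(50, default_acq, clogged=False,
                                    rng=np.random.default_rng(0))
        rep = run_qc(beads, default_acq, run_id="r1")
        assert rep.accepted
        assert rep.reasons == []
        assert rep.bead_trajectory_pass_fraction == 1.0

    def test_clogged_run_rejected_on_trajectory(self, default_acq):
        beads = synthesize_bead_run(50, default_acq, clogged=True,
                                    rng=np.random.default_rng(0))
        rep = run_qc(beads, default_acq)
        assert not rep.accepted
        assert any("trajectory" in r for r in rep.reasons)

    def test_slow_flow_rejected_on_velocity(self, default_acq):
        slow_acq = AcquisitionParams(
            nominal_speed_um_per_frame=0.8 * default_acq.nominal_speed_um_per_frame)
        beads = synthesize_bead_run(50, slow_acq, clogged=False,
                                    rng=np.random.default_rng(0))
        rep = run_qc(beads, default_acq)
        assert not rep.accepted
        assert any("velocity" in r for r in rep.reasons)

    def test_insufficient_controls(self, default_acq):
        beads = synthesize_bead_run(5, default_acq, clogged=False,
                                    rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="insufficient controls"):
            run_qc(beads, default_acq)
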