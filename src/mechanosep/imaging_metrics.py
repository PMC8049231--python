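"""Per-event metric recovery and run-level quality control.

Two front ends produce frame descriptors: the descriptor path (directly from
:mod:`mechanosep.event_sim`) and the image path (rendered frames passed
through classical moments-based segmentation).  Both feed the same
estimators:

* **AR** — max over frames of major/minor after 3-point median smoothing.
* **VEIR** — full excursion (max - min) of the 3-point-median-smoothed
  axial (flow-direction) extent, in um.
* **rest size** — median of sqrt(major x minor) over frames up to the
  deformation peak (the geometric-mean diameter is area-consistent, so the
  stretch frames do not bias it).

Median smoothing guards the extremum statistics against single-frame
outliers; the synthesized waveform holds its extrema for two frames so the
noise-free round trip is exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .config import AcquisitionParams, QcThresholds
from .event_sim import EventTrace, FrameDescriptor, TraceBatch

MIN_TRACE_FRAMES = 5
_MINOR_FLOOR = 1e-6


def _median3(a: np.ndarray) -> np.ndarray:
    """3-point running median along axis 1, nearest-edge padding,
    NaN-tail preserving."""
    prev = np.concatenate([a[:, :1], a[:, :-1]], axis=1)
    nxt = np.concatenate([a[:, 1:], a[:, -1:]], axis=1)
    nxt = np.where(np.isnan(nxt) & ~np.isnan(a), a, nxt)
    return np.median(np.stack([prev, a, nxt]), axis=0)


def _axial(batch_major, batch_minor, orientation):
    """Flow-direction extent from sorted axes + orientation."""
    return np.where(orientation < np.pi / 4, batch_major, batch_minor)


def _estimate_arrays(major: np.ndarray, minor: np.ndarray,
                     orientation: np.ndarray):
    """Vectorized (AR, VEIR, rest size) from NaN-padded descriptor arrays."""
    if np.any(np.nan_to_num(minor, nan=1.0) <= _MINOR_FLOOR):
        raise ValueError("degenerate minor axis (<= 0) in trace")
    sm_major = _median3(major)
    sm_minor = _median3(minor)
    ar = np.nanmax(sm_major / sm_minor, axis=1)

    axial = _axial(major, minor, orientation)
    sm_axial = _median3(axial)
    veir = np.nanmax(sm_axial, axis=1) - np.nanmin(sm_axial, axis=1)

    peak_idx = np.nanargmax(sm_axial, axis=1)
    geo = np.sqrt(major * minor)
    pre = np.arange(major.shape[1])[None, :] <= peak_idx[:, None]
    size = np.nanmedian(np.where(pre, geo, np.nan), axis=1)
    return ar, veir, size


def extract_events(batch: TraceBatch,
                   min_frames: int = MIN_TRACE_FRAMES) -> pd.DataFrame:
    """Aggregate a trace batch into one row per event.

    Traces shorter than ``min_frames`` are dropped.  Intensity is carried
    through from the acquisition (the optical model is not simulated).
    """
    keep = batch.n_frames >= min_frames
    ar, veir, size = _estimate_arrays(batch.major[keep], batch.minor[keep],
                                      batch.orientation[keep])
    return pd.DataFrame({
        "cell_id": batch.cell_id[keep],
        "subject_id": batch.subject_id[keep],
        "size": size,
        "intensity": batch.intensity[keep],
        "ar": ar,
        "veir": veir,
        "n_frames": batch.n_frames[keep],
        "is_bead": batch.is_bead[keep],
    })


def _trace_arrays(trace: EventTrace):
    f = trace.frames
    if len(f) < MIN_TRACE_FRAMES:
        raise ValueError(f"trace {trace.cell_id}: needs >= {MIN_TRACE_FRAMES} frames")
    major = np.array([[fr.major_axis for fr in f]])
    minor = np.array([[fr.minor_axis for fr in f]])
    orient = np.array([[fr.orientation for fr in f]])
    return major, minor, orient


def estimate_ar(trace: EventTrace) -> float:
    """Peak deformation aspect ratio of one event."""
    ar, _, _ = _estimate_arrays(*_trace_arrays(trace))
    return float(ar[0])


def estimate_veir(trace: EventTrace) -> float:
    """Visco-elastic inertial response (um) of one event."""
    _, veir, _ = _estimate_arrays(*_trace_arrays(trace))
    return float(veir[0])


def estimate_rest_size(trace: EventTrace) -> float:
    """Rest diameter estimate (um) from pre/at-peak frames."""
    _, _, size = _estimate_arrays(*_trace_arrays(trace))
    return float(size[0])


# ---------------------------------------------------------------------------
# image path


def detect_cells(image: np.ndarray, acq: AcquisitionParams,
                 min_area_px: int = 20,
                 contrast_floor: float = 0.1,
                 psf_sigma_px: float = 1.0) -> list[FrameDescriptor]:
    """Classical moments-based segmentation of one grayscale frame.

    Background-subtracted Otsu threshold finds connected components above an
    area floor; each component's centroid and axes then come from
    intensity-weighted second-order moments over its neighbourhood
    (axes = 4 sqrt(eigenvalues of the pixel-coordinate covariance), the
    equivalent solid ellipse), after removing the known optical-blur and
    pixel-integration variance (psf_sigma^2 + 1/12 per axis).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    img = np.asarray(image, dtype=float)
    work = img - np.median(img)
    if work.max() - work.min() < contrast_floor:
        return []
    mask = work > threshold_otsu(work)
    labels = label(mask)
    out: list[FrameDescriptor] = []
    upp = acq.um_per_pixel
    half = acq.image_size_px / 2
    pad = int(np.ceil(4 * psf_sigma_px)) + 1
    var_corr = psf_sigma_px**2 + 1.0 / 12.0
    n_rows, n_cols = img.shape
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        r0, c0, r1, c1 = prop.bbox
        r0, c0 = max(r0 - pad, 0), max(c0 - pad, 0)
        r1, c1 = min(r1 + pad, n_rows), min(c1 + pad, n_cols)
        w = np.clip(work[r0:r1, c0:c1], 0.0, None)
        other = (labels[r0:r1, c0:c1] != 0) & (labels[r0:r1, c0:c1] != prop.label)
        w = np.where(other, 0.0, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        total = w.sum()
        cx = float((w * xx).sum() / total)
        cy = float((w * yy).sum() / total)
        cxx = float((w * (xx - cx) ** 2).sum() / total)
        cyy = float((w * (yy - cy) ** 2).sum() / total)
        cxy = float((w * (xx - cx) * (yy - cy)).sum() / total)
        cov = np.array([[cxx, cxy], [cxy, cyy]])
        lam, vec = np.linalg.eigh(cov)
        axes = 4.0 * np.sqrt(np.maximum(lam - var_corr, 1e-6)) * upp
        # principal eigenvector angle against the flow (x) axis
        vx, vy = vec[:, 1]
        orient = float(abs(np.arctan2(vy, vx)))
        if orient > np.pi / 2:
            orient = np.pi - orient
        out.append(FrameDescriptor(
            t=0,
            x=float((cx - half) * upp + acq.junction_position_um),
            y=float((cy - half) * upp),
            major_axis=float(axes[1]),
            minor_axis=float(max(axes[0], _MINOR_FLOOR * 2)),
            orientation=orient))
    return out


def link_frames_to_events(detections: list[list[FrameDescriptor]],
                          acq: AcquisitionParams,
                          min_frames: int = MIN_TRACE_FRAMES) -> list[EventTrace]:
    """Nearest-centroid frame linking.

    Each open track predicts its next centroid one nominal step downstream;
    detections within a gate of twice the nominal per-frame speed extend the
    nearest track, everything else opens a new track.  Tracks shorter than
    ``min_frames`` are discarded.
    """
    gate = 2.0 * acq.nominal_speed_um_per_frame
    open_tracks: list[list[FrameDescriptor]] = []
    closed: list[list[FrameDescriptor]] = []
    for t, dets in enumerate(detections):
        dets = [FrameDescriptor(t=t, x=d.x, y=d.y, major_axis=d.major_axis,
                                minor_axis=d.minor_axis, orientation=d.orientation)
                for d in dets]
        pairs = []
        for ti, track in enumerate(open_tracks):
            px = track[-1].x + acq.nominal_speed_um_per_frame * (t - track[-1].t)
            py = track[-1].y
            for di, d in enumerate(dets):
                dist = float(np.hypot(d.x - px, d.y - py))
                if dist <= gate:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t, used_d = set(), set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            open_tracks[ti].append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        still_open = []
        for ti, track in enumerate(open_tracks):
            if ti in used_t:
                still_open.append(track)
            else:
                closed.append(track)
        open_tracks = still_open
        for di, d in enumerate(dets):
            if di not in used_d:
                open_tracks.append([d])
    closed.extend(open_tracks)
    return [EventTrace(cell_id=f"trk{k:05d}", frames=tr)
            for k, tr in enumerate(closed) if len(tr) >= min_frames]


# ---------------------------------------------------------------------------
# run QC


@dataclass
class QCReport:
    """Accept/reject decision for one test run, from control-bead behaviour."""

    run_id: str
    bead_trajectory_pass_fraction: float
    median_bead_speed: float
    drift_flag: bool
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def run_qc(bead_batch: TraceBatch, acq: AcquisitionParams,
           thresholds: QcThresholds | None = None,
           run_id: str = "run") -> QCReport:
    """Accept a run iff the control beads flew straight at the target speed.

    Trajectory check: per-bead maximum transverse deviation below the limit.
    Velocity check: median per-bead speed within the tolerance of nominal.
    """
    thresholds = thresholds or QcThresholds()
    n = len(bead_batch)
    if n < thresholds.min_beads:
        raise ValueError(
            f"insufficient controls: {n} bead traces < {thresholds.min_beads}")
    dev = np.nanmax(np.abs(bead_batch.y - bead_batch.y[:, :1]), axis=1)
    straight = dev <= thresholds.transverse_limit_um
    pass_fraction = float(straight.mean())
    speeds = np.nanmean(np.diff(bead_batch.x, axis=1), axis=1)
    median_speed = float(np.median(speeds))
    nominal = acq.nominal_speed_um_per_frame

    reasons = []
    if pass_fraction < thresholds.trajectory_pass_min:
        reasons.append(
            f"trajectory failure: only {pass_fraction:.0%} of beads flew "
            f"straight (limit {thresholds.trajectory_pass_min:.0%})")
    if abs(median_speed - nominal) > thresholds.speed_tolerance * nominal:
        reasons.append(
            f"velocity failure: median bead speed {median_speed:.2f} um/frame "
            f"outside {thresholds.speed_tolerance:.0%} of nominal {nominal:.2f}")
    return QCReport(run_id=run_id,
                    bead_trajectory_pass_fraction=pass_fraction,
                    median_bead_speed=median_speed,
                    drift_flag=pass_fraction < 1.0,
                    accepted=not reasons,
                    reasons=reasons)
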