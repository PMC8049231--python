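"""Frame-descriptor synthesis for cells transiting the extensional-flow junction.

Each cell event is a short sequence (10-15 frames) of ellipse descriptors:
rest frames upstream, an area-preserving stretch at the junction, and a
damped recoil whose full axial excursion equals the cell's true VEIR exactly.

Waveform (noise-free axial extent, rest diameter d, aspect ratio A, VEIR V):

* frames 0-2: rest, axial = d
* frames 3-5: stretch plateau, axial = d*sqrt(A)  (area preserving)
* frames 6-8: recoil trough, axial = d + (C - V) with stretch amplitude
  C = d*(sqrt(A)-1)
* frames 9+: damped alternation about d with per-extremum decay
  exp(-zeta*pi/sqrt(1-zeta^2)), zeta = 0.3

Extrema are held for three consecutive frames so that the 3-point median
smoothing used by the estimators passes them unchanged — and, on noisy
descriptors, reads an unbiased median of the plateau — making the
generator/estimator pair exactly closed in the noise-free limit.  Above rest
length the transverse extent is area-preserving (d^2/axial); during the
undershoot the projection contracts isotropically (both extents equal), so
the stretch peak remains the frame of maximal aspect ratio.

The feasible VEIR interval for this waveform is ``[C, C + 0.95 d]`` with
stretch amplitude ``C = d*(sqrt(A)-1)``: below it the excursion cannot be
this small (the stretch alone exceeds it), above it the recoil trough would
collapse the cell.  Out-of-range cells raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BEAD_DIAMETER_UM, AcquisitionParams

#: fixed recoil damping ratio; per-extremum envelope decay
DAMPING_RATIO = 0.3
RECOIL_DECAY = float(np.exp(-DAMPING_RATIO * np.pi / np.sqrt(1 - DAMPING_RATIO**2)))

N_REST = 3          # upstream rest frames
PEAK_FRAMES = (3, 5)     # inclusive plateau, 3 frames
TROUGH_FRAMES = (6, 8)   # inclusive plateau, 3 frames
_MIN_LAYOUT_FRAMES = 10

AXIS_FLOOR_UM = 0.2
#: loose enough to absorb decimal round-tripping of boundary-clamped cells
FEASIBILITY_TOL = 1e-6


@dataclass
class FrameDescriptor:
    """One detected/synthesized ellipse in one frame (axes in um)."""

    t: int
    x: float
    y: float
    major_axis: float
    minor_axis: float
    orientation: float  # 0 = major axis along flow, pi/2 = transverse

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("require major_axis >= minor_axis > 0")


@dataclass
class EventTrace:
    """Ordered frame descriptors for one cell event."""

    cell_id: str
    frames: list[FrameDescriptor]
    is_bead: bool = False
    intensity: float = np.nan

    def __post_init__(self) -> None:
        ts = [f.t for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame indices must be strictly increasing")


@dataclass
class TraceBatch:
    """Vectorized trace container: NaN-padded (n_events, max_frames) arrays."""

    cell_id: np.ndarray
    subject_id: np.ndarray
    is_bead: np.ndarray
    intensity: np.ndarray
    n_frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    orientation: np.ndarray

    def __len__(self) -> int:
        return len(self.cell_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format traces table (one row per frame)."""
        n, m = self.major.shape
        valid = ~np.isnan(self.major)
        rows, ts = np.nonzero(valid)
        return pd.DataFrame({
            "cell_id": self.cell_id[rows],
            "t": ts,
            "x": self.x[valid],
            "y": self.y[valid],
            "major": self.major[valid],
            "minor": self.minor[valid],
            "orientation": self.orientation[valid],
            "is_bead": self.is_bead[rows],
        })


def batch_from_frame(traces: pd.DataFrame,
                     meta: pd.DataFrame | None = None) -> TraceBatch:
    """Rebuild a :class:`TraceBatch` from the long-format traces table."""
    traces = traces.sort_values(["cell_id", "t"], kind="stable")
    ids, start = np.unique(traces["cell_id"].to_numpy(), return_index=True)
    order = np.argsort(start)
    ids = ids[order]
    counts = np.diff(np.sort(start).tolist() + [len(traces)])
    max_f = int(counts.max())
    n = len(ids)

    def _pad(col):
        out = np.full((n, max_f), np.nan)
        pos = np.concatenate([np.arange(c) for c in counts])
        row = np.repeat(np.arange(n), counts)
        out[row, pos] = traces[col].to_numpy()
        return out

    is_bead = traces.groupby("cell_id", sort=False)["is_bead"].first()
    is_bead = is_bead.reindex(ids).to_numpy().astype(bool)
    if meta is not None:
        meta = meta.set_index("cell_id").reindex(ids)
        subject = meta["subject_id"].to_numpy()
        intensity = meta["intensity"].to_numpy(dtype=float)
    else:
        subject = np.array([""] * n, dtype=object)
        intensity = np.full(n, np.nan)
    return TraceBatch(cell_id=ids, subject_id=subject, is_bead=is_bead,
                      intensity=intensity, n_frames=counts.astype(int),
                      x=_pad("x"), y=_pad("y"), major=_pad("major"),
                      minor=_pad("minor"), orientation=_pad("orientation"))


def _axial_series(d: np.ndarray, ar: np.ndarray, veir: np.ndarray,
                  n_frames: np.ndarray, max_f: int) -> np.ndarray:
    """Noise-free axial (flow-direction) extent, (n, max_f), NaN beyond event."""
    n = d.size
    stretch = d * (np.sqrt(ar) - 1.0)            # C
    trough_dev = stretch - veir                  # <= 0
    out = np.full((n, max_f), np.nan)
    t = np.arange(max_f)
    live = t[None, :] < n_frames[:, None]

    dev = np.zeros((n, max_f))
    dev[:, PEAK_FRAMES[0]:PEAK_FRAMES[1] + 1] = stretch[:, None]
    dev[:, TROUGH_FRAMES[0]:TROUGH_FRAMES[1] + 1] = trough_dev[:, None]
    k = t - TROUGH_FRAMES[1]                     # 1, 2, ... past the trough
    tail = t > TROUGH_FRAMES[1]
    decay = np.where(tail, (-RECOIL_DECAY) ** np.where(tail, k, 0), 0.0)
    # asymmetric recoil: re-expansion above rest length is capped below the
    # stretch amplitude so the junction peak stays the global maximum for
    # every feasible VEIR (deep undershoots would otherwise rebound past it)
    dev[:, tail] = np.minimum(trough_dev[:, None] * decay[None, tail],
                              0.9 * stretch[:, None])
    out = np.where(live, d[:, None] + dev, np.nan)
    return out


def _transverse_series(d: np.ndarray, axial: np.ndarray) -> np.ndarray:
    """Area-preserving during the junction stretch; isotropic downstream.

    Hydrodynamic stress elongates the cell only at the junction (frames up
    to the stretch plateau); once released the cell is round again and its
    apparent diameter rings down, so every relaxation frame has aspect
    ratio 1 and the stretch peak is always the frame of maximal aspect
    ratio — the AR estimator reads the true AR exactly on noise-free traces.
    """
    d2 = d[:, None]
    trans = np.where(axial >= d2, d2**2 / axial, axial)
    t = np.arange(axial.shape[1])[None, :]
    return np.where(t <= PEAK_FRAMES[1], trans, axial)


def check_feasible(d: np.ndarray, ar: np.ndarray, veir: np.ndarray,
                   cell_id: np.ndarray | None = None) -> None:
    from .synth_cohort import veir_feasible_bounds
    lo, hi = veir_feasible_bounds(np.asarray(d, float), np.asarray(ar, float))
    bad = (veir < lo - FEASIBILITY_TOL) | (veir > hi + FEASIBILITY_TOL)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        name = cell_id[idx] if cell_id is not None else f"#{idx}"
        raise ValueError(
            f"cell {name}: VEIR {veir[idx]:.4g} outside the realizable "
            f"interval [{lo[idx]:.4g}, {hi[idx]:.4g}] of the recoil waveform")


def synthesize_traces(cells: pd.DataFrame, acq: AcquisitionParams,
                      rng: np.random.Generator) -> TraceBatch:
    """Vectorized trace synthesis for a cell-truth table.

    ``cells`` needs columns cell_id, subject_id, size, true_ar, true_veir,
    intensity and optionally true_type (type 'bead' forces a rigid sphere).
    """
    n = len(cells)
    d = cells["size"].to_numpy(dtype=float)
    ar = cells["true_ar"].to_numpy(dtype=float)
    veir = cells["true_veir"].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy()
    if "true_type" in cells:
        is_bead = (cells["true_type"].to_numpy() == "bead")
    else:
        is_bead = np.zeros(n, dtype=bool)
    ar = np.where(is_bead, 1.0, ar)
    veir = np.where(is_bead, 0.0, veir)
    check_feasible(d, ar, veir, ids)

    n_frames = rng.integers(acq.min_frames, acq.max_frames + 1, size=n)
    max_f = int(n_frames.max())
    axial = _axial_series(d, ar, veir, n_frames, max_f)
    trans = _transverse_series(d, axial)

    t = np.arange(max_f)[None, :]
    x0 = acq.junction_position_um - (PEAK_FRAMES[0] + 0.5) * acq.nominal_speed_um_per_frame
    x = x0 + t * acq.nominal_speed_um_per_frame + np.zeros((n, 1))
    y = np.zeros((n, max_f))

    sd = acq.descriptor_noise_sd_um
    if sd > 0:
        axial = axial + sd * rng.standard_normal(axial.shape)
        trans = trans + sd * rng.standard_normal(trans.shape)
        x = x + sd * rng.standard_normal(x.shape)
        y = y + sd * rng.standard_normal(y.shape)
        axial = np.maximum(axial, AXIS_FLOOR_UM)
        trans = np.maximum(trans, AXIS_FLOOR_UM)

    live = ~np.isnan(axial)
    major = np.where(live, np.maximum(axial, trans), np.nan)
    minor = np.where(live, np.minimum(axial, trans), np.nan)
    orientation = np.where(live, np.where(axial >= trans, 0.0, np.pi / 2), np.nan)
    x = np.where(live, x, np.nan)
    y = np.where(live, y, np.nan)

    subject = (cells["subject_id"].to_numpy() if "subject_id" in cells
               else np.array([""] * n, dtype=object))
    intensity = (cells["intensity"].to_numpy(dtype=float) if "intensity" in cells
                 else np.full(n, np.nan))
    return TraceBatch(cell_id=ids, subject_id=subject, is_bead=is_bead,
                      intensity=intensity, n_frames=n_frames.astype(int),
                      x=x, y=y, major=major, minor=minor, orientation=orientation)


def synthesize_trace(cell, acq: AcquisitionParams,
                     rng: np.random.Generator) -> EventTrace:
    """Single-event convenience wrapper around :func:`synthesize_traces`.

    ``cell`` is a mapping with cell_id, size, true_ar, true_veir and
    optionally subject_id / intensity / true_type.
    """
    row = {"cell_id": cell["cell_id"], "size": cell["size"],
           "true_ar": cell["true_ar"], "true_veir": cell["true_veir"],
           "subject_id": cell.get("subject_id", ""),
           "intensity": cell.get("intensity", np.nan),
           "true_type": cell.get("true_type", "unknown")}
    batch = synthesize_traces(pd.DataFrame([row]), acq, rng)
    frames = [FrameDescriptor(t=int(t), x=float(batch.x[0, t]), y=float(batch.y[0, t]),
                              major_axis=float(batch.major[0, t]),
                              minor_axis=float(batch.minor[0, t]),
                              orientation=float(batch.orientation[0, t]))
              for t in range(int(batch.n_frames[0]))]
    return EventTrace(cell_id=str(row["cell_id"]), frames=frames,
                      is_bead=bool(batch.is_bead[0]),
                      intensity=float(batch.intensity[0]))


def synthesize_bead_run(n_beads: int, acq: AcquisitionParams,
                        clogged: bool, rng: np.random.Generator,
                        deflected_fraction: float = 0.4) -> TraceBatch:
    """Control-bead traces for run QC.

    Unobstructed flow gives straight centroid paths at ~nominal speed (2% SD);
    a clogged junction deflects >= 30% of beads transversely and slows them by
    at least 25%.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    n_frames = rng.integers(acq.min_frames, acq.max_frames + 1, size=n_beads)
    max_f = int(n_frames.max())
    t = np.arange(max_f)[None, :]
    live = t < n_frames[:, None]

    speed = rng.normal(acq.nominal_speed_um_per_frame,
                       0.02 * acq.nominal_speed_um_per_frame, n_beads)
    drift = np.zeros(n_beads)
    if clogged:
        n_defl = max(int(np.ceil(deflected_fraction * n_beads)),
                     int(np.ceil(0.3 * n_beads)))
        defl = rng.choice(n_beads, size=n_defl, replace=False)
        sign = rng.choice([-1.0, 1.0], size=n_defl)
        drift[defl] = sign * rng.uniform(0.15, 0.40, n_defl)
        speed[defl] *= rng.uniform(0.50, 0.75, n_defl)

    x = speed[:, None] * t
    y = drift[:, None] * t
    d = np.full((n_beads, max_f), BEAD_DIAMETER_UM)
    sd = acq.descriptor_noise_sd_um
    if sd > 0:
        x = x + sd * rng.standard_normal(x.shape)
        y = y + sd * rng.standard_normal(y.shape)
        d = d + sd * rng.standard_normal(d.shape)
    a = np.where(live, d, np.nan)
    b = a.copy()
    major = np.maximum(a, b)
    return TraceBatch(
        cell_id=np.array([f"bead{i:05d}" for i in range(n_beads)]),
        subject_id=np.array([""] * n_beads, dtype=object),
        is_bead=np.ones(n_beads, dtype=bool),
        intensity=np.full(n_beads, np.nan),
        n_frames=n_frames.astype(int),
        x=np.where(live, x, np.nan), y=np.where(live, y, np.nan),
        major=major, minor=major.copy(),
        orientation=np.where(live, 0.0, np.nan))


PSF_SIGMA_PX = 1.0  # optical blur applied by the rasterizer


def rasterize_frame(frame: FrameDescriptor, acq: AcquisitionParams,
                    rng: np.random.Generator | None = None,
                    background: float = 0.05, foreground: float = 0.9,
                    shot_noise_scale: float = 0.0,
                    supersample: int = 4) -> np.ndarray:
    """Render one descriptor as a grayscale image (float in [0, ~1]).

    The ellipse is drawn filled with sub-pixel (supersampled) coverage at the
    frame's centroid — um coordinates are mapped so that the junction
    position sits at the image center — then blurred with a 1 px Gaussian
    PSF and optionally degraded with shot noise.
    """
    from skimage.filters import gaussian

    npx = acq.image_size_px
    upp = acq.um_per_pixel
    cx = (frame.x - acq.junction_position_um) / upp + npx / 2
    cy = frame.y / upp + npx / 2
    a = frame.major_axis / 2 / upp   # semi-axes in px
    b = frame.minor_axis / 2 / upp
    reach = max(a, b)
    if not (reach <= cx <= npx - 1 - reach and reach <= cy <= npx - 1 - reach):
        raise ValueError(
            f"frame t={frame.t}: ellipse (centre {cx:.1f},{cy:.1f} px, "
            f"semi-axes {a:.1f}/{b:.1f} px) does not fit the image")

    c, s = np.cos(frame.orientation), np.sin(frame.orientation)
    offsets = (np.arange(supersample) + 0.5) / supersample - 0.5
    coverage = np.zeros((npx, npx))
    yy, xx = np.mgrid[0:npx, 0:npx]
    for dy in offsets:
        for dx in offsets:
            xr = (xx + dx - cx) * c + (yy + dy - cy) * s
            yr = -(xx + dx - cx) * s + (yy + dy - cy) * c
            coverage += (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    coverage /= supersample**2
    img = background + (foreground - background) * coverage
    img = gaussian(img, sigma=PSF_SIGMA_PX, preserve_range=True)
    if shot_noise_scale > 0 and rng is not None:
        img = rng.poisson(img / shot_noise_scale) * shot_noise_scale
    return img
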