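"""Domain types for RF ultrasound data, ROI geometry, and the on-disk container.

Raw radiofrequency (RF) echo frames are the physical input to quantitative
ultrasound spectroscopy: unlike B-mode pixels, they retain the frequency-dependent
scattering information that the spectral estimators exploit.  This module defines
the in-memory types (:class:`RFFrame`, :class:`ROIContour`, :class:`ROIMask`),
a self-describing HDF5 container for frames + tumor contours + response labels,
contour rasterization onto the RF sample grid, and B-mode rendering for QC.

Coordinate convention (pulse-echo): axial depth of sample ``i`` is
``axial_origin + i * c / (2 * sampling_rate)``; lateral position of line ``j``
is ``j * lateral_pitch``.  Depths and contour vertices are expressed in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from matplotlib import path as _mpath
from scipy.signal import hilbert
from shapely.geometry import Polygon

__all__ = [
    "RFFrame",
    "ROIContour",
    "ROIMask",
    "FormatError",
    "ValidationError",
    "LinkageError",
    "read_rf_container",
    "write_rf_container",
    "rasterize_contour",
    "compute_bmode",
]


class ValidationError(ValueError):
    """An input violates a physical or structural invariant."""


class FormatError(ValueError):
    """An on-disk container is malformed (missing key, bad layout)."""


class LinkageError(ValueError):
    """Contours or labels refer to frames that do not exist."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

MIN_AXIAL_SAMPLES = 64
MIN_LINES = 8


@dataclass
class RFFrame:
    """One RF frame: axial-sample x scan-line matrix plus acquisition metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_axial, n_lines)
        RF amplitude in arbitrary linear units.
    sampling_rate, center_frequency, band_low, band_high : float
        Hz.  Defaults elsewhere in the package mimic a 6.5 MHz linear probe
        with a 3.0-8.5 MHz bandwidth.
    speed_of_sound : float
        m/s, default 1540 (soft tissue).
    lateral_pitch : float
        m between adjacent scan lines.
    axial_origin : float
        Depth (m) of the first axial sample.
    """

    samples: np.ndarray
    sampling_rate: float
    center_frequency: float = 6.5e6
    band_low: float = 3.0e6
    band_high: float = 8.5e6
    speed_of_sound: float = 1540.0
    lateral_pitch: float = 2.0e-4
    axial_origin: float = 0.0
    frame_id: str = "frame0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("RF samples must be a 2-D axial x line matrix")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("RF samples contain non-finite values")
        n_ax, n_ln = self.samples.shape
        if n_ax < MIN_AXIAL_SAMPLES or n_ln < MIN_LINES:
            raise ValidationError(
                f"frame too small: {n_ax}x{n_ln}, need >= "
                f"{MIN_AXIAL_SAMPLES} samples x {MIN_LINES} lines"
            )
        if self.sampling_rate <= 2.0 * self.band_high:
            raise ValidationError(
                f"Nyquist violation: sampling_rate {self.sampling_rate:g} Hz "
                f"<= 2 x band_high {self.band_high:g} Hz"
            )
        if not (self.band_low < self.center_frequency < self.band_high):
            raise ValidationError("center_frequency must lie inside the band")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_mm(self) -> np.ndarray:
        """Depth of each axial sample centre, mm."""
        step = self.speed_of_sound / (2.0 * self.sampling_rate)
        return (self.axial_origin + np.arange(self.n_axial) * step) * 1e3

    @property
    def lateral_mm(self) -> np.ndarray:
        """Lateral position of each scan line, mm."""
        return np.arange(self.n_lines) * self.lateral_pitch * 1e3

    @property
    def axial_sample_mm(self) -> float:
        """Axial spacing between sample centres, mm (pulse-echo)."""
        return self.speed_of_sound / (2.0 * self.sampling_rate) * 1e3


@dataclass
class ROIContour:
    """Closed tumor contour in physical coordinates (axial mm, lateral mm)."""

    vertices: np.ndarray
    frame_id: str = "frame0"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("contour vertices must be an N x 2 array")
        # close implicitly
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValidationError("contour needs >= 3 distinct vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError("contour vertices must be finite")
        self.vertices = v

    @property
    def closed_vertices(self) -> np.ndarray:
        return np.vstack([self.vertices, self.vertices[:1]])

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class ROIMask:
    """Boolean mask congruent with an RFFrame's sample grid."""

    grid: np.ndarray
    frame_id: str = "frame0"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if not self.grid.any():
            raise ValidationError("mask has no true elements")


@dataclass
class LabelRecord:
    patient_id: str
    frame_id: str
    response: str  # "R" or "NR"

    def __post_init__(self) -> None:
        if self.response not in ("R", "NR"):
            raise ValidationError(f"response must be 'R' or 'NR', got {self.response!r}")


# ---------------------------------------------------------------------------
# Container I/O (HDF5)
# ---------------------------------------------------------------------------

_FRAME_ATTRS = (
    "sampling_rate_hz",
    "center_frequency_hz",
    "band_low_hz",
    "band_high_hz",
    "speed_of_sound_m_s",
    "lateral_pitch_m",
    "axial_origin_m",
)

_LABEL_DTYPE = np.dtype(
    [("patient_id", "S32"), ("frame_id", "S32"), ("response", "S4")]
)


def write_rf_container(frames, contours, labels, path) -> str:
    """Write frames, contours and labels to a self-describing HDF5 container.

    Writing is deterministic: identical inputs produce byte-identical files
    (groups are written in sorted order and HDF5 timestamps are disabled).
    """
    frames = list(frames)
    contours = list(contours)
    labels = list(labels)
    if not frames:
        raise ValidationError("refusing to write a container with no frames")
    frame_ids = {f.frame_id for f in frames}
    if len(frame_ids) != len(frames):
        raise ValidationError("duplicate frame_id in frames")
    for c in contours:
        if c.frame_id not in frame_ids:
            raise LinkageError(f"contour references unknown frame_id {c.frame_id!r}")
    for lab in labels:
        if lab.frame_id not in frame_ids:
            raise LinkageError(f"label references unknown frame_id {lab.frame_id!r}")

    with h5py.File(path, "w", track_order=False) as h5:
        h5.attrs["format"] = "qusrad-rf-container"
        h5.attrs["version"] = 1
        gf = h5.create_group("frames")
        for f in sorted(frames, key=lambda f: f.frame_id):
            g = gf.create_group(f.frame_id)
            g.create_dataset(
                "rf", data=f.samples.astype(np.float32), track_times=False
            )
            meta = {
                "sampling_rate_hz": f.sampling_rate,
                "center_frequency_hz": f.center_frequency,
                "band_low_hz": f.band_low,
                "band_high_hz": f.band_high,
                "speed_of_sound_m_s": f.speed_of_sound,
                "lateral_pitch_m": f.lateral_pitch,
                "axial_origin_m": f.axial_origin,
            }
            for k in _FRAME_ATTRS:
                g.attrs[k] = float(meta[k])
            # JSON copy of the metadata for language-neutral consumers
            g.create_dataset(
                "metadata_json",
                data=json.dumps(meta, sort_keys=True),
                track_times=False,
            )
        gc = h5.create_group("contours")
        for c in sorted(contours, key=lambda c: c.frame_id):
            g = gc.create_group(c.frame_id)
            g.create_dataset(
                "vertices", data=c.vertices.astype(np.float64), track_times=False
            )
        rec = np.array(
            [
                (l.patient_id.encode(), l.frame_id.encode(), l.response.encode())
                for l in sorted(labels, key=lambda l: (l.patient_id, l.frame_id))
            ],
            dtype=_LABEL_DTYPE,
        )
        h5.create_dataset("labels", data=rec, track_times=False)
    return str(path)


def read_rf_container(path):
    """Read a container written by :func:`write_rf_container`.

    Returns ``(frames, contours, labels)`` with metadata round-tripped
    bit-exact; contours are linked to frames by ``frame_id``.
    """
    frames, contours, labels = [], [], []
    with h5py.File(path, "r") as h5:
        if "frames" not in h5:
            raise FormatError("missing group 'frames'")
        for fid in sorted(h5["frames"]):
            g = h5["frames"][fid]
            for k in _FRAME_ATTRS:
                if k not in g.attrs:
                    raise FormatError(f"frame {fid!r} missing metadata key {k!r}")
            frames.append(
                RFFrame(
                    samples=np.asarray(g["rf"], dtype=np.float64),
                    sampling_rate=float(g.attrs["sampling_rate_hz"]),
                    center_frequency=float(g.attrs["center_frequency_hz"]),
                    band_low=float(g.attrs["band_low_hz"]),
                    band_high=float(g.attrs["band_high_hz"]),
                    speed_of_sound=float(g.attrs["speed_of_sound_m_s"]),
                    lateral_pitch=float(g.attrs["lateral_pitch_m"]),
                    axial_origin=float(g.attrs["axial_origin_m"]),
                    frame_id=fid,
                )
            )
        if "contours" in h5:
            for fid in sorted(h5["contours"]):
                contours.append(
                    ROIContour(
                        vertices=np.asarray(h5["contours"][fid]["vertices"]),
                        frame_id=fid,
                    )
                )
        if "labels" in h5:
            for row in np.asarray(h5["labels"]):
                labels.append(
                    LabelRecord(
                        patient_id=row["patient_id"].decode(),
                        frame_id=row["frame_id"].decode(),
                        response=row["response"].decode(),
                    )
                )
    return frames, contours, labels


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def rasterize_contour(contour: ROIContour, frame: RFFrame) -> ROIMask:
    """Rasterize a physical-mm contour onto the frame's sample grid.

    A sample-grid cell is included when its centre lies inside the closed
    polygon (even-odd rule, orientation independent).
    """
    poly = contour.polygon()
    if poly.area <= 0.0:
        raise ValidationError("degenerate contour: zero area")
    ax = frame.axial_mm
    lat = frame.lateral_mm
    if (
        contour.vertices[:, 0].min() < ax[0] - frame.axial_sample_mm
        or contour.vertices[:, 0].max() > ax[-1] + frame.axial_sample_mm
        or contour.vertices[:, 1].min() < lat[0] - frame.lateral_pitch * 1e3
        or contour.vertices[:, 1].max() > lat[-1] + frame.lateral_pitch * 1e3
    ):
        raise ValidationError("contour extends outside frame physical extent")
    # even-odd point-in-polygon on sample centres; restrict to the bounding box
    i0 = int(np.searchsorted(ax, contour.vertices[:, 0].min()) - 1)
    i1 = int(np.searchsorted(ax, contour.vertices[:, 0].max()) + 1)
    j0 = int(np.searchsorted(lat, contour.vertices[:, 1].min()) - 1)
    j1 = int(np.searchsorted(lat, contour.vertices[:, 1].max()) + 1)
    i0, j0 = max(i0, 0), max(j0, 0)
    i1, j1 = min(i1, frame.n_axial), min(j1, frame.n_lines)
    grid = np.zeros((frame.n_axial, frame.n_lines), dtype=bool)
    if i1 > i0 and j1 > j0:
        aa, ll = np.meshgrid(ax[i0:i1], lat[j0:j1], indexing="ij")
        pts = np.column_stack([aa.ravel(), ll.ravel()])
        mp = _mpath.Path(contour.closed_vertices)
        inside = mp.contains_points(pts)
        grid[i0:i1, j0:j1] = inside.reshape(aa.shape)
    if not grid.any():
        raise ValidationError("contour encloses no sample centres (empty mask)")
    return ROIMask(grid=grid, frame_id=contour.frame_id)


# ---------------------------------------------------------------------------
# B-mode rendering
# ---------------------------------------------------------------------------


def compute_bmode(frame: RFFrame, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Log-compressed echo envelope, normalized to peak.

    Envelope is the analytic-signal magnitude per scan line; output is mapped
    to [0, dynamic_range_db] (0 = at or below -DR dB relative to the peak).
    Invariant to global amplitude scaling of the RF frame.
    """
    if dynamic_range_db <= 0:
        raise ValidationError("dynamic_range_db must be positive")
    env = np.abs(hilbert(frame.samples, axis=0))
    peak = env.max()
    if peak <= 0:
        raise ValidationError("all-zero frame: envelope has no peak")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return np.clip(db, -dynamic_range_db, 0.0) + dynamic_range_db


def save_bmode_png(image: np.ndarray, path, dynamic_range_db: float = 60.0) -> None:
    """Export a B-mode image as 8-bit grayscale PNG (QC figure)."""
    from PIL import Image

    u8 = np.round(image / dynamic_range_db * 255.0).astype(np.uint8)
    Image.fromarray(u8, mode="L").save(path)
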