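"""Reading cine long-axis image series and mapping pixels to patient space.

A cine series is a stack of 2D grayscale frames, one per reconstructed
cardiac phase, acquired in a fixed imaging plane. The plane's position and
orientation in the DICOM LPS patient coordinate system come from the
ImagePositionPatient / ImageOrientationPatient / PixelSpacing header tags;
timing comes from the nominal RR interval (or, failing that, trigger times).

Pixel convention: 0-based fractional (row, col) indices addressing pixel
*centers*. ``row_dir`` is the direction cosine of increasing column index
(the first ImageOrientationPatient triplet, i.e. "along a row") and
``col_dir`` the direction of increasing row index; ``spacing`` is
(row_spacing, col_spacing) = PixelSpacing, the distance between adjacent
rows and adjacent columns respectively.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("masweep")

VIEW_LABELS = ("two_chamber", "three_chamber", "four_chamber")

_ORTHO_TOL = 1e-3
FIXTURE_SIDECAR = "geometry.json"
#: fixture PNG frames are uint16 scaled by this factor from float intensity
FIXTURE_INTENSITY_SCALE = 20000.0


@dataclass
class CineView:
    """One long-axis cine series with its spatial and temporal geometry."""

    view_label: str
    frames: np.ndarray            # (P, H, W) float intensities
    origin: np.ndarray            # (3,) mm, center of pixel (0, 0), LPS
    row_dir: np.ndarray           # (3,) unit, direction of increasing column
    col_dir: np.ndarray           # (3,) unit, direction of increasing row
    spacing: tuple[float, float]  # (row_spacing_mm, col_spacing_mm)
    rr_interval_ms: float

    def __post_init__(self) -> None:
        if self.view_label not in VIEW_LABELS:
            raise ValueError(f"unknown view label {self.view_label!r}")
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ValueError("frames must be a (P, H, W) stack")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.row_dir = _unit(np.asarray(self.row_dir, dtype=float).reshape(3))
        self.col_dir = _unit(np.asarray(self.col_dir, dtype=float).reshape(3))
        if abs(float(self.row_dir @ self.col_dir)) >= _ORTHO_TOL:
            raise ValueError("row_dir and col_dir are not orthogonal")
        rs, cs = self.spacing
        if rs <= 0 or cs <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.rr_interval_ms <= 0:
            raise ValueError("RR interval must be positive")

    @property
    def n_phases(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def plane_normal(self) -> np.ndarray:
        return np.cross(self.row_dir, self.col_dir)

    def phase_times_ms(self) -> np.ndarray:
        p = self.n_phases
        return np.arange(p) * (self.rr_interval_ms / p)


@dataclass
class StudyGeometry:
    """The three long-axis views of one study, with consistent P and RR."""

    views: dict[str, CineView] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = sorted(self.views)
        if labels != sorted(VIEW_LABELS):
            raise ValueError(
                f"a study needs exactly the views {VIEW_LABELS}, got {labels}"
            )
        phases = {v.n_phases for v in self.views.values()}
        if len(phases) != 1:
            raise ValueError(f"views disagree on phase count: {phases}")
        rrs = {round(v.rr_interval_ms, 6) for v in self.views.values()}
        if len(rrs) != 1:
            raise ValueError(f"views disagree on RR interval: {rrs}")

    @property
    def n_phases(self) -> int:
        return next(iter(self.views.values())).n_phases

    @property
    def rr_interval_ms(self) -> float:
        return next(iter(self.views.values())).rr_interval_ms


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


# ---------------------------------------------------------------------------
# coordinate mapping
# ---------------------------------------------------------------------------

def pixel_to_patient(view: CineView, pixel: tuple[float, float]) -> np.ndarray:
    """Map a fractional (row, col) pixel index to a 3D patient point in mm.

    Pure affine map: origin + row * row_spacing * col_dir
    + col * col_spacing * row_dir. Out-of-bounds pixels are allowed (the
    plane extends beyond the image) but logged.
    """
    row, col = float(pixel[0]), float(pixel[1])
    h, w = view.shape
    if not (0 <= row <= h - 1 and 0 <= col <= w - 1):
        logger.warning(
            "pixel (%.2f, %.2f) outside %dx%d image of %s view",
            row, col, h, w, view.view_label,
        )
    rs, cs = view.spacing
    return view.origin + row * rs * view.col_dir + col * cs * view.row_dir


def patient_to_pixel(view: CineView, point: np.ndarray) -> tuple[float, float]:
    """Project a 3D patient point onto the view plane, returning (row, col).

    Inverse of :func:`pixel_to_patient` for in-plane points; the component
    normal to the plane is discarded.
    """
    d = np.asarray(point, dtype=float) - view.origin
    rs, cs = view.spacing
    return float(d @ view.col_dir) / rs, float(d @ view.row_dir) / cs


# ---------------------------------------------------------------------------
# DICOM loading
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = {
    "ImagePositionPatient": "(0020,0032)",
    "ImageOrientationPatient": "(0020,0037)",
    "PixelSpacing": "(0028,0030)",
}


def load_dicom_view(path: str | Path, view_label: str) -> CineView:
    """Read one single-slice cine DICOM series from a directory.

    Frames are sorted by TriggerTime when present, otherwise by
    InstanceNumber; phase 0 is taken as end-diastole (retrospective gating).
    The RR interval comes from NominalInterval when present, otherwise it is
    extrapolated as P x (mean inter-trigger spacing).
    """
    import pydicom

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "pixel_array") or "PixelData" in ds:
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM image files found in {path}")

    for name, tag in _REQUIRED_TAGS.items():
        for ds in datasets:
            if getattr(ds, name, None) is None:
                raise ValueError(f"missing geometry tag {name} {tag} in series")

    if all(getattr(ds, "TriggerTime", None) is not None for ds in datasets):
        datasets.sort(key=lambda ds: float(ds.TriggerTime))
        logger.info("sorted %s series by TriggerTime", view_label)
    else:
        datasets.sort(key=lambda ds: int(ds.InstanceNumber))
        logger.info("sorted %s series by InstanceNumber", view_label)

    ref = datasets[0]
    ipp = np.asarray([float(x) for x in ref.ImagePositionPatient])
    iop = np.asarray([float(x) for x in ref.ImageOrientationPatient])
    spacing = tuple(float(x) for x in ref.PixelSpacing)
    for ds in datasets[1:]:
        if not np.allclose([float(x) for x in ds.ImagePositionPatient], ipp, atol=1e-4):
            raise ValueError("inconsistent ImagePositionPatient across frames")
        if not np.allclose([float(x) for x in ds.ImageOrientationPatient], iop, atol=1e-6):
            raise ValueError("inconsistent ImageOrientationPatient across frames")
        if not np.allclose([float(x) for x in ds.PixelSpacing], spacing, atol=1e-6):
            raise ValueError("inconsistent PixelSpacing across frames")

    frames = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    rr = _rr_interval_ms(datasets)
    return CineView(
        view_label=view_label,
        frames=frames,
        origin=ipp,
        row_dir=iop[:3],
        col_dir=iop[3:],
        spacing=spacing,
        rr_interval_ms=rr,
    )


def _rr_interval_ms(datasets) -> float:
    nominal = getattr(datasets[0], "NominalInterval", None)
    if nominal:
        logger.info("RR interval from NominalInterval: %s ms", nominal)
        return float(nominal)
    triggers = [getattr(ds, "TriggerTime", None) for ds in datasets]
    if any(t is None for t in triggers) or len(triggers) < 2:
        raise ValueError(
            "cannot determine RR interval: missing tag NominalInterval "
            "(0018,1062) and no usable TriggerTime (0018,1060) sequence"
        )
    tt = np.asarray([float(t) for t in triggers])
    rr = len(tt) * float(np.mean(np.diff(tt)))
    logger.info("RR interval extrapolated from trigger times: %.1f ms", rr)
    return rr


# ---------------------------------------------------------------------------
# plain-text fixture format: PNG frames + JSON geometry sidecar
# ---------------------------------------------------------------------------

def load_fixture_view(study_dir: str | Path, view_label: str) -> CineView:
    """Load one view of the download-free fixture format.

    Layout: ``<study_dir>/geometry.json`` plus one subdirectory per view
    holding 16-bit PNG frames named ``frame_###.png`` in phase order.
    """
    study_dir = Path(study_dir)
    sidecar = json.loads((study_dir / FIXTURE_SIDECAR).read_text())
    meta = sidecar["views"][view_label]
    frame_dir = study_dir / view_label
    frame_files = sorted(frame_dir.glob("frame_*.png"))
    if len(frame_files) != meta["n_phases"]:
        raise ValueError(
            f"{view_label}: sidecar declares {meta['n_phases']} phases but "
            f"{len(frame_files)} frames found"
        )
    import imageio.v3 as iio

    frames = np.stack(
        [iio.imread(f).astype(float) / FIXTURE_INTENSITY_SCALE for f in frame_files]
    )
    return CineView(
        view_label=view_label,
        frames=frames,
        origin=np.asarray(meta["origin"], float),
        row_dir=np.asarray(meta["row_dir"], float),
        col_dir=np.asarray(meta["col_dir"], float),
        spacing=tuple(meta["spacing"]),
        rr_interval_ms=float(meta["rr_interval_ms"]),
    )


def load_study(study_dir: str | Path, dicom: bool = False) -> StudyGeometry:
    """Load all three long-axis views of a study directory."""
    loader = load_dicom_view if dicom else load_fixture_view
    views = {lbl: loader(Path(study_dir) if not dicom else Path(study_dir) / lbl, lbl)
             for lbl in VIEW_LABELS}
    return StudyGeometry(views=views)


def write_fixture_study(study: StudyGeometry, out_dir: str | Path) -> Path:
    """Write a StudyGeometry in the fixture format (PNG frames + sidecar)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {"views": {}}
    for lbl, view in study.views.items():
        vd = out_dir / lbl
        vd.mkdir(exist_ok=True)
        for i, frame in enumerate(view.frames):
            img = np.clip(frame * FIXTURE_INTENSITY_SCALE, 0, 65535).astype(np.uint16)
            iio.imwrite(vd / f"frame_{i:03d}.png", img)
        sidecar["views"][lbl] = {
            "origin": list(view.origin),
            "row_dir": list(view.row_dir),
            "col_dir": list(view.col_dir),
            "spacing": list(view.spacing),
            "rr_interval_ms": view.rr_interval_ms,
            "n_phases": view.n_phases,
        }
    sidecar["rr_interval_ms"] = study.rr_interval_ms
    sidecar["n_phases"] = study.n_phases
    (out_dir / FIXTURE_SIDECAR).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return out_dir
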