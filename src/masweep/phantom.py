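"""Synthetic three-view cine phantom of a moving mitral annulus.

The phantom prescribes an analytic annular motion — systolic descent toward
the apex, early-diastolic (E-wave) recovery of a set fraction of the
descent, a diastasis plateau, and atrial-systolic (A-wave) recovery of the
remainder — and renders it into three long-axis image planes 60 degrees
apart through a common long axis, mimicking the two-, three- and
four-chamber cine views. Each view shows the two annulus-plane intersection
points as high-contrast textured blobs that the NCC tracker can lock onto,
over simple blood-pool / myocardium bands; optional Gaussian blur and noise
are applied after the ground truth is captured.

The E and A waves are raised-cosine velocity pulses: infinitely smooth,
with closed-form integrals and peak velocities, so the prescribed E:A
peak-velocity ratio and recovered-volume fractions are exact. The analytic
profile yields a ground-truth sweep curve and ground-truth diastolic
parameters (computed at dense temporal sampling) against which the full
pipeline can be validated without any image data downloads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import diastology
from .annulus import SweepCurve
from .cine_io import CineView, StudyGeometry

logger = logging.getLogger("masweep")

#: view-plane azimuths about the long axis (degrees)
VIEW_ANGLES_DEG = {"four_chamber": 0.0, "three_chamber": 60.0, "two_chamber": 120.0}

#: dense sampling used for the analytic ground-truth curve
TRUTH_SAMPLES = 2000


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, motion and imaging parameters of the synthetic study.

    Timing fractions (systole, early diastole, diastasis, atrial systole)
    are fractions of the RR interval and must sum to 1. ``ea_peak_ratio``
    prescribes the ratio of peak E-wave to peak A-wave axial velocity; the
    raised-cosine pulses are narrowed inside their intervals to honor it.
    Defaults emulate a normal-function subject: 15 mm annular radius, 12 mm
    systolic descent with 70% early-diastolic recovery, 25 phases over an
    857 ms cycle (~70 bpm).
    """

    radius_mm: float = 15.0
    saddle_height_mm: float = 2.0
    systolic_descent_mm: float = 12.0
    e_fraction: float = 0.7
    ea_peak_ratio: float = 2.0
    timing: tuple[float, float, float, float] = (0.35, 0.20, 0.25, 0.20)
    rr_ms: float = 857.0
    n_phases: int = 25
    size_px: int = 96
    spacing_mm: float = 1.0
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    base_depth_mm: float = 30.0     # annulus depth at end-diastole
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.timing) - 1.0) > 1e-9:
            raise ValueError("timing fractions must sum to 1")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.n_phases < 8:
            raise ValueError("need at least 8 phases")
        if not 0.0 <= self.e_fraction <= 1.0:
            raise ValueError("e_fraction must lie in [0, 1]")


@dataclass
class MotionProfile:
    """Analytic axial displacement z(t) of the annular centroid (mm, apex-
    positive) and its closed-form pulse parameters."""

    spec: PhantomSpec
    t_sys_ms: float
    t_ed_ms: float          # duration of early diastole
    t_as_ms: float
    e_pulse_start_ms: float
    e_pulse_width_ms: float
    a_pulse_start_ms: float
    a_pulse_width_ms: float

    @property
    def delta_e_mm(self) -> float:
        return self.spec.e_fraction * self.spec.systolic_descent_mm

    @property
    def delta_a_mm(self) -> float:
        return (1.0 - self.spec.e_fraction) * self.spec.systolic_descent_mm

    @property
    def peak_e_velocity_mm_s(self) -> float:
        if self.e_pulse_width_ms == 0:
            return 0.0
        return 2.0 * self.delta_e_mm / (self.e_pulse_width_ms / 1000.0)

    @property
    def peak_a_velocity_mm_s(self) -> float:
        if self.a_pulse_width_ms == 0:
            return 0.0
        return 2.0 * self.delta_a_mm / (self.a_pulse_width_ms / 1000.0)

    def z(self, t_ms) -> np.ndarray | float:
        """Axial displacement at time(s) ``t_ms`` within [0, RR]."""
        scalar = np.ndim(t_ms) == 0
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        d = self.spec.systolic_descent_mm
        ts = self.t_sys_ms
        out = np.zeros_like(t)
        if d != 0:
            # systolic descent: half-cosine ramp 0 -> D
            sys_mask = t < ts
            out[sys_mask] = 0.5 * d * (1 - np.cos(np.pi * t[sys_mask] / ts))
            out[~sys_mask] = d
            out -= self.delta_e_mm * _pulse_integral(
                t, self.e_pulse_start_ms, self.e_pulse_width_ms)
            out -= self.delta_a_mm * _pulse_integral(
                t, self.a_pulse_start_ms, self.a_pulse_width_ms)
        return float(out[0]) if scalar else out

    def zdot(self, t_ms) -> np.ndarray | float:
        """Axial velocity in mm/s (positive toward the apex)."""
        scalar = np.ndim(t_ms) == 0
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        d = self.spec.systolic_descent_mm
        ts = self.t_sys_ms
        out = np.zeros_like(t)
        if d != 0:
            sys_mask = t < ts
            out[sys_mask] = 0.5 * d * np.pi / ts * np.sin(np.pi * t[sys_mask] / ts)
            out -= self.delta_e_mm * _pulse_rate(
                t, self.e_pulse_start_ms, self.e_pulse_width_ms)
            out -= self.delta_a_mm * _pulse_rate(
                t, self.a_pulse_start_ms, self.a_pulse_width_ms)
        out *= 1000.0
        return float(out[0]) if scalar else out


def _pulse_integral(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """Fraction of a raised-cosine velocity pulse completed by time t."""
    if width == 0:
        return np.zeros_like(t)
    s = np.clip((t - start) / width, 0.0, 1.0)
    return s - np.sin(2 * np.pi * s) / (2 * np.pi)


def _pulse_rate(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """d/dt of the pulse fraction (per ms): (1 - cos 2 pi s) / width."""
    if width == 0:
        return np.zeros_like(t)
    s = (t - start) / width
    inside = (s >= 0) & (s <= 1)
    out = np.zeros_like(t)
    out[inside] = (1 - np.cos(2 * np.pi * s[inside])) / width
    return out


def spec_for_peak_ratio(ea_peak_ratio: float, **kwargs) -> PhantomSpec:
    """Phantom spec prescribing an E:A peak-velocity ratio physiologically.

    In real diastology a depressed e'/a' ratio goes hand in hand with a
    reduced early-filling fraction, so this constructor co-varies
    ``e_fraction`` with the prescribed ratio such that both recovery pulses
    span their full intervals: with full-width raised-cosine pulses the peak
    ratio is (dE/T_ED)/(dA/T_AS), giving
    e_fraction = rho T_ED / (rho T_ED + T_AS). Keeping both pulses at full
    width also keeps them resolvable at coarse (25-phase) cine sampling
    across the whole 0.5-3.0 ratio range.
    """
    timing = kwargs.pop("timing", PhantomSpec.timing)
    _, f_ed, _, f_as = timing
    e_fraction = ea_peak_ratio * f_ed / (ea_peak_ratio * f_ed + f_as)
    return PhantomSpec(ea_peak_ratio=ea_peak_ratio, e_fraction=e_fraction,
                       timing=timing, **kwargs)


def build_motion_profile(spec: PhantomSpec) -> MotionProfile:
    """Place the E/A raised-cosine pulses to honor the prescribed peak ratio.

    The wider interval keeps a full-width pulse; the other pulse is narrowed
    (raising its peak) or the roles swap, until both peak velocities sit in
    the requested ratio. If no placement fits inside the stated interval
    durations, the timing is declared incompatible.
    """
    f_sys, f_ed, f_md, f_as = spec.timing
    t = spec.rr_ms
    t_sys, t_ed, t_as = f_sys * t, f_ed * t, f_as * t
    d_e = spec.e_fraction * spec.systolic_descent_mm
    d_a = (1 - spec.e_fraction) * spec.systolic_descent_mm
    rho = spec.ea_peak_ratio
    if rho <= 0:
        raise ValueError("ea_peak_ratio must be positive")

    if d_e == 0 and d_a == 0:          # null motion: no recovery waves
        w_e, w_a = 0.0, 0.0
    elif d_e == 0 or d_a == 0:
        raise ValueError(
            "timing fractions incompatible with requested ea_peak_ratio: "
            "one recovery wave has zero volume (e_fraction 0 or 1)"
        )
    else:
        w_e = t_ed
        v_e = 2 * d_e / t_ed
        w_a = 2 * d_a / (v_e / rho)
        if w_a > t_as + 1e-9:
            w_a = t_as
            v_a = 2 * d_a / t_as
            w_e = 2 * d_e / (rho * v_a)
            if w_e > t_ed + 1e-9:
                raise ValueError(
                    "timing fractions incompatible with requested ea_peak_ratio"
                )
    ed_start = t_sys
    as_start = t - t_as
    return MotionProfile(
        spec=spec,
        t_sys_ms=t_sys,
        t_ed_ms=t_ed,
        t_as_ms=t_as,
        e_pulse_start_ms=ed_start + 0.5 * (t_ed - w_e),
        e_pulse_width_ms=w_e,
        a_pulse_start_ms=as_start + 0.5 * (t_as - w_a),
        a_pulse_width_ms=w_a,
    )


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Everything the pipeline should recover, known analytically."""

    motion: MotionProfile
    z_mm: np.ndarray                 # (P,) axial displacement per phase
    area_mm2: np.ndarray             # (P,) annular area per phase
    truth_curve: SweepCurve          # dense analytic sweep curve
    truth_params: diastology.DiastolicParameters
    avj_pixels: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def seeds(self) -> dict[str, dict[str, tuple[int, int]]]:
        """Integer phase-0 seed pixels for the tracker, per view and point."""
        return {
            view: {pt: (int(round(px[0, 0])), int(round(px[0, 1])))
                   for pt, px in pts.items()}
            for view, pts in self.avj_pixels.items()
        }


def analytic_truth(spec: PhantomSpec, n_dense: int = TRUTH_SAMPLES) -> PhantomTruth:
    """Ground-truth sweep curve and diastolic parameters for a spec.

    The annular area is constant (pi R^2); the cumulative sweep volume is
    therefore area x z(t). Parameters are computed from the analytic profile
    sampled densely in time, using the same diastology definitions the
    pipeline applies to measured curves.
    """
    motion = build_motion_profile(spec)
    area = np.pi * spec.radius_mm**2
    t_dense = np.arange(n_dense) * (spec.rr_ms / n_dense)
    cumulative = area * motion.z(t_dense)
    essv = float(cumulative.max())
    if essv <= 0:
        raise ValueError("phantom has no systolic excursion")
    curve = SweepCurve(
        increments_mm3=np.diff(cumulative),
        cumulative_mm3=cumulative,
        essv_mm3=essv,
        normalized=cumulative / essv,
        times_ms=t_dense,
        rr_interval_ms=spec.rr_ms,
        long_axis=np.array([0.0, 0.0, 1.0]),
    )
    rate = diastology.sweep_rate(curve)
    seg = diastology.segment_intervals(curve, rate)
    params = diastology.compute_parameters(curve, rate, seg)
    t_phase = np.arange(spec.n_phases) * (spec.rr_ms / spec.n_phases)
    return PhantomTruth(
        motion=motion,
        z_mm=motion.z(t_phase),
        area_mm2=np.full(spec.n_phases, area),
        truth_curve=curve,
        truth_params=params,
    )


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

#: per-point texture constants (spatial frequencies rad/px and phases) so the
#: septal and lateral blobs are distinctive and asymmetric
_TEXTURES = {
    "septal": (0.55, 0.80, 0.65, -0.70, 0.9, 2.1),
    "lateral": (0.75, 0.50, -0.60, 0.85, 2.4, 0.7),
}
_BLOB_SIGMA_PX = 5.0
_BLOB_AMPLITUDE = 0.9


def _blob(rows: np.ndarray, cols: np.ndarray, r0: float, c0: float,
          point_label: str) -> np.ndarray:
    a1, b1, a2, b2, p1, p2 = _TEXTURES[point_label]
    du = cols - c0
    dv = rows - r0
    env = np.exp(-(du**2 + dv**2) / (2 * _BLOB_SIGMA_PX**2))
    pattern = (0.5 + 0.25 * np.cos(a1 * du + b1 * dv + p1)
               + 0.25 * np.cos(a2 * du + b2 * dv + p2))
    return _BLOB_AMPLITUDE * env * pattern


def render_views(
    spec: PhantomSpec, truth: PhantomTruth | None = None
) -> tuple[StudyGeometry, PhantomTruth]:
    """Render the three-view cine study and record exact junction pixels.

    Planes intersect in the long axis (patient z, apex-positive) at 0/60/120
    degrees; image rows run along the long axis and columns across it. Noise
    and blur are applied after the truth pixels are captured; rendering is
    deterministic under a fixed seed.
    """
    if truth is None:
        truth = analytic_truth(spec)
    s = spec.size_px
    sp = spec.spacing_mm
    p = spec.n_phases
    t_phase = np.arange(p) * (spec.rr_ms / p)
    z_t = truth.motion.z(t_phase)
    depth = spec.base_depth_mm + z_t                       # mm from image top
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")

    views: dict[str, CineView] = {}
    for label, angle_deg in VIEW_ANGLES_DEG.items():
        theta = np.deg2rad(angle_deg)
        u_hat = np.array([np.cos(theta), np.sin(theta), 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        origin = -(s / 2) * sp * u_hat
        saddle = spec.saddle_height_mm * np.cos(2 * theta)
        row_t = (depth + saddle) / sp                      # (P,) continuous
        col_lat = s / 2 + spec.radius_mm / sp
        col_sep = s / 2 - spec.radius_mm / sp
        if (row_t.min() < 0 or row_t.max() > s - 1
                or col_sep < 0 or col_lat > s - 1):
            raise ValueError("annulus leaves the field of view")

        frames = np.empty((p, s, s))
        for n in range(p):
            img = np.full((s, s), 0.12)
            r_ann = row_t[n]
            cavity = (rows > r_ann) & (np.abs(cols - s / 2) < 0.8 * spec.radius_mm / sp)
            img[cavity] = 0.55
            atrium = (rows < r_ann - 3) & (np.abs(cols - s / 2) < 0.8 * spec.radius_mm / sp)
            img[atrium] = 0.35
            band = np.abs(np.abs(cols - s / 2) - spec.radius_mm / sp) < 2.5
            img[band & (rows > r_ann)] = 0.30
            img += _blob(rows, cols, r_ann, col_sep, "septal")
            img += _blob(rows, cols, r_ann, col_lat, "lateral")
            frames[n] = img

        truth.avj_pixels[label] = {
            "septal": np.column_stack([row_t, np.full(p, col_sep)]),
            "lateral": np.column_stack([row_t, np.full(p, col_lat)]),
        }
        if spec.blur_sigma > 0:
            for n in range(p):
                frames[n] = gaussian_filter(frames[n], spec.blur_sigma)
        if spec.noise_sigma > 0:
            frames += rng.normal(0.0, spec.noise_sigma, frames.shape)
        frames = np.clip(frames, 0.0, None)

        views[label] = CineView(
            view_label=label,
            frames=frames,
            origin=origin,
            row_dir=u_hat,
            col_dir=z_hat,
            spacing=(sp, sp),
            rr_interval_ms=spec.rr_ms,
        )
    return StudyGeometry(views=views), truth


def generate_phantom(spec: PhantomSpec | None = None
                     ) -> tuple[StudyGeometry, PhantomTruth]:
    """Convenience: analytic truth + rendered study for a (default) spec."""
    spec = spec or PhantomSpec()
    return render_views(spec, analytic_truth(spec))


def write_phantom_study(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Emit the fixture-format study, a truth JSON and a tracker seed file."""
    from .cine_io import write_fixture_study

    study, truth = generate_phantom(spec)
    out_dir = Path(out_dir)
    write_fixture_study(study, out_dir)
    tp = truth.truth_params
    truth_doc = {
        "z_mm": [float(v) for v in truth.z_mm],
        "area_mm2": [float(v) for v in truth.area_mm2],
        "essv_mm3": truth.truth_curve.essv_mm3,
        "truth_params": {k: v for k, v in tp.to_dict().items()
                         if isinstance(v, (int, float)) and np.isfinite(v)},
        "avj_pixels": {
            view: {pt: [[float(a), float(b)] for a, b in px]
                   for pt, px in pts.items()}
            for view, pts in truth.avj_pixels.items()
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    seeds = {v: {pt: list(px) for pt, px in pts.items()}
             for v, pts in truth.seeds().items()}
    (out_dir / "seeds.json").write_text(json.dumps(seeds, indent=1, sort_keys=True))
    logger.info("phantom study written to %s", out_dir)
    return out_dir


# ---------------------------------------------------------------------------
# auxiliary test sequences
# ---------------------------------------------------------------------------

def translating_sequence(
    n_phases: int = 25,
    shift_per_phase: tuple[int, int] = (1, 1),
    size_px: int = 96,
    seed: int = 0,
) -> CineView:
    """Noiseless rigid integer-translation sequence (periodic wrap).

    A smooth random texture is rolled by an exact integer shift per phase —
    the simplest sequence on which chained NCC tracking must be pixel-exact.
    """
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.normal(size=(size_px, size_px)), 2.0)
    base = (base - base.min()) / (base.max() - base.min())
    frames = np.stack([
        np.roll(base, (n * shift_per_phase[0], n * shift_per_phase[1]),
                axis=(0, 1))
        for n in range(n_phases)
    ])
    return CineView(
        view_label="four_chamber",
        frames=frames,
        origin=np.zeros(3),
        row_dir=np.array([1.0, 0.0, 0.0]),
        col_dir=np.array([0.0, 1.0, 0.0]),
        spacing=(1.0, 1.0),
        rr_interval_ms=1000.0,
    )
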