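"""3D mitral annulus reconstruction and sweep-volume accumulation.

Per cardiac phase, the six tracked junction points (two per long-axis view)
are ordered circumferentially, interpolated with a closed periodic cubic
spline, and reduced to an annular area, centroid and best-fit plane normal.
Between consecutive phases the annular disk sweeps an incremental volume
V_n = 0.5 * (A_{n-1} + A_n) * d_n, where d_n is the signed displacement of
the centroid along a fixed apex-directed long axis (positive toward the
apex); the cumulative sum starting from end-diastole (phase 0) is the net
sweep volume curve, whose maximum is the end-systolic sweep volume (ESSV)
used to normalize the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger("masweep")

#: default number of samples on the interpolated annulus curve
N_CURVE_SAMPLES = 120
_COINCIDENT_TOL = 1e-6
_PLANE_CONDITION_MAX = 1e6

#: canonical starting label for circumferential ordering
_START_LABEL = ("four_chamber", "septal")


@dataclass
class AnnulusFrame:
    """Reconstructed annulus at one cardiac phase."""

    phase: int
    points6: np.ndarray        # (6, 3) mm, circumferential order
    curve: np.ndarray          # (N, 3) closed spline samples (first == last)
    area_mm2: float
    centroid: np.ndarray       # (3,)
    plane_normal: np.ndarray   # (3,) unit


@dataclass
class SweepCurve:
    """Incremental and cumulative annular sweep volumes over the cycle."""

    increments_mm3: np.ndarray      # (P-1,) V_n for n = 1..P-1, signed
    cumulative_mm3: np.ndarray      # (P,) net sweep volume, cumulative[0] = 0
    essv_mm3: float                 # end-systolic sweep volume (max cumulative)
    normalized: np.ndarray          # cumulative / ESSV, peaks at exactly 1
    times_ms: np.ndarray            # (P,) phase times 0, RR/P, ...
    rr_interval_ms: float
    long_axis: np.ndarray = field(default_factory=lambda: np.zeros(3))
    closure_residual_mm3: float = 0.0   # wrap increment P-1 -> 0, not summed

    @property
    def n_phases(self) -> int:
        return len(self.cumulative_mm3)

    @property
    def es_index(self) -> int:
        """Phase of end-systole: argmax of the cumulative curve.

        Pixel-resolution tracking can flatten the systolic peak into a tied
        plateau; the middle of the maximal plateau is then the least-biased
        end-systole estimate (any tied index leaves normalized == 1 there).
        """
        c = self.cumulative_mm3
        tied = np.flatnonzero(c >= c.max() - 1e-12 * max(abs(c.max()), 1.0))
        run = [tied[0]]
        for i in tied[1:]:
            if i == run[-1] + 1:
                run.append(i)
            else:
                break
        return int(run[len(run) // 2])


# ---------------------------------------------------------------------------
# plane fitting and point ordering
# ---------------------------------------------------------------------------

def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through 3D points: (centroid, unit normal).

    The normal's sign is fixed deterministically (largest-magnitude
    component positive); callers needing anatomical orientation flip it.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < s[0] / _PLANE_CONDITION_MAX:
        raise ValueError("near-collinear points: plane fit is degenerate")
    normal = vt[2]
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    return centroid, normal


def order_annulus_points(
    labelled_points: dict[tuple[str, str], np.ndarray],
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Order six labelled junction points circumferentially.

    Points are sorted by angle about the centroid in the best-fit plane,
    counter-clockwise about the plane normal, starting from the septal point
    of the four-chamber view. Returns the (6, 3) ordered array and the label
    order.
    """
    labels = list(labelled_points)
    pts = np.asarray([labelled_points[k] for k in labels], dtype=float)
    if len(pts) != 6:
        raise ValueError(f"expected six labelled points, got {len(pts)}")
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    if np.any(d[np.triu_indices(6, 1)] <= _COINCIDENT_TOL):
        raise ValueError("coincident annulus points")

    centroid, normal = fit_plane(pts)
    # in-plane orthonormal basis (u, v) with u x v = normal
    u = np.eye(3)[int(np.argmin(np.abs(normal)))]
    u = u - (u @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rel = pts - centroid
    angles = np.arctan2(rel @ v, rel @ u)

    if _START_LABEL not in labels:
        raise ValueError(f"missing start point {_START_LABEL}")
    start = labels.index(_START_LABEL)
    shifted = np.mod(angles - angles[start], 2 * np.pi)
    order = np.argsort(shifted, kind="stable")
    return pts[order], [labels[i] for i in order]


# ---------------------------------------------------------------------------
# spline interpolation, area, centroid
# ---------------------------------------------------------------------------

def interpolate_annulus(
    ordered_points: np.ndarray, n_samples: int = N_CURVE_SAMPLES
) -> np.ndarray:
    """Closed periodic cubic spline through an ordered ring of 3D points.

    Chord-length parameterized and resampled at ``n_samples`` uniform
    parameter values spanning one full period, so the first and last samples
    coincide. The spline passes through every input point exactly.
    """
    pts = np.asarray(ordered_points, dtype=float)
    if len(pts) < 4:
        raise ValueError("need at least four points for a closed cubic spline")
    closed = np.vstack([pts, pts[0]])
    chords = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(chords <= _COINCIDENT_TOL):
        raise ValueError("coincident consecutive points")
    t = np.concatenate([[0.0], np.cumsum(chords)])
    spline = CubicSpline(t, closed, axis=0, bc_type="periodic")
    u = np.linspace(0.0, t[-1], n_samples)
    return spline(u)


def annulus_area_centroid(
    curve: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and plane normal of a closed sampled 3D curve.

    The centroid is the mean of the (unique) samples. The area is a triangle
    fan about the centroid with each triangle's vector area projected onto
    the best-fit plane normal — signed contributions summed, absolute total
    returned — which reduces to the shoelace area for planar curves and
    converges for gently saddle-shaped annuli.
    """
    pts = np.asarray(curve, dtype=float)
    if np.linalg.norm(pts[0] - pts[-1]) <= 1e-9:
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("need at least three distinct curve samples")
    centroid, normal = fit_plane(pts)
    rel = pts - centroid
    cross = np.cross(rel, np.roll(rel, -1, axis=0))
    signed = 0.5 * cross @ normal
    area = abs(float(signed.sum()))
    if area <= _COINCIDENT_TOL:
        raise ValueError("degenerate zero-area annulus curve")
    return area, centroid, normal


def make_annulus_frame(
    phase: int,
    labelled_points: dict[tuple[str, str], np.ndarray],
    n_samples: int = N_CURVE_SAMPLES,
) -> AnnulusFrame:
    """Order, interpolate and measure the annulus at one phase."""
    ordered, _ = order_annulus_points(labelled_points)
    curve = interpolate_annulus(ordered, n_samples)
    area, centroid, normal = annulus_area_centroid(curve)
    return AnnulusFrame(
        phase=phase, points6=ordered, curve=curve,
        area_mm2=area, centroid=centroid, plane_normal=normal,
    )


def orient_normals(frames: list[AnnulusFrame], long_axis: np.ndarray) -> None:
    """Flip plane normals in place for orientation continuity along the axis."""
    for f in frames:
        if f.plane_normal @ long_axis < 0:
            f.plane_normal = -f.plane_normal


# ---------------------------------------------------------------------------
# sweep volume accumulation
# ---------------------------------------------------------------------------

def estimate_long_axis(frames: list[AnnulusFrame]) -> np.ndarray:
    """Fixed long-axis direction: the end-diastolic plane normal, oriented
    toward the side the centroid moves during systole (the apex)."""
    n0 = frames[0].plane_normal
    disp = np.asarray([(f.centroid - frames[0].centroid) @ n0 for f in frames])
    k = int(np.argmax(np.abs(disp)))
    if disp[k] == 0:
        return n0
    return n0 * np.sign(disp[k])


def sweep_volume(
    frames: list[AnnulusFrame],
    rr_interval_ms: float,
    long_axis: np.ndarray | None = None,
) -> SweepCurve:
    """Accumulate signed incremental sweep volumes from end-diastole.

    d_n is the centroid displacement projected on the fixed apex-directed
    long axis; V_n = 0.5 (A_{n-1} + A_n) d_n (trapezoid of areas, the
    frustum approximation). The wrap increment closing the last phase back
    to phase 0 is reported as a closure residual but not added to the curve;
    a large residual indicates tracking drift.
    """
    if len(frames) < 3:
        raise ValueError("need at least three phases")
    axis = estimate_long_axis(frames) if long_axis is None else (
        np.asarray(long_axis, float) / np.linalg.norm(long_axis))
    orient_normals(frames, axis)

    areas = np.asarray([f.area_mm2 for f in frames])
    cents = np.asarray([f.centroid for f in frames])
    d = np.diff(cents, axis=0) @ axis                     # (P-1,) signed mm
    increments = 0.5 * (areas[:-1] + areas[1:]) * d
    cumulative = np.concatenate([[0.0], np.cumsum(increments)])
    essv = float(cumulative.max())
    if essv <= 0:
        raise ValueError("no systolic excursion: annulus never descends")
    closure = 0.5 * (areas[-1] + areas[0]) * float((cents[0] - cents[-1]) @ axis)
    logger.info("sweep closure residual: %.2f mm3 (%.2f%% of ESSV)",
                closure, 100 * closure / essv)
    p = len(frames)
    times = np.arange(p) * (rr_interval_ms / p)
    return SweepCurve(
        increments_mm3=increments,
        cumulative_mm3=cumulative,
        essv_mm3=essv,
        normalized=cumulative / essv,
        times_ms=times,
        rr_interval_ms=rr_interval_ms,
        long_axis=axis,
        closure_residual_mm3=closure,
    )
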