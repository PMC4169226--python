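"""Atrioventricular-junction tracking by normalized cross-correlation.

A square template centered on the junction point in phase *n* is slid over
every placement inside a larger search window in phase *n+1*; each placement
gets the zero-mean normalized (Pearson) correlation coefficient between the
template and the underlying patch. The argmax of this correlation map is the
junction location in phase *n+1*, which then seeds the next step, chaining
through the whole cardiac cycle. A correction at any phase replaces the
position there and re-tracks all subsequent phases from it, mirroring the
interactive correct-and-retrack workflow.

Windows follow the published "20-pixel template / 40-pixel search" sizes,
realized as odd 21/41 squares so the tracked point is a true center pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .cine_io import CineView

logger = logging.getLogger("masweep")

_VAR_EPS = 1e-12


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


@dataclass(frozen=True)
class TrackConfig:
    """Tracking window sizes and quality-control threshold.

    template_px / roi_px are nominal square sides in pixels; they are
    realized as the next odd size so windows center on the tracked pixel.
    Phases whose peak correlation falls below ``min_corr`` are flagged for
    review (the scriptable stand-in for interactive visual QC). Subpixel
    refinement (3-point parabolic) is off by default: tracking is performed
    at pixel resolution.
    """

    template_px: int = 20
    roi_px: int = 40
    min_corr: float = 0.5
    subpixel: bool = False

    def __post_init__(self) -> None:
        if self.template_side < 5:
            raise ValueError("template must be at least 5 px")
        if self.roi_side <= self.template_side:
            raise ValueError("search window must exceed the template")
        if not -1.0 <= self.min_corr <= 1.0:
            raise ValueError("min_corr must lie in [-1, 1]")

    @property
    def template_side(self) -> int:
        return _odd(self.template_px)

    @property
    def roi_side(self) -> int:
        return _odd(self.roi_px)


@dataclass
class TrackResult:
    """Per-phase pixel trajectory of one junction point in one view."""

    view_label: str
    point_label: str              # "septal" or "lateral"
    pixels: np.ndarray            # (P, 2) (row, col); ints unless subpixel
    corr: np.ndarray              # (P,) peak correlation per phase (phase 0 = 1)
    corrected_phases: set[int] = field(default_factory=set)
    low_corr_phases: set[int] = field(default_factory=set)

    @property
    def n_phases(self) -> int:
        return len(self.pixels)


def ncc_match(
    template: np.ndarray, search_region: np.ndarray
) -> tuple[tuple[int, int], float, np.ndarray]:
    """Correlate a template against every placement inside a search region.

    Returns ``(displacement, peak_corr, corr_map)`` where ``corr_map[i, j]``
    is the Pearson correlation of the template with the patch whose top-left
    corner is at (i, j) — only fully contained placements are scored — and
    ``displacement`` is the argmax expressed relative to the centered
    placement. Ties break to the first occurrence in row-major order.

    A constant template has no defined correlation and raises; a constant
    *placement* is assigned ``-inf`` so it can never win the argmax.
    """
    t = np.asarray(template, dtype=float)
    s = np.asarray(search_region, dtype=float)
    if t.ndim != 2 or s.ndim != 2:
        raise ValueError("template and search region must be 2D")
    if t.shape[0] >= s.shape[0] or t.shape[1] >= s.shape[1]:
        raise ValueError("template must be strictly smaller than search region")

    tz = t - t.mean()
    t_ss = float(np.sum(tz * tz))
    if t_ss < _VAR_EPS:
        raise ValueError("untrackable feature: template has zero intensity variance")

    windows = sliding_window_view(s, t.shape)           # (H', W', th, tw)
    n = t.size
    w_sum = windows.sum(axis=(2, 3))
    w_ss = np.einsum("ijkl,ijkl->ij", windows, windows) - w_sum**2 / n
    num = np.einsum("ijkl,kl->ij", windows, tz)          # tz is zero-mean
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_map = num / np.sqrt(w_ss * t_ss)
    corr_map = np.where(w_ss < _VAR_EPS, -np.inf, np.clip(corr_map, -1.0, 1.0))

    flat = int(np.argmax(corr_map))                      # first max, row-major
    idx = np.unravel_index(flat, corr_map.shape)
    center = ((s.shape[0] - t.shape[0]) // 2, (s.shape[1] - t.shape[1]) // 2)
    displacement = (int(idx[0] - center[0]), int(idx[1] - center[1]))
    return displacement, float(corr_map[idx]), corr_map


def _clamp_seed(pos: tuple[float, float], shape: tuple[int, int], half: int
                ) -> tuple[int, int]:
    h, w = shape
    if h < 2 * half + 1 or w < 2 * half + 1:
        raise ValueError("image too small for any template support")
    r = int(round(pos[0]))
    c = int(round(pos[1]))
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"seed pixel {pos} outside {h}x{w} image")
    rc = min(max(r, half), h - 1 - half)
    cc = min(max(c, half), w - 1 - half)
    if (rc, cc) != (r, c):
        logger.info("seed clamped from (%d, %d) to (%d, %d) for template support",
                    r, c, rc, cc)
    return rc, cc


def _match_step(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    pos: tuple[int, int],
    config: TrackConfig,
) -> tuple[tuple[float, float], float]:
    """One chained NCC step: locate the phase-n template in phase n+1.

    The search window is clipped at image borders; placements lacking full
    template support are implicitly excluded because the correlation map is
    computed only over fully contained placements of the clipped window.
    """
    th = config.template_side // 2
    rh = config.roi_side // 2
    h, w = frame_a.shape
    r, c = int(round(pos[0])), int(round(pos[1]))
    template = frame_a[r - th:r + th + 1, c - th:c + th + 1]
    r0, r1 = max(r - rh, 0), min(r + rh + 1, h)
    c0, c1 = max(c - rh, 0), min(c + rh + 1, w)
    roi = frame_b[r0:r1, c0:c1]
    _, peak, corr_map = ncc_match(template, roi)
    i, j = np.unravel_index(int(np.argmax(corr_map)), corr_map.shape)
    if config.subpixel:
        di = _parabolic_offset(corr_map[:, j], i)
        dj = _parabolic_offset(corr_map[i, :], j)
        return (r0 + i + di + th, c0 + j + dj + th), peak
    return (float(r0 + i + th), float(c0 + j + th)), peak


def _parabolic_offset(line: np.ndarray, k: int) -> float:
    """Vertex offset in (-0.5, 0.5) of a parabola through three samples."""
    if k == 0 or k == len(line) - 1:
        return 0.0
    a, b, c = line[k - 1], line[k], line[k + 1]
    if not np.all(np.isfinite([a, b, c])):
        return 0.0
    denom = a - 2 * b + c
    if abs(denom) < _VAR_EPS:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def track_point(
    view: CineView,
    seed_pixel: tuple[float, float],
    config: TrackConfig = TrackConfig(),
    point_label: str = "septal",
) -> TrackResult:
    """Track one junction point through all phases by chained NCC.

    The phase-0 position is the (clamped) seed; each subsequent position is
    the correlation argmax of the previous phase's template inside the next
    phase's search window. The trajectory stops at the last phase (no wrap).
    """
    return _track_from(view, seed_pixel, 0, config, point_label,
                       corrected=set())


def correct_and_retrack(
    result: TrackResult,
    view: CineView,
    phase: int,
    new_pixel: tuple[float, float],
    config: TrackConfig = TrackConfig(),
) -> TrackResult:
    """Override the position at one phase and re-track all later phases."""
    p = view.n_phases
    if not 0 <= phase < p:
        raise ValueError(f"phase {phase} outside [0, {p})")
    h, w = view.shape
    if not (0 <= new_pixel[0] < h and 0 <= new_pixel[1] < w):
        raise ValueError(f"corrected pixel {new_pixel} out of bounds")
    tail = _track_from(view, new_pixel, phase, config, result.point_label,
                       corrected=set(result.corrected_phases) | {phase})
    pixels = np.concatenate([result.pixels[:phase], tail.pixels])
    corr = np.concatenate([result.corr[:phase], tail.corr])
    low = {n for n in result.low_corr_phases if n < phase} | tail.low_corr_phases
    return replace(result, pixels=pixels, corr=corr,
                   corrected_phases=tail.corrected_phases, low_corr_phases=low)


def _track_from(
    view: CineView,
    start_pixel: tuple[float, float],
    start_phase: int,
    config: TrackConfig,
    point_label: str,
    corrected: set[int],
) -> TrackResult:
    half = config.template_side // 2
    pos = _clamp_seed(start_pixel, view.shape, half)
    p = view.n_phases
    positions: list[tuple[float, float]] = [(float(pos[0]), float(pos[1]))]
    corrs = [1.0]
    low: set[int] = set()
    for n in range(start_phase, p - 1):
        new_pos, peak = _match_step(
            view.frames[n], view.frames[n + 1], positions[-1], config
        )
        positions.append(new_pos)
        corrs.append(peak)
        if peak < config.min_corr:
            low.add(n + 1)
            logger.warning(
                "%s/%s phase %d: peak correlation %.3f below %.2f — flagged",
                view.view_label, point_label, n + 1, peak, config.min_corr,
            )
    pixels = np.asarray(positions)
    if not config.subpixel:
        pixels = np.rint(pixels).astype(int)
    return TrackResult(
        view_label=view.view_label,
        point_label=point_label,
        pixels=pixels,
        corr=np.asarray(corrs),
        corrected_phases=corrected,
        low_corr_phases=low,
    )
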