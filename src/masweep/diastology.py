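"""Diastolic-function parameters from the normalized sweep-volume curve.

The net sweep volume curve, normalized to the end-systolic sweep volume
(ESSV), is differentiated to obtain the sweep *rate*; the descending
(diastolic) limb of the curve is segmented into early diastole (ED),
mid-diastole (MD, the diastasis plateau) and atrial systole (AS) from the
rate's peak/valley structure, and the following indices are computed:

* PSR_E, PSR_A — normalized peak sweep rates in ED and AS (s^-1), the CMR
  analogue of the tissue-Doppler e' and a' annular velocities, and their
  ratio PSR_E/PSR_A;
* average normalized sweep rates over ED, MD and AS;
* percentage sweep-volume recovery in ED and AS (fraction of ESSV recovered
  between the interval endpoints) and the corresponding absolute volumes;
* AT_SV — acceleration time from ED onset to the PSR_E peak;
* DT_SV — deceleration time, by linear extrapolation of the rate's descent
  from the PSR_E peak to baseline (zero rate);
* DSVRT_50 — time for the annulus to recover 50% of ESSV after end-systole,
  expressed as a percentage of the RR interval.

Recovery rates are reported positive (the signed derivative is negative
while the annulus returns toward the base); the signed derivative is
retained alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks

from .annulus import SweepCurve

logger = logging.getLogger("masweep")

#: peak prominence threshold for E/A detection, fraction of the max rate
PEAK_PROMINENCE_FRAC = 0.10
#: band above the inter-peak minimum within which a sample counts as
#: "at the minimum" when locating interval boundaries on flat plateaus
_MIN_BAND_FRAC = 0.05
#: diastolic recovery fraction defining DSVRT (0.5 per the published index;
#: configurable for research use)
DSVRT_THRESHOLD = 0.5


class SweepRate(NamedTuple):
    """Recovery rate r(t) = -d(normalized)/dt and the signed derivative."""

    rate: np.ndarray          # (P,) s^-1, positive during diastolic recovery
    derivative: np.ndarray    # (P,) signed d(normalized)/dt, s^-1
    times_ms: np.ndarray


@dataclass
class IntervalSegmentation:
    """Cardiac-cycle interval boundaries on the sweep curve (ms)."""

    es_index: int
    ed_onset_ms: float
    ed_end_ms: float
    md_end_ms: float
    as_onset_ms: float
    cycle_end_ms: float
    source: str = "automatic"          # "automatic" | "manual"
    e_peak_time_ms: float = math.nan
    a_peak_time_ms: float = math.nan

    def __post_init__(self) -> None:
        if not (0 < self.ed_onset_ms < self.ed_end_ms <= self.md_end_ms
                <= self.as_onset_ms < self.cycle_end_ms):
            raise ValueError(
                "interval boundaries must satisfy "
                "0 < ED onset < ED end <= MD end <= AS onset < cycle end"
            )


@dataclass
class DiastolicParameters:
    """All sweep-volume diastolic indices for one subject."""

    psr_e: float                  # normalized peak sweep rate, ED (s^-1)
    psr_a: float                  # normalized peak sweep rate, AS (s^-1)
    psr_ratio: float              # PSR_E / PSR_A
    psr_e_abs_cm3s: float
    psr_a_abs_cm3s: float
    avg_rate_ed: float
    avg_rate_md: float
    avg_rate_as: float
    pct_recovery_ed: float        # % of ESSV recovered during ED
    pct_recovery_as: float
    abs_sweep_ed_cm3: float
    abs_sweep_as_cm3: float
    at_sv_ms: float
    dt_sv_ms: float
    dsvrt50_pct_rr: float
    essv_cm3: float
    sweep_over_sv_ed_pct: float | None = None
    sweep_over_sv_as_pct: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["qc_flags"] = list(self.qc_flags)
        return d


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def sweep_rate(curve: SweepCurve) -> SweepRate:
    """Differentiate the normalized sweep curve on the periodic phase grid.

    Central differences with periodic wrap-around; grid spacing RR/P. Rates
    are in s^-1 of normalized volume.
    """
    y = curve.normalized
    p = len(y)
    if p < 5:
        raise ValueError("need at least five phases to differentiate")
    dt_s = (curve.rr_interval_ms / p) / 1000.0
    deriv = (np.roll(y, -1) - np.roll(y, 1)) / (2.0 * dt_s)
    return SweepRate(rate=-deriv, derivative=deriv, times_ms=curve.times_ms)


# ---------------------------------------------------------------------------
# interval segmentation
# ---------------------------------------------------------------------------

def _first_in_band(r: np.ndarray, lo: int, hi: int, band: float) -> int:
    for i in range(lo, hi + 1):
        if r[i] <= band:
            return i
    return hi


def _last_in_band(r: np.ndarray, lo: int, hi: int, band: float) -> int:
    for i in range(hi, lo - 1, -1):
        if r[i] <= band:
            return i
    return lo


def segment_intervals(
    curve: SweepCurve,
    rate: SweepRate,
    override: dict[str, float] | None = None,
) -> IntervalSegmentation:
    """Divide the cycle into systole / ED / MD / AS from the rate's shape.

    End-systole is the argmax of the cumulative curve; within diastole the
    recovery rate's local maxima with prominence >= 10% of the peak rate
    give the E wave (first) and A wave (last). ED ends at the rate minimum
    after the E peak and AS starts at the minimum immediately before the A
    peak; on flat diastasis plateaus, where that minimum is non-unique, the
    boundary is placed at the plateau edge (first/last sample within a small
    band above the inter-peak minimum). Mid-diastole spans between the two
    boundaries and may be empty. A manual ``override`` dict replaces any
    subset of boundaries, replaying the interactive slope-transition
    segmentation.
    """
    r = rate.rate
    t = curve.times_ms
    p = len(r)
    es = curve.es_index
    if es == 0 or es >= p - 2:
        raise ValueError("end-systole not strictly inside the cycle")

    seg_r = r[es:]                       # diastolic limb, ES .. last phase
    prom = PEAK_PROMINENCE_FRAC * float(r.max())
    peaks, _ = find_peaks(seg_r, prominence=prom)
    # a peak sitting exactly at the last sample has no right neighbor for
    # find_peaks; append the periodic continuation (rate at phase 0) to test it
    peaks_ext, _ = find_peaks(np.append(seg_r, r[0]), prominence=prom)
    peaks = sorted(set(peaks) | {q for q in peaks_ext if q < len(seg_r)})
    if len(peaks) < 2:
        raise ValueError("E/A fusion — manual segmentation required "
                         f"({len(peaks)} qualifying diastolic rate peak(s))")
    e_peak = es + peaks[0]
    a_peak = es + peaks[-1]

    m = float(r[e_peak + 1:a_peak].min())
    height = min(float(r[e_peak]), float(r[a_peak])) - m
    band = m + _MIN_BAND_FRAC * max(height, 0.0)
    ed_end = _first_in_band(r, e_peak + 1, a_peak - 1, band)
    as_onset = _last_in_band(r, e_peak + 1, a_peak - 1, band)

    seg = IntervalSegmentation(
        es_index=es,
        ed_onset_ms=float(t[es]),
        ed_end_ms=float(t[ed_end]),
        md_end_ms=float(t[as_onset]),
        as_onset_ms=float(t[as_onset]),
        cycle_end_ms=float(curve.rr_interval_ms),
        e_peak_time_ms=float(t[e_peak]),
        a_peak_time_ms=float(t[a_peak]),
    )
    if override:
        fields = {k: float(v) for k, v in override.items()}
        unknown = set(fields) - {
            "ed_onset_ms", "ed_end_ms", "md_end_ms", "as_onset_ms",
            "cycle_end_ms",
        }
        if unknown:
            raise ValueError(f"unknown segmentation override(s): {sorted(unknown)}")
        for k, v in fields.items():
            setattr(seg, k, v)
        # MD end is definitionally the AS onset unless pinned separately
        if "md_end_ms" not in fields:
            seg.md_end_ms = seg.as_onset_ms
        seg.source = "manual"
        seg.__post_init__()              # re-validate ordering
        seg.es_index = int(np.argmin(np.abs(t - seg.ed_onset_ms)))
    return seg


# ---------------------------------------------------------------------------
# parameter computation
# ---------------------------------------------------------------------------

def _interval_mask(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (t >= lo - 1e-9) & (t <= hi + 1e-9)


def _deceleration_time_ms(
    r: np.ndarray, t: np.ndarray, peak_idx: int, floor_idx: int,
    flags: list[str],
) -> float:
    """DT_SV: extrapolate the E-wave descent linearly to zero rate.

    A least-squares line is fitted to the monotone descending samples from
    the E peak toward the next rate minimum (coarse 25-phase sampling makes
    a two-point tangent unstable); DT is the time from the peak to the
    line's zero crossing.
    """
    end = peak_idx + 1
    while end <= floor_idx and r[end] < r[end - 1]:
        end += 1
    idx = np.arange(peak_idx, end)
    if len(idx) < 2:
        flags.append("dt_sv_undefined")
        return math.nan
    slope, intercept = np.polyfit(t[idx], r[idx], 1)
    if slope >= 0:
        flags.append("dt_sv_nondescending")
        return math.nan
    t_zero = -intercept / slope
    return float(t_zero - t[peak_idx])


def compute_parameters(
    curve: SweepCurve,
    rate: SweepRate,
    seg: IntervalSegmentation,
    stroke_volume_ml: float | None = None,
    dsvrt_threshold: float = DSVRT_THRESHOLD,
) -> DiastolicParameters:
    """Compute every sweep-volume diastolic index from a segmented curve."""
    r, t, y = rate.rate, curve.times_ms, curve.normalized
    flags: list[str] = []

    ed = _interval_mask(t, seg.ed_onset_ms, seg.ed_end_ms)
    md = _interval_mask(t, seg.ed_end_ms, seg.as_onset_ms)
    as_ = _interval_mask(t, seg.as_onset_ms, seg.cycle_end_ms)

    ed_idx = np.flatnonzero(ed)
    as_idx = np.flatnonzero(as_)
    if len(ed_idx) == 0 or len(as_idx) == 0:
        raise ValueError("empty ED or AS interval")

    psr_e_i = ed_idx[int(np.argmax(r[ed_idx]))]
    psr_a_i = as_idx[int(np.argmax(r[as_idx]))]
    psr_e = float(r[psr_e_i])
    psr_a = float(r[psr_a_i])
    if psr_e <= 0 or psr_a <= 0:
        flags.append("nonpositive_peak_rate")

    rr = curve.rr_interval_ms

    def norm_at(time_ms: float) -> float:
        # periodic extension: the curve closes to its phase-0 value at t = RR
        if time_ms > t[-1]:
            frac = (time_ms - t[-1]) / (rr - t[-1])
            return float(y[-1] + frac * (y[0] - y[-1]))
        return float(np.interp(time_ms, t, y))

    pct_ed = 100.0 * (norm_at(seg.ed_onset_ms) - norm_at(seg.ed_end_ms))
    pct_as = 100.0 * (norm_at(seg.as_onset_ms) - norm_at(seg.cycle_end_ms))
    essv_cm3 = curve.essv_mm3 / 1000.0

    # DT_SV fit window: E peak -> boundary sample of the following minimum
    ed_end_i = int(np.argmin(np.abs(t - seg.ed_end_ms)))
    dt_sv = _deceleration_time_ms(r, t, psr_e_i, max(ed_end_i, psr_e_i + 1), flags)
    at_sv = float(t[psr_e_i] - seg.ed_onset_ms)

    dsvrt = _dsvrt_pct_rr(curve, seg, dsvrt_threshold, flags)

    md_idx = np.flatnonzero(md)
    avg_md = float(np.mean(r[md_idx])) if len(md_idx) else 0.0
    if not len(md_idx):
        flags.append("empty_mid_diastole")

    params = DiastolicParameters(
        psr_e=psr_e,
        psr_a=psr_a,
        psr_ratio=psr_e / psr_a if psr_a != 0 else math.nan,
        psr_e_abs_cm3s=psr_e * essv_cm3,
        psr_a_abs_cm3s=psr_a * essv_cm3,
        avg_rate_ed=float(np.mean(r[ed_idx])),
        avg_rate_md=avg_md,
        avg_rate_as=float(np.mean(r[as_idx])),
        pct_recovery_ed=pct_ed,
        pct_recovery_as=pct_as,
        abs_sweep_ed_cm3=pct_ed / 100.0 * essv_cm3,
        abs_sweep_as_cm3=pct_as / 100.0 * essv_cm3,
        at_sv_ms=at_sv,
        dt_sv_ms=dt_sv,
        dsvrt50_pct_rr=dsvrt,
        essv_cm3=essv_cm3,
        qc_flags=flags,
    )
    if stroke_volume_ml is not None:
        params.sweep_over_sv_ed_pct = 100.0 * params.abs_sweep_ed_cm3 / stroke_volume_ml
        params.sweep_over_sv_as_pct = 100.0 * params.abs_sweep_as_cm3 / stroke_volume_ml
    return params


def _dsvrt_pct_rr(
    curve: SweepCurve,
    seg: IntervalSegmentation,
    threshold: float,
    flags: list[str],
) -> float:
    """Time after ED onset at which the normalized curve first crosses the
    recovery threshold, linearly interpolated, as % of RR."""
    y, t = curve.normalized, curve.times_ms
    es = seg.es_index
    level = threshold
    for i in range(es, len(y) - 1):
        if y[i] >= level > y[i + 1]:
            frac = (y[i] - level) / (y[i] - y[i + 1])
            t_cross = t[i] + frac * (t[i + 1] - t[i])
            return 100.0 * (t_cross - seg.ed_onset_ms) / curve.rr_interval_ms
    # no crossing within the sampled diastolic phases: the wrap back to the
    # phase-0 value is an artifact of periodic reconstruction, not recovery
    flags.append("incomplete_recovery_dsvrt_undefined")
    logger.warning("normalized curve never crosses %.2f in diastole — "
                   "DSVRT undefined", level)
    return math.nan
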