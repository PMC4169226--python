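"""End-to-end orchestration: track -> reconstruct -> sweep -> parameters."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annulus, diastology, tracking
from .cine_io import StudyGeometry, pixel_to_patient
from .tracking import TrackConfig, TrackResult

logger = logging.getLogger("masweep")

POINT_LABELS = ("septal", "lateral")

#: seed / corrections structure: {view_label: {point_label: (row, col)}}
Seeds = dict[str, dict[str, tuple[float, float]]]


@dataclass
class StudyResult:
    """Everything computed for one subject."""

    tracks: dict[tuple[str, str], TrackResult]
    frames: list[annulus.AnnulusFrame]
    curve: annulus.SweepCurve
    rate: diastology.SweepRate
    segmentation: diastology.IntervalSegmentation
    parameters: diastology.DiastolicParameters


def track_study(
    study: StudyGeometry,
    seeds: Seeds,
    config: TrackConfig = TrackConfig(),
    corrections: list[dict] | None = None,
) -> dict[tuple[str, str], TrackResult]:
    """Track both junction points in all three views, applying corrections.

    Corrections are dicts {view, point, phase, row, col}, replayed in phase
    order through correct-and-retrack (the scriptable form of the
    interactive workflow).
    """
    tracks: dict[tuple[str, str], TrackResult] = {}
    for view_label, view in study.views.items():
        for point_label in POINT_LABELS:
            seed = seeds[view_label][point_label]
            tracks[(view_label, point_label)] = tracking.track_point(
                view, seed, config, point_label=point_label
            )
    for corr in sorted(corrections or [], key=lambda c: c["phase"]):
        key = (corr["view"], corr["point"])
        tracks[key] = tracking.correct_and_retrack(
            tracks[key], study.views[corr["view"]], corr["phase"],
            (corr["row"], corr["col"]), config,
        )
    return tracks


def reconstruct(
    study: StudyGeometry,
    tracks: dict[tuple[str, str], TrackResult],
    n_samples: int = annulus.N_CURVE_SAMPLES,
) -> list[annulus.AnnulusFrame]:
    """Fuse tracked pixels into a 3D annulus reconstruction per phase."""
    frames = []
    for n in range(study.n_phases):
        labelled = {
            (view_label, point_label): pixel_to_patient(
                study.views[view_label], tr.pixels[n])
            for (view_label, point_label), tr in tracks.items()
        }
        frames.append(annulus.make_annulus_frame(n, labelled, n_samples))
    return frames


def analyze_study(
    study: StudyGeometry,
    seeds: Seeds,
    config: TrackConfig = TrackConfig(),
    corrections: list[dict] | None = None,
    segmentation_override: dict[str, float] | None = None,
    stroke_volume_ml: float | None = None,
) -> StudyResult:
    """Full pipeline on one study."""
    tracks = track_study(study, seeds, config, corrections)
    frames = reconstruct(study, tracks)
    curve = annulus.sweep_volume(frames, study.rr_interval_ms)
    rate = diastology.sweep_rate(curve)
    seg = diastology.segment_intervals(curve, rate, segmentation_override)
    params = diastology.compute_parameters(
        curve, rate, seg, stroke_volume_ml=stroke_volume_ml
    )
    return StudyResult(tracks=tracks, frames=frames, curve=curve, rate=rate,
                       segmentation=seg, parameters=params)


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------

def tracks_table(tracks: dict[tuple[str, str], TrackResult]) -> pd.DataFrame:
    """Long-format per-phase tracking log."""
    rows = []
    for (view, point), tr in sorted(tracks.items()):
        for n in range(tr.n_phases):
            rows.append({
                "view": view, "point": point, "phase": n,
                "row": float(tr.pixels[n][0]), "col": float(tr.pixels[n][1]),
                "peak_corr": float(tr.corr[n]),
                "corrected": n in tr.corrected_phases,
                "low_corr": n in tr.low_corr_phases,
            })
    return pd.DataFrame(rows)


def geometry_table(result: StudyResult) -> pd.DataFrame:
    """Per-phase annular geometry and sweep-volume curve."""
    c = result.curve
    rows = []
    for n, f in enumerate(result.frames):
        rows.append({
            "phase": n,
            "time_ms": float(c.times_ms[n]),
            "area_mm2": f.area_mm2,
            "centroid_x": f.centroid[0],
            "centroid_y": f.centroid[1],
            "centroid_z": f.centroid[2],
            "increment_mm3": float(c.increments_mm3[n - 1]) if n else 0.0,
            "cumulative_mm3": float(c.cumulative_mm3[n]),
            "normalized": float(c.normalized[n]),
            "rate_per_s": float(result.rate.rate[n]),
        })
    return pd.DataFrame(rows)


def export_curve_obj(frames: list[annulus.AnnulusFrame], path) -> None:
    """Write the per-phase annulus curves as OBJ polylines (visualization)."""
    with open(path, "w") as fh:
        offset = 0
        for f in frames:
            pts = f.curve[:-1]
            for p in pts:
                fh.write(f"v {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
            n = len(pts)
            idx = " ".join(str(offset + i + 1) for i in range(n))
            fh.write(f"l {idx} {offset + 1}\n")
            offset += n


def subject_record(result: StudyResult) -> dict:
    """One-row summary of parameters, boundaries and QC flags."""
    seg = result.segmentation
    rec = dict(result.parameters.to_dict())
    rec.update({
        "es_index": seg.es_index,
        "ed_onset_ms": seg.ed_onset_ms,
        "ed_end_ms": seg.ed_end_ms,
        "as_onset_ms": seg.as_onset_ms,
        "cycle_end_ms": seg.cycle_end_ms,
        "segmentation_source": seg.source,
        "essv_mm3": result.curve.essv_mm3,
        "closure_residual_mm3": result.curve.closure_residual_mm3,
        "n_phases": result.curve.n_phases,
        "rr_interval_ms": result.curve.rr_interval_ms,
        "n_corrected_phases": int(sum(len(t.corrected_phases)
                                      for t in result.tracks.values())),
        "n_low_corr_phases": int(sum(len(t.low_corr_phases)
                                     for t in result.tracks.values())),
    })
    rec["qc_flags"] = ";".join(result.parameters.qc_flags)
    return rec


def tracking_error_px(
    tracks: dict[tuple[str, str], TrackResult],
    truth_pixels: dict[str, dict[str, np.ndarray]],
) -> float:
    """RMS pixel distance between tracked and ground-truth trajectories."""
    sq = []
    for (view, point), tr in tracks.items():
        diff = np.asarray(tr.pixels, float) - truth_pixels[view][point]
        sq.append(np.sum(diff**2, axis=1))
    return float(np.sqrt(np.mean(np.concatenate(sq))))
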