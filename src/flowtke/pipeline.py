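"""End-to-end quantification: acquisition + segmentations -> subject metrics.

Order of operations: velocity from phase differences, phase-wrap
correction, background-offset correction (velocity domain), sigma/TKE from
magnitudes (phase corrections do not affect them), volume curves and
cardiac time points from the LV segmentation, regional frame metrics, and
finally the time-point-selected subject summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import SegmentationSet, chamber_volumes
from .hemodynamics import (
    FrameMetrics,
    PhysicalConstants,
    SubjectMetrics,
    detect_timepoints,
    frame_metrics,
    median_filter_frames,
    subject_summary,
)
from .recon import (
    FlowAcquisition,
    compute_velocity,
    correct_background,
    estimate_sigma,
    unwrap_velocity,
)

__all__ = ["quantify", "metrics_to_row", "derive_static_mask", "SUMMARY_FIELDS"]

SUMMARY_FIELDS = (
    "tke_tot",
    "tke_max",
    "vel_avg",
    "vel_max",
    "mean_diam",
    "max_diam",
    "re_avg",
    "re_max",
)


def derive_static_mask(
    speed: np.ndarray, body_mask: np.ndarray, rel_std: float = 0.02
) -> np.ndarray:
    """Static-tissue mask from the data itself.

    Voxels inside the body whose speed varies little over the cycle
    (temporal standard deviation below ``rel_std`` of the body-wide 95th
    percentile speed) are treated as stationary tissue for the
    background-offset fit.
    """
    scale = float(np.percentile(speed[body_mask], 95)) if body_mask.any() else 1.0
    scale = max(scale, 1e-6)
    tstd = speed.std(axis=3)
    return body_mask & (tstd < rel_std * scale)


def quantify(
    acq: FlowAcquisition,
    seg: SegmentationSet,
    static_mask: np.ndarray | None = None,
    body_mask: np.ndarray | None = None,
    constants: PhysicalConstants = PhysicalConstants(),
    poly_order: int = 2,
    unwrap: bool = True,
) -> tuple[SubjectMetrics, dict[str, FrameMetrics]]:
    """Run the full quantification on one subject.

    ``static_mask``/``body_mask`` come from ground truth when available;
    otherwise the body is thresholded from the reference magnitude and
    static tissue derived from temporal velocity stability.  Set
    ``poly_order`` negative to skip background correction.
    """
    if body_mask is None:
        body_mask = acq.s_ref.mean(axis=3) > 0.5 * acq.s_ref.max()
    vf = compute_velocity(acq)
    if unwrap:
        vf = unwrap_velocity(vf, acq.venc, body_mask)
    if poly_order >= 0:
        if static_mask is None:
            static_mask = derive_static_mask(vf.speed, body_mask)
        if static_mask.sum() >= 50:
            vf = correct_background(vf, static_mask, order=poly_order)
    tm = estimate_sigma(acq, rho=constants.rho)
    speed = vf.speed
    tke_filt = median_filter_frames(tm.tke)
    metrics = {
        region: frame_metrics(tm.tke, speed, seg, region, tke_filtered=tke_filt)
        for region in seg.masks
    }
    if "LV" not in seg.masks:
        raise ValueError("LV segmentation is required for time-point detection")
    systole, early = detect_timepoints(chamber_volumes(seg, "LV"))
    summary = subject_summary(metrics, seg, systole, early, constants)
    return summary, metrics


def metrics_to_row(subject_id: str, summary: SubjectMetrics) -> dict:
    """Flatten a subject summary into one table row per region set."""
    row: dict = {
        "subject_id": subject_id,
        "systole_frame": summary.systole_frame,
        "early_diastole_frame": summary.early_diastole_frame,
    }
    for region, rs in summary.regions.items():
        for f in SUMMARY_FIELDS:
            row[f"{region}_{f}"] = getattr(rs, f)
        row[f"{region}_selected_frame"] = rs.selected_frame
    for region in summary.absent:
        for f in SUMMARY_FIELDS:
            row[f"{region}_{f}"] = np.nan
    return row


def metrics_long_table(metrics: dict[str, FrameMetrics]) -> pd.DataFrame:
    """Per-region per-frame metrics in long form (one row per frame)."""
    rows = []
    for region, fm in metrics.items():
        for t in range(fm.n_frames):
            rows.append(
                {
                    "region": region,
                    "frame": t,
                    "tke_tot": fm.tke_tot[t],
                    "tke_max": fm.tke_max[t],
                    "vel_avg": fm.vel_avg[t],
                    "vel_max": fm.vel_max[t],
                    "volume": fm.volume[t],
                }
            )
    return pd.DataFrame(rows)
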