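"""Regional, time-resolved hemodynamic metrics and subject-level summaries.

For every region and cardiac time frame the pipeline reports

* ``TKE_tot`` [mJ] — TKE density integrated over the region volume,
* ``TKE_max`` [J/m^3] — regional maximum of the 3x3x3 median-filtered TKE,
* ``Vel_avg`` [m/s] — mean speed over the region,
* ``Vel_max`` [m/s] — maximum speed over the region,

and summarizes them at physiologically chosen time points: peak early
diastolic filling (E-wave) for the ventricles — sensitive to aortic and
pulmonary regurgitation — and peak ventricular systole for the atria and
ascending aorta — sensitive to aortic stenosis and mitral/tricuspid
regurgitation.  Each summary is averaged over a +/-2.5% window of the
cardiac cycle (one frame either side at 40 frames).  Reynolds numbers
``Re = rho * v * D / mu`` pair each velocity summary with a diameter taken
at the frame of that velocity's peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    SegmentationSet,
    VolumeCurve,
    aorta_centerline,
    aorta_diameter,
    chamber_volumes,
    equivalent_diameter,
)
from .recon import MU_BLOOD, RHO_BLOOD

__all__ = [
    "PhysicalConstants",
    "FrameMetrics",
    "RegionSummary",
    "SubjectMetrics",
    "frame_metrics",
    "median_filter_3",
    "detect_timepoints",
    "window_average",
    "reynolds",
    "subject_summary",
    "VENTRICLES",
    "SYSTOLIC_REGIONS",
]

#: Regions summarized at peak early diastolic filling.
VENTRICLES = ("LV", "RV")
#: Regions summarized at peak ventricular systole.
SYSTOLIC_REGIONS = ("LA", "RA", "AAo")


@dataclass(frozen=True)
class PhysicalConstants:
    """Blood density [kg/m^3] and dynamic viscosity [Pa*s]."""

    rho: float = RHO_BLOOD
    mu: float = MU_BLOOD

    def __post_init__(self) -> None:
        if not 900.0 <= self.rho <= 1200.0:
            raise ValueError("rho outside the plausible range 900-1200 kg/m^3")
        if not 1e-3 <= self.mu <= 1e-2:
            raise ValueError("mu outside the plausible range 1e-3 to 1e-2 Pa*s")


@dataclass
class FrameMetrics:
    """Per-frame hemodynamic metrics for one region."""

    region: str
    tke_tot: np.ndarray  # mJ
    tke_max: np.ndarray  # J/m^3, after 3x3x3 median filtering
    vel_avg: np.ndarray  # m/s
    vel_max: np.ndarray  # m/s
    volume: np.ndarray  # mL

    @property
    def n_frames(self) -> int:
        return len(self.tke_tot)


@dataclass
class RegionSummary:
    """Time-point-selected metrics for one region of one subject."""

    region: str
    selected_frame: int
    tke_tot: float  # mJ, window-averaged at selected_frame
    tke_max: float  # J/m^3
    vel_avg: float  # m/s
    vel_max: float  # m/s
    mean_diam: float  # m, at frame of peak vel_avg
    max_diam: float  # m, at frame of peak vel_max
    re_avg: float  # Reynolds number from (vel_avg, mean_diam)
    re_max: float  # Reynolds number from (vel_max, max_diam)


@dataclass
class SubjectMetrics:
    """Region summaries for one subject; absent regions are recorded."""

    regions: dict[str, RegionSummary]
    absent: tuple[str, ...] = ()
    systole_frame: int = -1
    early_diastole_frame: int = -1


def median_filter_3(vol: np.ndarray) -> np.ndarray:
    """3x3x3 median filter of a 3D scalar field, borders edge-replicated."""
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("median_filter_3 expects a 3D scalar field")
    return ndimage.median_filter(vol, size=3, mode="nearest")


def median_filter_frames(tke: np.ndarray) -> np.ndarray:
    """Apply the 3x3x3 median filter to every frame of a 4D field."""
    tke = np.asarray(tke, float)
    out = np.empty_like(tke)
    for t in range(tke.shape[3]):
        out[..., t] = median_filter_3(tke[..., t])
    return out


def frame_metrics(
    tke: np.ndarray,
    speed: np.ndarray,
    seg: SegmentationSet,
    region: str,
    tke_filtered: np.ndarray | None = None,
) -> FrameMetrics:
    """Regional metrics per frame.

    The median filter for ``tke_max`` is applied on the full grid before
    masking so near-wall voxels keep complete 27-neighborhoods.  Pass a
    precomputed ``tke_filtered`` (from :func:`median_filter_frames`) when
    evaluating several regions on the same field.
    """
    tke = np.asarray(tke, float)
    speed = np.asarray(speed, float)
    if region not in seg.masks:
        raise KeyError(f"region {region!r} absent from segmentation set")
    mask = seg.masks[region]
    if tke.shape != mask.shape or speed.shape != mask.shape:
        raise ValueError("tke/speed fields and masks must share grid and frames")
    nt = mask.shape[3]
    vv = seg.voxel_volume
    tke_tot = np.zeros(nt)
    tke_max = np.zeros(nt)
    vel_avg = np.zeros(nt)
    vel_max = np.zeros(nt)
    volume = np.zeros(nt)
    for t in range(nt):
        m = mask[..., t]
        volume[t] = m.sum() * vv * 1e6
        if not m.any():
            continue
        tke_tot[t] = tke[..., t][m].sum() * vv * 1e3  # J/m^3 * m^3 -> mJ
        filt = (
            tke_filtered[..., t] if tke_filtered is not None else median_filter_3(tke[..., t])
        )
        tke_max[t] = filt[m].max()
        sp = speed[..., t][m]
        vel_avg[t] = sp.mean()
        vel_max[t] = sp.max()
    return FrameMetrics(
        region=region,
        tke_tot=tke_tot,
        tke_max=tke_max,
        vel_avg=vel_avg,
        vel_max=vel_max,
        volume=volume,
    )


def detect_timepoints(lv_curve: VolumeCurve) -> tuple[int, int]:
    """Locate peak ventricular systole and peak early diastolic filling.

    Both are read off the LV volume curve: peak systole is the frame of
    the most negative cyclic central difference dV/dt (peak ejection);
    peak early filling is the frame of the most positive dV/dt within the
    first half of the interval from the volume minimum to the subsequent
    volume maximum, which isolates the E-wave and excludes the atrial
    kick.  Ties break toward the earlier frame.

    Returns ``(systole_frame, early_diastole_frame)``.
    """
    v = np.asarray(lv_curve.volumes, float)
    n = len(v)
    if n < 8:
        raise ValueError("volume curve must have at least 8 frames")
    if np.ptp(v) == 0:
        raise ValueError("degenerate (constant) volume curve")
    dv = (np.roll(v, -1) - np.roll(v, 1)) / 2.0  # cyclic central difference
    systole = int(np.argmin(dv))
    t_min = int(np.argmin(v))
    # cyclic distance to the next volume maximum after the minimum
    t_max = int(np.argmax(v))
    dist = (t_max - t_min) % n
    if dist == 0:
        raise ValueError("volume minimum and maximum coincide")
    half = max(1, dist // 2)
    window = [(t_min + k) % n for k in range(1, half + 1)]
    early = window[int(np.argmax(dv[window]))]
    return systole, early


def window_average(series: np.ndarray, frame: int, half_width: int | None = None) -> float:
    """Cyclic mean over a +/-2.5%-of-cycle window centered at ``frame``.

    At the usual 40-frame resolution the window is one frame either side;
    for other frame counts it is ``round(0.025 * n)`` frames per side,
    minimum 1.
    """
    series = np.asarray(series, float)
    n = len(series)
    if n < 3:
        raise ValueError("series must have at least 3 frames")
    if half_width is None:
        half_width = max(1, round(0.025 * n))
    idx = [(frame + k) % n for k in range(-half_width, half_width + 1)]
    return float(series[idx].mean())


def reynolds(v: float, d: float, constants: PhysicalConstants = PhysicalConstants()) -> float:
    """Reynolds number ``rho * v * D / mu`` (dimensionless)."""
    if v < 0 or d < 0:
        raise ValueError("speed and diameter must be non-negative")
    return constants.rho * v * d / constants.mu


def _region_diameter(
    seg: SegmentationSet, region: str, frame: int, volumes_ml: np.ndarray
) -> float:
    """Diameter [m] of a region at one frame.

    Chambers are modeled as spheres (diameter from the cavity volume); the
    ascending aorta uses the centerline/cross-section method.
    """
    if region == "AAo":
        mask3 = seg.masks[region][..., frame]
        cl = aorta_centerline(mask3, seg.voxel_size)
        return aorta_diameter(mask3, cl, seg.voxel_size)
    return equivalent_diameter(volumes_ml[frame] * 1e-6)


def subject_summary(
    metrics: dict[str, FrameMetrics],
    seg: SegmentationSet,
    systole_frame: int,
    early_diastole_frame: int,
    constants: PhysicalConstants = PhysicalConstants(),
) -> SubjectMetrics:
    """Time-point-selected summaries for every region of one subject.

    Ventricles are window-averaged at peak early diastolic filling, atria
    and aorta at peak ventricular systole.  The mean diameter is evaluated
    at the frame of the global peak of the ``vel_avg`` series and the max
    diameter at the frame of the peak of ``vel_max`` (single frames, not
    window-averaged); Reynolds numbers pair the window-averaged velocity
    summaries with these diameters.
    """
    out: dict[str, RegionSummary] = {}
    absent: list[str] = []
    for region in VENTRICLES + SYSTOLIC_REGIONS:
        fm = metrics.get(region)
        if fm is None or region not in seg.masks:
            absent.append(region)
            continue
        sel = early_diastole_frame if region in VENTRICLES else systole_frame
        vel_avg = window_average(fm.vel_avg, sel)
        vel_max = window_average(fm.vel_max, sel)
        frame_avg_peak = int(np.argmax(fm.vel_avg))
        frame_max_peak = int(np.argmax(fm.vel_max))
        mean_diam = _region_diameter(seg, region, frame_avg_peak, fm.volume)
        max_diam = _region_diameter(seg, region, frame_max_peak, fm.volume)
        out[region] = RegionSummary(
            region=region,
            selected_frame=sel,
            tke_tot=window_average(fm.tke_tot, sel),
            tke_max=window_average(fm.tke_max, sel),
            vel_avg=vel_avg,
            vel_max=vel_max,
            mean_diam=mean_diam,
            max_diam=max_diam,
            re_avg=reynolds(vel_avg, mean_diam, constants),
            re_max=reynolds(vel_max, max_diam, constants),
        )
    return SubjectMetrics(
        regions=out,
        absent=tuple(absent),
        systole_frame=systole_frame,
        early_diastole_frame=early_diastole_frame,
    )
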