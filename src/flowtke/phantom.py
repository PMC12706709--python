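"""Synthetic 4D flow phantom with exact ground truth.

The phantom emulates the structure of a whole-heart 4D flow MRI exam:
five anatomical regions (ascending aorta as a tube; LV, LA, RV, RA as
moving spheres) with prescribed per-frame volume curves, mean-velocity
fields (parabolic tube profile in the aorta, Gaussian-profile inflow jets
in the chambers) and intravoxel velocity standard deviation fields (a
uniform baseline plus a jet-shaped Gaussian elevation).  The intravoxel
velocity distribution is Gaussian per direction — the model under which
the magnitude-attenuation relation for sigma is exact — so a noise-free
phantom round-trips through the reconstruction to floating precision.

Signals follow the 4-point encoding model: reference magnitude ``S = s0``,
encoded magnitudes ``S_i = s0 * exp(-kv^2 sigma_i^2 / 2)`` and phase
differences ``phi_i = wrap(kv * u_i)``.  Optional complex Gaussian noise
makes the magnitudes Rician; an optional low-order polynomial phase
emulates background phase offsets.  Chamber masks are regenerated each
frame as the N voxels nearest the moving center with N set by the
prescribed volume, so segmentation volumes track the prescribed curves to
within one voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import REGIONS, SegmentationSet
from .hemodynamics import FrameMetrics, frame_metrics, median_filter_frames
from .recon import (
    FlowAcquisition,
    compute_tke,
    normalized_coords,
    polynomial_design_matrix,
)

__all__ = [
    "PhantomSpec",
    "RegionGeometry",
    "GroundTruth",
    "default_spec",
    "build_phantom",
    "encode_signals",
    "add_noise",
    "add_background_offset",
    "wrap_phase",
]

#: Number of polynomial terms for each supported background phase order.
_POLY_TERMS = {0: 1, 1: 4, 2: 10, 3: 20}


@dataclass
class RegionGeometry:
    """Geometry, motion, flow and turbulence model for one region.

    ``size_curve`` is the per-frame sphere volume [mL] for chambers and
    the (usually constant) tube radius [mm] for the aorta.  ``peak_speed``
    and ``sigma_peak`` are per-frame peak values [m/s] of the jet velocity
    and of the jet-shaped sigma elevation; ``sigma_base`` is a uniform
    sigma floor inside the region.
    """

    name: str
    shape: str  # "sphere" | "tube"
    center_path: np.ndarray  # (nt, 3) mm
    size_curve: np.ndarray  # (nt,)
    peak_speed: np.ndarray  # (nt,) m/s
    jet_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    jet_width: float = 8.0  # mm, Gaussian sigma of the jet profile
    sigma_base: float = 0.02  # m/s
    sigma_peak: np.ndarray | None = None  # (nt,) m/s
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # tube only
    length: float = 100.0  # mm, tube only

    def validate(self, n_frames: int, venc_ms: float) -> None:
        if self.name not in REGIONS:
            raise ValueError(f"regions: unknown region name {self.name!r}")
        if self.shape not in ("sphere", "tube"):
            raise ValueError(f"regions[{self.name}].shape must be sphere or tube")
        self.center_path = np.asarray(self.center_path, float)
        self.size_curve = np.asarray(self.size_curve, float)
        self.peak_speed = np.asarray(self.peak_speed, float)
        if self.sigma_peak is None:
            self.sigma_peak = np.zeros(n_frames)
        self.sigma_peak = np.asarray(self.sigma_peak, float)
        if self.center_path.shape != (n_frames, 3):
            raise ValueError(f"regions[{self.name}].center_path must be (n_frames, 3)")
        for attr in ("size_curve", "peak_speed", "sigma_peak"):
            if getattr(self, attr).shape != (n_frames,):
                raise ValueError(f"regions[{self.name}].{attr} must have n_frames entries")
        if np.any(self.size_curve <= 0):
            raise ValueError(f"regions[{self.name}].size_curve must be strictly positive")
        if np.any(self.sigma_peak < 0) or self.sigma_base < 0:
            raise ValueError(f"regions[{self.name}]: sigma values must be >= 0")
        if np.any(np.abs(self.peak_speed) >= 2.0 * venc_ms):
            raise ValueError(
                f"regions[{self.name}].peak_speed must stay below 2*VENC "
                "(at most a single phase wrap)"
            )


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.8  # mm, isotropic
    n_frames: int = 40
    venc: float = 120.0  # cm/s
    rr_interval: float = 1000.0  # ms
    regions: list[RegionGeometry] = field(default_factory=list)
    noise_snr: float = 0.0  # reference-magnitude SNR; 0 disables noise
    background_poly_coeffs: np.ndarray | None = None  # rad, order <= 3
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape: all dimensions must be >= 8")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_frames < 4:
            raise ValueError("n_frames must be >= 4")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.noise_snr < 0:
            raise ValueError("noise_snr must be >= 0")
        if self.background_poly_coeffs is not None:
            coeffs = np.asarray(self.background_poly_coeffs, float)
            if coeffs.ndim != 1 or len(coeffs) not in _POLY_TERMS.values():
                raise ValueError(
                    "background_poly_coeffs must be a flat coefficient vector "
                    f"of length in {sorted(_POLY_TERMS.values())} (order <= 3)"
                )
            self.background_poly_coeffs = coeffs
        for r in self.regions:
            r.validate(self.n_frames, self.venc / 100.0)


@dataclass
class GroundTruth:
    """Noise-free truth underlying one phantom acquisition."""

    true_velocity: np.ndarray  # (nx, ny, nz, nt, 3) m/s
    true_sigma: np.ndarray  # (nx, ny, nz, nt, 3) m/s
    true_tke: np.ndarray  # (nx, ny, nz, nt) J/m^3
    masks: SegmentationSet
    true_region_metrics: dict[str, FrameMetrics]
    body_mask: np.ndarray  # 3D, s0 = 1 inside
    static_mask: np.ndarray  # 3D, body voxels outside every region, zero flow


def _ramp(p: np.ndarray, p0: float, p1: float) -> np.ndarray:
    """Smooth cosine step from 0 to 1 over the phase interval [p0, p1]."""
    x = np.clip((p - p0) / (p1 - p0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _lv_shape(p: np.ndarray) -> np.ndarray:
    """Normalized LV volume over the cycle (1 = EDV, 0 = ESV).

    Systolic ejection to phase 0.35, isovolumic hold, a steep E-wave
    refill to 70% of the stroke volume, diastasis, then a gentler A-wave
    (atrial kick) back to EDV.  The E-wave slope exceeds the A-wave slope
    roughly 3:1, as in a normal transmitral inflow pattern.
    """
    p = np.asarray(p, float)
    v = 1.0 - _ramp(p, 0.0, 0.35)  # ejection
    v = v + 0.70 * _ramp(p, 0.42, 0.58)  # E-wave
    v = v + 0.30 * _ramp(p, 0.78, 0.97)  # A-wave
    return v


def _pulse(p: np.ndarray, center: float, width: float) -> np.ndarray:
    """Cyclic Gaussian pulse in cardiac phase."""
    d = (p - center + 0.5) % 1.0 - 0.5
    return np.exp(-0.5 * (d / width) ** 2)


def default_spec(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: float = 2.8,
    n_frames: int = 40,
    venc: float = 120.0,
    noise_snr: float = 0.0,
    background_poly_coeffs: np.ndarray | None = None,
    seed: int = 0,
    jet_speed_scale: float = 1.0,
) -> PhantomSpec:
    """Whole-heart phantom matching typical clinical scan geometry.

    Defaults follow the acquisition layout the pipeline targets:
    isotropic 2.8 mm voxels, 40 reconstructed time frames, VENC
    120 cm/s.  Region positions and sizes scale with the field of view so
    smaller grids produce geometrically similar phantoms.  Peak speeds
    stay below VENC by default; ``jet_speed_scale > 1`` raises them (e.g.
    1.5 to plant single phase wraps in the aortic jet).
    """
    fov = np.array(grid_shape, float) * voxel_size
    sc = float(min(fov)) / 179.2  # relative to the 64-voxel reference build
    p = np.arange(n_frames) / n_frames
    lv = _lv_shape(p)

    def centers(frac: tuple[float, float, float], sway: float = 2.0) -> np.ndarray:
        """Per-frame center path: fractional position plus a small sway."""
        base = np.array(frac) * fov
        offset = sway * sc * np.sin(2 * np.pi * p)
        path = np.tile(base, (n_frames, 1))
        path[:, 0] += offset
        return path

    systolic = _pulse(p, 0.18, 0.07)
    e_wave = _pulse(p, 0.50, 0.045)
    a_wave = _pulse(p, 0.87, 0.055)

    regions = [
        RegionGeometry(
            name="AAo",
            shape="tube",
            center_path=centers((0.68, 0.68, 0.50), sway=0.0),
            size_curve=np.full(n_frames, 14.0 * sc),
            peak_speed=jet_speed_scale * (1.1 * systolic + 0.02),
            axis=(0.0, 0.0, 1.0),
            length=0.62 * float(fov[2]),
            jet_width=7.0 * sc,
            sigma_base=0.02,
            sigma_peak=0.28 * systolic,
        ),
        RegionGeometry(
            name="LV",
            shape="sphere",
            center_path=centers((0.31, 0.31, 0.33)),
            size_curve=(60.0 + 90.0 * lv) * sc**3,
            peak_speed=jet_speed_scale * (1.0 * e_wave + 0.45 * a_wave + 0.02),
            jet_direction=(0.0, 0.0, 1.0),
            jet_width=8.0 * sc,
            sigma_base=0.02,
            sigma_peak=0.30 * e_wave + 0.10 * a_wave,
        ),
        RegionGeometry(
            name="LA",
            shape="sphere",
            center_path=centers((0.31, 0.31, 0.74)),
            size_curve=(30.0 + 40.0 * (1.0 - lv)) * sc**3,
            peak_speed=jet_speed_scale * (0.6 * systolic + 0.02),
            jet_direction=(0.0, 1.0, 0.0),
            jet_width=6.0 * sc,
            sigma_base=0.02,
            sigma_peak=0.20 * systolic,
        ),
        RegionGeometry(
            name="RV",
            shape="sphere",
            center_path=centers((0.70, 0.28, 0.31)),
            size_curve=(70.0 + 90.0 * lv) * sc**3,
            peak_speed=jet_speed_scale * (0.9 * e_wave + 0.40 * a_wave + 0.02),
            jet_direction=(0.0, 0.0, 1.0),
            jet_width=8.0 * sc,
            sigma_base=0.02,
            sigma_peak=0.25 * e_wave + 0.08 * a_wave,
        ),
        RegionGeometry(
            name="RA",
            shape="sphere",
            center_path=centers((0.70, 0.28, 0.74)),
            size_curve=(35.0 + 45.0 * (1.0 - lv)) * sc**3,
            peak_speed=jet_speed_scale * (0.55 * systolic + 0.02),
            jet_direction=(0.0, 1.0, 0.0),
            jet_width=6.0 * sc,
            sigma_base=0.02,
            sigma_peak=0.18 * systolic,
        ),
    ]
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size=voxel_size,
        n_frames=n_frames,
        venc=venc,
        regions=regions,
        noise_snr=noise_snr,
        background_poly_coeffs=background_poly_coeffs,
        seed=seed,
    )


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase into (-pi, pi]."""
    return np.mod(phi - np.pi, -2.0 * np.pi) + np.pi


def encode_signals(
    velocity: np.ndarray,
    sigma: np.ndarray,
    venc: float,
    s0: np.ndarray,
    voxel_size: float,
    rr_interval: float = 1000.0,
) -> FlowAcquisition:
    """Forward 4-point encoding model.

    ``S = s0``; ``S_i = s0 * exp(-kv^2 sigma_i^2 / 2)``;
    ``phi_i = wrap(kv * u_i)`` with ``kv = pi / VENC`` (VENC converted
    from cm/s to m/s).  ``s0`` is the per-frame reference magnitude.
    """
    velocity = np.asarray(velocity, float)
    sigma = np.asarray(sigma, float)
    s0 = np.asarray(s0, float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    if np.any(s0 < 0):
        raise ValueError("s0 must be non-negative")
    kv = np.pi / (venc / 100.0)
    s_enc = s0[..., None] * np.exp(-0.5 * kv**2 * sigma**2)
    phase = wrap_phase(kv * velocity)
    return FlowAcquisition(
        s_ref=s0,
        s_enc=s_enc,
        phase_diff=phase,
        venc=venc,
        voxel_size=voxel_size,
        rr_interval=rr_interval,
    )


def add_noise(acq: FlowAcquisition, snr: float, seed: int) -> FlowAcquisition:
    """Add complex Gaussian measurement noise to every encoding.

    The per-component noise standard deviation is ``mean(s0 over the body
    support)/snr``, where the body support is taken as voxels with
    reference magnitude above half its maximum (so air does not dilute
    the reference level).  Reference and encoded complex signals receive
    independent noise; magnitudes become Rician and the phase difference
    is re-derived from the noisy complex pair.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    body = acq.s_ref > 0.5 * acq.s_ref.max()
    level = float(acq.s_ref[body].mean()) if body.any() else float(acq.s_ref.mean())
    sd = level / snr
    ref_c = acq.s_ref.astype(complex)
    ref_c += rng.normal(0, sd, acq.s_ref.shape) + 1j * rng.normal(0, sd, acq.s_ref.shape)
    enc_c = acq.s_enc * np.exp(1j * acq.phase_diff)
    enc_c += rng.normal(0, sd, acq.s_enc.shape) + 1j * rng.normal(0, sd, acq.s_enc.shape)
    phase = np.angle(enc_c * np.conj(ref_c)[..., None])
    phase = wrap_phase(phase)
    return FlowAcquisition(
        s_ref=np.abs(ref_c),
        s_enc=np.abs(enc_c),
        phase_diff=phase,
        venc=acq.venc,
        voxel_size=acq.voxel_size,
        rr_interval=acq.rr_interval,
    )


def add_background_offset(acq: FlowAcquisition, coeffs: np.ndarray) -> FlowAcquisition:
    """Add a low-order polynomial background phase to all encodings.

    The polynomial (order <= 3, monomials on coordinates normalized to
    [-1, 1]) is evaluated once and added to every phase-difference
    direction in every frame, then re-wrapped — the artifact that the
    background-offset correction is meant to remove.
    """
    coeffs = np.asarray(coeffs, float)
    order = {v: k for k, v in _POLY_TERMS.items()}.get(len(coeffs))
    if coeffs.ndim != 1 or order is None:
        raise ValueError(
            f"coeffs must have length in {sorted(_POLY_TERMS.values())} (order <= 3)"
        )
    basis = polynomial_design_matrix(normalized_coords(acq.grid_shape), order)
    offset = basis @ coeffs  # (nx, ny, nz), rad
    phase = wrap_phase(acq.phase_diff + offset[..., None, None])
    return FlowAcquisition(
        s_ref=acq.s_ref,
        s_enc=acq.s_enc,
        phase_diff=phase,
        venc=acq.venc,
        voxel_size=acq.voxel_size,
        rr_interval=acq.rr_interval,
    )


def _sphere_mask(dist2: np.ndarray, volume_ml: float, voxel_size: float) -> np.ndarray:
    """N nearest voxels to the center, N fixed by the prescribed volume.

    Keeps the voxelized volume within one voxel of the prescription,
    which a hard radius threshold cannot guarantee.
    """
    n = int(round(volume_ml * 1e3 / voxel_size**3))
    n = max(n, 1)
    flat = dist2.ravel()
    idx = np.argpartition(flat, n - 1)[:n]
    mask = np.zeros(flat.shape, bool)
    mask[idx] = True
    return mask.reshape(dist2.shape)


def build_phantom(
    spec: PhantomSpec,
) -> tuple[FlowAcquisition, SegmentationSet, GroundTruth]:
    """Generate one synthetic acquisition with complete ground truth.

    Deterministic given ``spec.seed``: all randomness (measurement noise)
    flows from the single seed.
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    nt = spec.n_frames
    vs = spec.voxel_size
    ax = [np.arange(n) * vs for n in (nx, ny, nz)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    coords = np.stack([X, Y, Z], axis=-1)  # voxel centers, mm

    vel = np.zeros((nx, ny, nz, nt, 3))
    sig = np.zeros((nx, ny, nz, nt, 3))
    masks = {r.name: np.zeros((nx, ny, nz, nt), bool) for r in spec.regions}

    for reg in spec.regions:
        jet_dir = np.asarray(reg.jet_direction, float)
        jet_dir = jet_dir / np.linalg.norm(jet_dir)
        for t in range(nt):
            c = reg.center_path[t]
            rel = coords - c
            if reg.shape == "sphere":
                dist2 = np.einsum("...k,...k->...", rel, rel)
                m = _sphere_mask(dist2, reg.size_curve[t], vs)
                # jet: Gaussian profile around the axis through the center
                along = rel @ jet_dir
                perp2 = dist2 - along**2
                profile = np.exp(-0.5 * perp2 / reg.jet_width**2)
                u_mag = reg.peak_speed[t] * profile
                for k in range(3):
                    vel[..., t, k][m] = (u_mag * jet_dir[k])[m]
                blob = np.exp(-0.5 * dist2 / reg.jet_width**2)
                s_val = reg.sigma_base + reg.sigma_peak[t] * blob
                for k in range(3):
                    sig[..., t, k][m] = s_val[m]
            else:  # tube
                axis = np.asarray(reg.axis, float)
                axis = axis / np.linalg.norm(axis)
                start = c - axis * reg.length / 2.0
                rel_t = coords - start
                along = rel_t @ axis
                perp2 = np.einsum("...k,...k->...", rel_t, rel_t) - along**2
                radius = reg.size_curve[t]
                m = (perp2 <= radius**2) & (along >= 0) & (along <= reg.length)
                profile = np.clip(1.0 - perp2 / radius**2, 0.0, None)
                u_mag = reg.peak_speed[t] * profile
                for k in range(3):
                    vel[..., t, k][m] = (u_mag * axis[k])[m]
                # sigma jet centered on the axis at mid-length
                dist2c = np.einsum("...k,...k->...", coords - c, coords - c)
                blob = np.exp(-0.5 * dist2c / reg.jet_width**2)
                s_val = reg.sigma_base + reg.sigma_peak[t] * blob
                for k in range(3):
                    sig[..., t, k][m] = s_val[m]
            masks[reg.name][..., t] = m

    any_region = np.zeros((nx, ny, nz), bool)
    for m4 in masks.values():
        any_region |= m4.any(axis=3)
    # body: ellipsoid covering the thorax; static tissue has zero flow
    center = (np.array([nx, ny, nz]) - 1) / 2.0 * vs
    semi = np.array([nx, ny, nz]) * vs * 0.48
    norm2 = (((coords - center) / semi) ** 2).sum(axis=-1)
    body = norm2 <= 1.0
    body |= any_region
    static = body & ~any_region

    s0_3d = np.where(body, 1.0, 0.05)
    s0 = np.broadcast_to(s0_3d[..., None], (nx, ny, nz, nt)).copy()

    acq = encode_signals(vel, sig, spec.venc, s0, vs, spec.rr_interval)
    if spec.background_poly_coeffs is not None and np.any(spec.background_poly_coeffs):
        acq = add_background_offset(acq, spec.background_poly_coeffs)
    if spec.noise_snr > 0:
        acq = add_noise(acq, spec.noise_snr, spec.seed)

    seg = SegmentationSet(masks=masks, voxel_size=vs)
    true_tke = compute_tke(sig)
    speed = np.linalg.norm(vel, axis=-1)
    tke_filt = median_filter_frames(true_tke)
    true_metrics = {
        name: frame_metrics(true_tke, speed, seg, name, tke_filtered=tke_filt)
        for name in masks
    }
    truth = GroundTruth(
        true_velocity=vel,
        true_sigma=sig,
        true_tke=true_tke,
        masks=seg,
        true_region_metrics=true_metrics,
        body_mask=body,
        static_mask=static,
    )
    return acq, seg, truth
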