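"""Voxelwise velocity and turbulence reconstruction for 4D flow MRI.

A 4D flow acquisition with simple asymmetric 4-point encoding measures, per
cardiac time frame, one flow-compensated reference magnitude image ``S`` and
three motion-encoded magnitude images ``S_i`` together with the three
phase-difference images ``phi_i``.  Under a Gaussian intravoxel velocity
distribution the mean velocity along encoding direction ``i`` is

    u_i = phi_i / kv,        kv = pi / VENC   (VENC in m/s)

and the intravoxel velocity standard deviation follows from the magnitude
attenuation of the encoded signal,

    sigma_i = (1/kv) * sqrt(2 * ln(S / S_i)).

Turbulent kinetic energy density is then

    TKE = 1/2 * rho * sum_i sigma_i**2    [J/m^3]

with blood density rho = 1060 kg/m^3.

Array conventions: scalar voxel fields have shape ``(nx, ny, nz, nt)``;
3-component fields have shape ``(nx, ny, nz, nt, 3)`` with the component
axis last.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RHO_BLOOD",
    "MU_BLOOD",
    "FlowAcquisition",
    "VelocityField",
    "TurbulenceMap",
    "compute_velocity",
    "unwrap_velocity",
    "correct_background",
    "estimate_sigma",
    "compute_tke",
    "polynomial_design_matrix",
    "normalized_coords",
]

#: Blood density [kg/m^3].
RHO_BLOOD = 1060.0
#: Dynamic viscosity of blood [Pa*s].
MU_BLOOD = 4.0e-3


@dataclass
class FlowAcquisition:
    """One 4-point 4D flow acquisition.

    Parameters
    ----------
    s_ref
        Reference (flow-compensated) magnitude, shape ``(nx, ny, nz, nt)``.
    s_enc
        Motion-encoded magnitudes, shape ``(nx, ny, nz, nt, 3)``.
    phase_diff
        Phase differences in radians, wrapped into ``(-pi, pi]``, shape
        ``(nx, ny, nz, nt, 3)``.
    venc
        Velocity encoding [cm/s].
    voxel_size
        Isotropic voxel edge length [mm].
    rr_interval
        RR interval (cycle duration) [ms].
    """

    s_ref: np.ndarray
    s_enc: np.ndarray
    phase_diff: np.ndarray
    venc: float
    voxel_size: float
    rr_interval: float = 1000.0

    def __post_init__(self) -> None:
        self.s_ref = np.asarray(self.s_ref, dtype=float)
        self.s_enc = np.asarray(self.s_enc, dtype=float)
        self.phase_diff = np.asarray(self.phase_diff, dtype=float)
        if self.s_ref.ndim != 4:
            raise ValueError("s_ref must be 4D (nx, ny, nz, nt)")
        if self.s_enc.shape != self.s_ref.shape + (3,):
            raise ValueError("s_enc must have shape s_ref.shape + (3,)")
        if self.phase_diff.shape != self.s_enc.shape:
            raise ValueError("phase_diff must have the same shape as s_enc")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if np.any(self.s_ref < 0) or np.any(self.s_enc < 0):
            raise ValueError("signal magnitudes must be non-negative")

    @property
    def venc_ms(self) -> float:
        """VENC in m/s."""
        return self.venc / 100.0

    @property
    def kv(self) -> float:
        """Motion sensitivity kv = pi / VENC [rad*s/m]."""
        return np.pi / self.venc_ms

    @property
    def n_frames(self) -> int:
        return self.s_ref.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.s_ref.shape[:3]


@dataclass
class VelocityField:
    """Per-frame 3-component velocity field [m/s]."""

    u: np.ndarray  # (nx, ny, nz, nt, 3)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 5 or self.u.shape[-1] != 3:
            raise ValueError("u must have shape (nx, ny, nz, nt, 3)")

    @property
    def speed(self) -> np.ndarray:
        """Euclidean speed ``||u||_2``, shape ``(nx, ny, nz, nt)``."""
        return np.linalg.norm(self.u, axis=-1)


@dataclass
class TurbulenceMap:
    """Intravoxel velocity standard deviations and TKE density.

    ``tke`` always equals ``1/2 * rho * sum_i sigma_i**2`` voxelwise.
    ``unreliable`` flags voxels where the magnitude ratio implied
    ``sigma_i * kv > 2`` (encoded signal below exp(-2) of the reference);
    there the inversion is ill-conditioned and sigma has been capped.
    """

    sigma: np.ndarray  # (nx, ny, nz, nt, 3)
    tke: np.ndarray  # (nx, ny, nz, nt)
    rho: float = RHO_BLOOD
    unreliable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.tke = np.asarray(self.tke, dtype=float)
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


def compute_velocity(acq: FlowAcquisition) -> VelocityField:
    """Velocity from phase differences: ``u_i = phi_i * VENC / pi``."""
    u = acq.phase_diff * (acq.venc_ms / np.pi)
    return VelocityField(u=u)


def _spatial_median6(vol: np.ndarray) -> np.ndarray:
    """Median of the 6-neighborhood (faces), edge replication, per voxel.

    ``vol`` is a 4D (nx, ny, nz, nt) array; the median is spatial only.
    """
    p = np.pad(vol, ((1, 1), (1, 1), (1, 1), (0, 0)), mode="edge")
    nbrs = np.stack(
        [
            p[:-2, 1:-1, 1:-1],
            p[2:, 1:-1, 1:-1],
            p[1:-1, :-2, 1:-1],
            p[1:-1, 2:, 1:-1],
            p[1:-1, 1:-1, :-2],
            p[1:-1, 1:-1, 2:],
        ],
        axis=0,
    )
    return np.median(nbrs, axis=0)


def unwrap_velocity(
    vf: VelocityField,
    venc: float,
    body_mask: np.ndarray | None = None,
    max_iter: int = 10,
) -> VelocityField:
    """Correct single phase wraps by candidate search.

    For each voxel, frame and direction the candidates
    ``u + k * 2 * VENC`` for ``k in {-1, 0, +1}`` are scored by the sum of
    absolute differences to the two temporal neighbors (cyclic) and to the
    spatial median of the 6-neighborhood; the lowest-cost candidate wins,
    with ties kept at ``k = 0``.  The sweep repeats until no voxel changes
    (at most ``max_iter`` passes), so a wrapped region wider than one voxel
    is peeled from its boundary inward.  On wrap-free fields the first
    sweep changes nothing, making the operation idempotent.

    Parameters
    ----------
    venc
        Velocity encoding [cm/s] (converted internally to m/s).
    body_mask
        Optional 3D boolean mask; voxels outside it are left untouched.
    """
    venc_ms = venc / 100.0
    u = vf.u.copy()
    sel = None
    if body_mask is not None:
        sel = np.asarray(body_mask, bool)[..., None]
    for _ in range(max_iter):
        changed = False
        for d in range(3):
            ud = u[..., d]
            prev = np.roll(ud, 1, axis=3)
            nxt = np.roll(ud, -1, axis=3)
            smed = _spatial_median6(ud)
            best = ud.copy()
            best_cost = np.abs(ud - prev) + np.abs(ud - nxt) + np.abs(ud - smed)
            for k in (-1, 1):
                cand = ud + k * 2.0 * venc_ms
                cost = np.abs(cand - prev) + np.abs(cand - nxt) + np.abs(cand - smed)
                better = cost < best_cost
                best = np.where(better, cand, best)
                best_cost = np.where(better, cost, best_cost)
            if sel is not None:
                best = np.where(np.broadcast_to(sel, ud.shape), best, ud)
            if not np.array_equal(best, ud):
                changed = True
                u[..., d] = best
        if not changed:
            break
    return VelocityField(u=u)


def normalized_coords(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-center coordinates normalized into [-1, 1] per axis.

    Returns an array of shape ``grid_shape + (3,)``.
    """
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in grid_shape
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def polynomial_design_matrix(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial basis x^a y^b z^c with a+b+c <= order.

    ``coords`` has shape ``(..., 3)``; the result has shape
    ``(..., n_terms)``.  Term order: graded lexicographic starting at the
    constant term.
    """
    if not 0 <= order <= 3:
        raise ValueError("polynomial order must be in [0, 3]")
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    cols = []
    for total in range(order + 1):
        for a, b, c in sorted(
            (a, b, c)
            for a in range(total + 1)
            for b in range(total + 1)
            for c in range(total + 1)
            if a + b + c == total
        ):
            cols.append(x**a * y**b * z**c)
    return np.stack(cols, axis=-1)


def correct_background(
    vf: VelocityField,
    static_mask: np.ndarray,
    order: int = 2,
    min_static_voxels: int = 50,
) -> VelocityField:
    """Remove slowly varying background velocity offsets.

    Per direction, a spatial polynomial (default order 2) is least-squares
    fitted to the time-averaged velocity inside ``static_mask`` (tissue
    assumed stationary) and subtracted from every frame.
    """
    static_mask = np.asarray(static_mask, bool)
    n_static = int(static_mask.sum())
    if n_static < min_static_voxels:
        raise ValueError(
            f"static mask has only {n_static} voxels (< {min_static_voxels}); "
            "use a larger mask or a lower polynomial order"
        )
    coords = normalized_coords(vf.u.shape[:3])
    basis_full = polynomial_design_matrix(coords, order)
    A = basis_full[static_mask]  # (n_static, n_terms)
    if n_static < A.shape[1]:
        raise ValueError("static mask smaller than the number of basis terms")
    u = vf.u.copy()
    u_mean = u.mean(axis=3)  # (nx, ny, nz, 3)
    for d in range(3):
        coef, *_ = np.linalg.lstsq(A, u_mean[..., d][static_mask], rcond=None)
        offset = basis_full @ coef
        u[..., d] -= offset[..., None]
    return VelocityField(u=u)


def estimate_sigma(
    acq: FlowAcquisition, rho: float = RHO_BLOOD, max_sigma_kv: float = 2.0
) -> TurbulenceMap:
    """Intravoxel velocity standard deviation from magnitude attenuation.

    ``sigma_i = (1/kv) sqrt(2 ln(S/S_i))`` wherever ``S > S_i > 0``.
    Where noise pushes ``S_i >= S`` (no apparent attenuation) or ``S = 0``,
    sigma is clamped to zero.  Where the ratio would imply
    ``sigma_i * kv > max_sigma_kv`` the value is capped and the voxel
    flagged unreliable: the encoded signal is essentially crushed and the
    inversion ill-conditioned.
    """
    kv = acq.kv
    s = acq.s_ref[..., None]
    si = acq.s_enc
    valid = (s > si) & (si > 0)
    ratio = np.divide(s, si, out=np.ones_like(si), where=valid)
    sigma = np.where(valid, np.sqrt(2.0 * np.log(ratio)) / kv, 0.0)
    cap = max_sigma_kv / kv
    unreliable = sigma > cap
    sigma = np.minimum(sigma, cap)
    tke = compute_tke(sigma, rho)
    return TurbulenceMap(
        sigma=sigma, tke=tke, rho=rho, unreliable=unreliable.any(axis=-1)
    )


def compute_tke(sigma: np.ndarray, rho: float = RHO_BLOOD) -> np.ndarray:
    """TKE density ``1/2 * rho * sum_i sigma_i**2`` [J/m^3].

    ``sigma`` carries the three direction components on its last axis.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    return 0.5 * rho * np.sum(sigma**2, axis=-1)
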