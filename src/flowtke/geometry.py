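"""Segmentation-derived geometry.

Chamber volumes over the cardiac cycle (hence EDV, ESV and stroke volume),
sphere-equivalent diameters for the non-tubular cavities, centerline-based
mean diameter of the ascending aorta, and Du Bois body surface area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import interp1d
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "REGIONS",
    "SegmentationSet",
    "VolumeCurve",
    "SubjectRecord",
    "chamber_volumes",
    "equivalent_diameter",
    "aorta_centerline",
    "aorta_diameter",
    "bsa_du_bois",
]

#: Anatomical regions handled by the pipeline: ascending aorta, left/right
#: ventricle, left/right atrium.
REGIONS = ("AAo", "LV", "LA", "RV", "RA")


@dataclass
class SegmentationSet:
    """Time-resolved binary masks per anatomical region.

    ``masks`` maps region name to a boolean array of shape
    ``(nx, ny, nz, nt)``.  ``voxel_size`` is the isotropic voxel edge
    length in mm; ``voxel_volume`` is derived in m^3.
    """

    masks: dict[str, np.ndarray]
    voxel_size: float  # mm

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.dtype != bool:
                if not np.isin(m, (0, 1)).all():
                    raise ValueError(f"mask for {name!r} is not binary")
                m = m.astype(bool)
            if m.ndim != 4:
                raise ValueError(f"mask for {name!r} must be 4D (x, y, z, t)")
            self.masks[name] = m

    @property
    def voxel_volume(self) -> float:
        """Voxel volume [m^3]."""
        return (self.voxel_size * 1e-3) ** 3

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.masks)

    @property
    def n_frames(self) -> int:
        return next(iter(self.masks.values())).shape[3]


@dataclass
class VolumeCurve:
    """Per-frame cavity volume with end-diastolic/systolic summaries."""

    region: str
    volumes: np.ndarray  # per-frame, mL
    edv: float = field(init=False)  # mL
    esv: float = field(init=False)  # mL
    sv: float = field(init=False)  # mL, stroke volume = EDV - ESV

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")
        self.edv = float(self.volumes.max())
        self.esv = float(self.volumes.min())
        self.sv = self.edv - self.esv


@dataclass
class SubjectRecord:
    """Demographics and group membership for one subject.

    ``group_flags`` is a subset of {"control", "AS", "AR", "MR", "PR",
    "TR"}; valvular lesions may co-occur in one subject.  BSA is filled
    from weight and height by the Du Bois formula when not given.
    """

    subject_id: str
    group_flags: frozenset[str]
    age: float
    sex: str  # "F" | "M"
    weight: float | None = None  # kg
    height: float | None = None  # cm
    bsa: float | None = None  # m^2

    def __post_init__(self) -> None:
        allowed = {"control", "AS", "AR", "MR", "PR", "TR"}
        self.group_flags = frozenset(self.group_flags)
        if not self.group_flags:
            raise ValueError("at least one group flag is required")
        if not self.group_flags <= allowed:
            raise ValueError(f"unknown group flags: {self.group_flags - allowed}")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.bsa is None and self.weight is not None and self.height is not None:
            self.bsa = bsa_du_bois(self.weight, self.height)


def chamber_volumes(seg: SegmentationSet, region: str) -> VolumeCurve:
    """Cavity volume per frame: voxel count times voxel volume, in mL."""
    if region not in seg.masks:
        raise KeyError(f"region {region!r} absent from segmentation set")
    counts = seg.masks[region].sum(axis=(0, 1, 2))
    volumes_ml = counts * seg.voxel_volume * 1e6
    return VolumeCurve(region=region, volumes=volumes_ml)


def equivalent_diameter(volume: float | np.ndarray) -> float | np.ndarray:
    """Diameter of the sphere with the given volume: ``D = (6V/pi)**(1/3)``.

    Volume in m^3, diameter in m.  Used to size the non-tubular cavities.
    """
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise ValueError("volume must be non-negative")
    d = np.cbrt(6.0 * volume / np.pi)
    return float(d) if d.ndim == 0 else d


def _medial_path(mask: np.ndarray) -> np.ndarray:
    """Minimal geodesic path through the mask interior, as voxel coords.

    Mask voxels form a 26-connected graph whose edge weights are the
    Euclidean step length scaled down toward the medial axis (inverse
    distance-to-wall), so shortest paths hug the vessel center.  The two
    endpoints are found with a double Dijkstra sweep (graph-diameter
    heuristic), which on a tubular mask lands on the inlet and outlet.
    """
    pts = np.argwhere(mask)
    n = len(pts)
    lookup = -np.ones(mask.shape, dtype=np.int64)
    lookup[tuple(pts.T)] = np.arange(n)
    edt = ndimage.distance_transform_edt(mask)
    # quadratic penalty: strongly favors steps along the medial axis
    centrality = 1.0 / (1.0 + edt[tuple(pts.T)]) ** 2
    rows, cols, wts = [], [], []
    # one offset per undirected neighbor pair (lexicographic half-space)
    offs = [
        np.array(o) - 1
        for o in np.ndindex(3, 3, 3)
        if (o[0], o[1], o[2]) > (1, 1, 1)
    ]
    for off in offs:
        q = pts + off
        ok = ((q >= 0) & (q < mask.shape)).all(axis=1)
        j = np.full(n, -1, dtype=np.int64)
        j[ok] = lookup[tuple(q[ok].T)]
        ok &= j >= 0
        i = np.arange(n)[ok]
        j = j[ok]
        step = float(np.linalg.norm(off))
        rows.append(i)
        cols.append(j)
        wts.append(step * 0.5 * (centrality[i] + centrality[j]))
    g = coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    d0 = dijkstra(g, directed=False, indices=0)
    far1 = int(np.argmax(np.where(np.isfinite(d0), d0, -1)))
    d1, pred = dijkstra(g, directed=False, indices=far1, return_predecessors=True)
    far2 = int(np.argmax(np.where(np.isfinite(d1), d1, -1)))
    path = [far2]
    while path[-1] != far1:
        path.append(int(pred[path[-1]]))
    return pts[path[::-1]].astype(float)


def _smooth_path(path: np.ndarray, k: int) -> np.ndarray:
    """Moving-average smoothing of an ordered point list, edge-replicated."""
    k = max(1, min(k, max(1, len(path) // 2)) | 1)  # odd, at most half length
    pad = k // 2
    padded = np.pad(path, ((pad, pad), (0, 0)), mode="edge")
    kern = np.ones(k) / k
    return np.stack(
        [np.convolve(padded[:, a], kern, mode="valid") for a in range(3)], axis=1
    )


def _recenter(path: np.ndarray, mask: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Pull path points to the centroid of the local perpendicular slab.

    Tangents come from a smoothed copy of the path so endpoint jitter does
    not tilt the slabs, and the slab is capped at the lumen radius so an
    oblique plane cannot reach far along the vessel.
    """
    coords = np.argwhere(mask).astype(float)
    r_cap = float(ndimage.distance_transform_edt(mask).max()) + 1.0
    for _ in range(n_iter):
        tang = np.gradient(_smooth_path(path, 5), axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        # near the ends the raw path runs diagonally from a cap corner, which
        # would tilt the slab and freeze the endpoints; borrow the adjacent
        # interior tangent instead
        edge = min(4, max(1, len(path) // 4))
        tang[:edge] = tang[edge]
        tang[-edge:] = tang[-edge - 1]
        new = path.copy()
        for i, (p, t) in enumerate(zip(path, tang)):
            rel = coords - p
            along = rel @ t
            perp2 = np.einsum("ij,ij->i", rel, rel) - along**2
            sel = (np.abs(along) <= 0.75) & (perp2 <= r_cap**2)
            if not sel.any():
                continue
            shift = rel[sel].mean(axis=0)
            shift -= (shift @ t) * t  # move only within the normal plane
            new[i] = p + shift
        path = new
    return path


def aorta_centerline(
    mask: np.ndarray, voxel_size: float, smoothing: int = 3
) -> np.ndarray:
    """Centerline of a tubular mask, ordered inlet to outlet, in mm.

    A medial geodesic path (Dijkstra through the mask with steps weighted
    toward the distance-transform ridge) is refined by perpendicular-slab
    centroid averaging, lightly smoothed with a moving average, and
    resampled to roughly one-voxel spacing by arc length.  Works on bent
    tubes, where slab-wise centroid tracking along a single fixed axis
    would fold back on itself.

    Raises
    ------
    ValueError
        If the mask is empty, disconnected, or too thin to be tubular
        (maximum inscribed radius below ~1.5 voxels).
    """
    mask = np.asarray(mask, bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3D volume (single frame)")
    if not mask.any():
        raise ValueError("mask is empty")
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components; expected 1")
    if ndimage.distance_transform_edt(mask).max() < 1.5:
        raise ValueError("mask is too thin to be a tubular structure")
    path_vox = _recenter(_medial_path(mask), mask)
    # moving-average smoothing with edge replication
    k = max(1, min(smoothing, len(path_vox) // 2) | 1)  # odd
    pad = k // 2
    padded = np.pad(path_vox, ((pad, pad), (0, 0)), mode="edge")
    kern = np.ones(k) / k
    sm = np.stack(
        [np.convolve(padded[:, a], kern, mode="valid") for a in range(3)], axis=1
    )
    # resample to ~1 voxel spacing by arc length
    seglen = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    if s[-1] <= 0:
        raise ValueError("degenerate centerline (zero length)")
    n_out = max(int(round(s[-1])) + 1, 5)
    s_new = np.linspace(0.0, s[-1], n_out)
    out = interp1d(s, sm, axis=0)(s_new)
    return out * voxel_size


def aorta_diameter(
    mask: np.ndarray,
    centerline: np.ndarray,
    voxel_size: float,
    n_planes: int = 10,
    end_fraction: float = 0.10,
) -> float:
    """Mean vessel diameter from cross-sectional areas along a centerline.

    At ``n_planes`` evenly spaced centerline points (excluding a fraction
    of the line at each end), the mask is intersected with a one-voxel
    thick slab normal to the local tangent; the cross-sectional area is
    the in-slab voxel volume divided by slab thickness, and the diameter
    of each plane is that of the circle with equal area.  Returns the mean
    diameter in meters.
    """
    mask = np.asarray(mask, bool)
    centerline = np.asarray(centerline, float)
    if len(centerline) < 5:
        raise ValueError("centerline must have at least 5 points")
    seglen = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    targets = np.linspace(end_fraction * total, (1 - end_fraction) * total, n_planes)
    pos = interp1d(s, centerline, axis=0)
    # tangents from centered finite differences of the resampled line
    eps = max(total * 1e-3, 1e-6)
    coords = (np.argwhere(mask) + 0.0) * voxel_size  # voxel centers, mm
    h = voxel_size  # slab thickness: one voxel
    areas = []
    for t in targets:
        p = pos(t)
        tan = pos(min(t + eps, total)) - pos(max(t - eps, 0.0))
        norm = np.linalg.norm(tan)
        if norm == 0:
            continue
        tan = tan / norm
        dist = (coords - p) @ tan
        n_in = int(np.count_nonzero(np.abs(dist) <= h / 2))
        if n_in == 0:
            continue
        areas.append(n_in * voxel_size**3 / h)  # mm^2
    if len(areas) < 3:
        raise ValueError("fewer than 3 valid cross-sectional planes")
    d_mm = float(np.mean([2.0 * np.sqrt(a / np.pi) for a in areas]))
    return d_mm * 1e-3


def bsa_du_bois(weight: float, height: float) -> float:
    """Du Bois body surface area [m^2] from weight [kg] and height [cm].

    ``BSA = 0.007184 * W**0.425 * H**0.725``.
    """
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725
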