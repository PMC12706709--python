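"""Dataset I/O: 4D NIfTI volumes plus a JSON manifest.

A dataset directory holds one 4D volume (x, y, z, frame) per quantity per
encoding — reference magnitude, three encoded magnitudes, three phase
differences — one 4D binary mask per region, and a ``manifest.json``
recording VENC, geometry, timing, seed and relative file paths.  Ground
truth, when present, lives under a ``truth/`` subtree with the same
layout.  The manifest is the unit of dataset identity: every pipeline
command takes it as input and validates it before computing.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from pydantic import BaseModel, Field

from .geometry import SegmentationSet
from .phantom import GroundTruth
from .recon import FlowAcquisition

__all__ = ["DatasetManifest", "write_dataset", "read_dataset", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.json"
_ENC = ("x", "y", "z")


class DatasetManifest(BaseModel):
    """Schema-validated description of one dataset on disk."""

    schema_version: int = 1
    venc: float = Field(gt=0, description="velocity encoding [cm/s]")
    voxel_size: float = Field(gt=0, description="isotropic voxel size [mm]")
    n_frames: int = Field(ge=4)
    rr_interval: float = Field(gt=0, description="cycle duration [ms]")
    seed: int | None = None
    encoding_order: list[str] = list(_ENC)
    regions: list[str]
    files: dict[str, str]
    has_truth: bool = False


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def _save(vol: np.ndarray, path: Path, voxel_size: float) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol), _affine(voxel_size))
    if path.suffix == ".gz":
        # gzip with mtime=0 so identical data yields identical bytes
        path.write_bytes(gzip.compress(img.to_bytes(), mtime=0))
    else:
        nib.save(img, str(path))


def _load(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"volume file missing: {path}")
    try:
        return np.asarray(nib.load(str(path)).get_fdata())
    except Exception as exc:  # corrupt file: identify it for the user
        raise OSError(f"failed to read volume file {path}: {exc}") from exc


def write_dataset(
    out_dir: str | Path,
    acq: FlowAcquisition,
    seg: SegmentationSet,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> Path:
    """Write a dataset directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = acq.voxel_size
    files: dict[str, str] = {}

    def put(key: str, vol: np.ndarray, rel: str, dtype=None) -> None:
        v = vol.astype(dtype) if dtype is not None else vol
        _save(v, out / rel, vs)
        files[key] = rel

    put("s_ref", acq.s_ref, "s_ref.nii.gz")
    for i, e in enumerate(_ENC):
        put(f"s_enc_{e}", acq.s_enc[..., i], f"s_enc_{e}.nii.gz")
        put(f"phase_{e}", acq.phase_diff[..., i], f"phase_{e}.nii.gz")
    for region, mask in seg.masks.items():
        put(f"mask_{region}", mask, f"mask_{region}.nii.gz", dtype=np.uint8)
    if truth is not None:
        for i, e in enumerate(_ENC):
            put(f"truth_velocity_{e}", truth.true_velocity[..., i], f"truth/velocity_{e}.nii.gz")
            put(f"truth_sigma_{e}", truth.true_sigma[..., i], f"truth/sigma_{e}.nii.gz")
        put("truth_tke", truth.true_tke, "truth/tke.nii.gz")
        put("truth_body_mask", truth.body_mask[..., None], "truth/body_mask.nii.gz", dtype=np.uint8)
        put("truth_static_mask", truth.static_mask[..., None], "truth/static_mask.nii.gz", dtype=np.uint8)

    manifest = DatasetManifest(
        venc=acq.venc,
        voxel_size=vs,
        n_frames=acq.n_frames,
        rr_interval=acq.rr_interval,
        seed=seed,
        regions=list(seg.masks),
        files=files,
        has_truth=truth is not None,
    )
    mpath = out / MANIFEST_NAME
    mpath.write_text(manifest.model_dump_json(indent=2))
    return mpath


def read_dataset(
    manifest_path: str | Path,
) -> tuple[FlowAcquisition, SegmentationSet, dict]:
    """Read a dataset; returns (acquisition, segmentations, extras).

    ``extras`` carries the manifest plus any ground-truth volumes found
    (keys ``true_velocity``, ``true_sigma``, ``true_tke``, ``body_mask``,
    ``static_mask``).
    """
    mpath = Path(manifest_path)
    if mpath.is_dir():
        mpath = mpath / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"manifest not found: {mpath}")
    manifest = DatasetManifest.model_validate_json(mpath.read_text())
    root = mpath.parent

    s_ref = _load(root / manifest.files["s_ref"])
    s_enc = np.stack([_load(root / manifest.files[f"s_enc_{e}"]) for e in _ENC], axis=-1)
    phase = np.stack([_load(root / manifest.files[f"phase_{e}"]) for e in _ENC], axis=-1)
    acq = FlowAcquisition(
        s_ref=s_ref,
        s_enc=s_enc,
        phase_diff=phase,
        venc=manifest.venc,
        voxel_size=manifest.voxel_size,
        rr_interval=manifest.rr_interval,
    )
    masks = {
        r: _load(root / manifest.files[f"mask_{r}"]).astype(bool)
        for r in manifest.regions
        if f"mask_{r}" in manifest.files
    }
    seg = SegmentationSet(masks=masks, voxel_size=manifest.voxel_size)
    extras: dict = {"manifest": manifest}
    if manifest.has_truth:
        extras["true_velocity"] = np.stack(
            [_load(root / manifest.files[f"truth_velocity_{e}"]) for e in _ENC], axis=-1
        )
        extras["true_sigma"] = np.stack(
            [_load(root / manifest.files[f"truth_sigma_{e}"]) for e in _ENC], axis=-1
        )
        extras["true_tke"] = _load(root / manifest.files["truth_tke"])
        extras["body_mask"] = _load(root / manifest.files["truth_body_mask"])[..., 0].astype(bool)
        extras["static_mask"] = _load(root / manifest.files["truth_static_mask"])[..., 0].astype(bool)
    return acq, seg, extras
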