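"""Volume preprocessing: background crop, resize, Z-score normalization.

The pipeline assumes volumes arrive already brain-extracted and
bias-corrected (standard external tools); what remains before the network
sees a case is (1) cropping away the black background, (2) resampling to
the working grid, (3) Z-score intensity standardization.

Voxel coordinate convention throughout: (depth, height, width) index
order, 0-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

from .nn.tensor import interp_matrix


@dataclasses.dataclass
class PreprocessConfig:
    """Working-grid and normalization settings.

    target_size components must be multiples of 16: the global branch
    tokenizes on a /16 patch grid and the segmentation ladder needs /8.
    """

    target_size: tuple = (160, 160, 160)
    crop_threshold: float = 0.0
    zscore_brain_only: bool = False
    zscore_before_resize: bool = False

    def __post_init__(self):
        for t in self.target_size:
            if t < 16 or t % 16:
                raise ValueError("target_size entries must be >=16 and divisible by 16")


def crop_background(volume: np.ndarray, mask: np.ndarray | None = None,
                    threshold: float = 0.0):
    """Crop to the minimal bounding box of voxels with intensity > threshold.

    Returns (cropped volume, cropped mask or None, bounding box) where the
    box is a tuple of three (start, stop) pairs for provenance.
    """
    if volume.size == 0:
        raise ValueError("empty volume")
    fg = volume > threshold
    if not fg.any():
        raise ValueError("volume is entirely background at this threshold")
    bbox = []
    slices = []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        prof = fg.any(axis=other)
        idx = np.nonzero(prof)[0]
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        bbox.append((lo, hi))
        slices.append(slice(lo, hi))
    sl = tuple(slices)
    out_mask = mask[sl] if mask is not None else None
    return volume[sl], out_mask, tuple(bbox)


def resize_volume(volume: np.ndarray, target: tuple,
                  mode: str = "linear") -> np.ndarray:
    """Resample to exactly ``target`` shape.

    ``mode`` "linear" for image volumes, "nearest" for masks (keeps the
    value set intact). Separable 1-D interpolation matrices give exact
    output shapes and full determinism.
    """
    if any(t <= 0 for t in target):
        raise ValueError("target sizes must be positive")
    out = np.asarray(volume, dtype=np.float32)
    for ax, (n_in, n_out) in enumerate(zip(volume.shape, target)):
        if n_in == n_out:
            continue
        M = interp_matrix(n_in, n_out, mode)
        out = np.moveaxis(np.tensordot(M, out, axes=([1], [ax])), 0, ax)
    if mode == "nearest":
        out = out.astype(volume.dtype)
    return out


def zscore(volume: np.ndarray, region: np.ndarray | None = None) -> np.ndarray:
    """Standardize to zero mean, unit SD (population SD over the full grid).

    ``region`` restricts the statistics to a boolean subset (e.g. brain
    voxels) while still transforming the whole volume.
    """
    vals = volume[region] if region is not None else volume
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("zero-variance volume cannot be Z-scored")
    return ((volume - mu) / sd).astype(np.float32)


def preprocess_case(volume: np.ndarray, mask: np.ndarray | None,
                    cfg: PreprocessConfig):
    """crop -> resize -> zscore (order of the last two configurable)."""
    vol, msk, bbox = crop_background(volume, mask, cfg.crop_threshold)
    if cfg.zscore_before_resize:
        region = vol > cfg.crop_threshold if cfg.zscore_brain_only else None
        vol = zscore(vol, region)
        vol = resize_volume(vol, cfg.target_size, "linear")
    else:
        vol = resize_volume(vol, cfg.target_size, "linear")
        region = vol > cfg.crop_threshold if cfg.zscore_brain_only else None
        vol = zscore(vol, region)
    if msk is not None:
        msk = resize_volume(msk, cfg.target_size, "nearest")
    return vol, msk, bbox


# -- NIfTI I/O ------------------------------------------------------------

def load_nifti(path: str | Path):
    """Return (array float32, affine). Axis order as stored (D, H, W)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float32), img.affine


def save_nifti(data: np.ndarray, path: str | Path,
               affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data),
                             np.eye(4) if affine is None else affine),
             str(path))


def preprocess_dataset(manifest, out_dir: str | Path,
                       cfg: PreprocessConfig):
    """Apply the pipeline to every case in a manifest; write a new manifest."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in manifest.itertuples():
        vol, affine = load_nifti(row.volume)
        msk, _ = load_nifti(row.mask)
        vol, msk, bbox = preprocess_case(vol, msk.astype(np.uint8), cfg)
        vpath = out / f"{row.case_id}_vol.nii.gz"
        mpath = out / f"{row.case_id}_mask.nii.gz"
        save_nifti(vol, vpath, affine)
        save_nifti(msk.astype(np.uint8), mpath, affine)
        rows.append({"case_id": row.case_id, "label": int(row.label),
                     "volume": str(vpath), "mask": str(mpath),
                     "bbox": str(bbox)})
    new_manifest = pd.DataFrame(rows)
    new_manifest.to_csv(out / "manifest.csv", index=False)
    return new_manifest
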