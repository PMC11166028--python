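"""Two-class 3-D lesion phantoms with exact ground-truth masks.

The generator emulates the situation the joint model is built for:
single-channel T2-FLAIR-like brain volumes in which white-matter lesions
appear as hyperintense ellipsoids inside a darker "brain" region, and the
two diseases differ in lesion *count*, *size* and *spatial dispersion* —
MS-like cases (label 0) carry many small scattered lesions, NMOSD-like
cases (label 1) fewer, larger, more compact ones. Masks are exact by
construction (union of the stamped ellipsoids), which is what makes every
downstream stage testable without clinical data.

Augmentation follows the training-time protocol: with probability ``p`` a
flip along one uniformly chosen axis, and independently with probability
``p`` a rotation (axis-aligned 90-degree multiples by default, so masks
need no interpolation; free-angle rotation is available behind a flag).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclasses.dataclass
class CaseSample:
    """One volume + lesion mask + disease label (0 = MS-like, 1 = NMOSD-like)."""

    volume: np.ndarray
    mask: np.ndarray
    label: int
    case_id: str

    def __post_init__(self):
        if self.volume.shape != self.mask.shape:
            raise ValueError("volume and mask shapes differ")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary")


@dataclasses.dataclass
class PhantomParams:
    """Generator knobs; per-class entries are (class0, class1).

    Class 0 draws more, smaller, more dispersed lesions than class 1 — the
    separability contract the classifier is trained against.
    """

    grid_size: int = 32
    lesion_count_range: tuple = ((6, 10), (1, 2))
    lesion_radius_range: tuple = ((1.5, 2.2), (3.0, 4.0))
    dispersion: tuple = (0.85, 0.40)
    lesion_intensity: float = 1.0
    background_intensity: float = 0.0
    brain_intensity: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        for lo, hi in self.lesion_count_range:
            if hi < lo or lo < 0:
                raise ValueError("empty lesion count range")
        for lo, hi in self.lesion_radius_range:
            if hi < lo or lo < 1.0:
                raise ValueError("lesion radii must be >= 1 voxel")
        # largest lesion (with its 1.1x per-axis jitter) must fit inside the
        # smallest brain semi-axis (0.35 * grid) with a one-voxel margin
        max_r = max(hi for _, hi in self.lesion_radius_range)
        if 0.35 * self.grid_size <= 1.1 * max_r + 1.0:
            raise ValueError(
                f"grid_size {self.grid_size} too small to contain a lesion "
                f"of radius {max_r}")


def _ellipsoid_mask(shape: tuple, center: np.ndarray, radii: np.ndarray,
                    rotation: np.ndarray) -> np.ndarray:
    """Boolean grid of voxels whose centres fall inside the ellipsoid."""
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    pts = np.stack(grids, axis=-1) - center          # (D,H,W,3)
    local = pts @ rotation                            # into ellipsoid frame
    q = (local / radii) ** 2
    return q.sum(axis=-1) <= 1.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation matrix (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def generate_case(label: int, params: PhantomParams, seed: int,
                  case_id: str | None = None) -> CaseSample:
    """Deterministically build one phantom for the given class."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    g = params.grid_size
    shape = (g, g, g)
    center = np.array([g / 2.0] * 3)
    brain_radii = np.array([0.42, 0.38, 0.35]) * g

    brain = _ellipsoid_mask(shape, center, brain_radii, np.eye(3))

    count_lo, count_hi = params.lesion_count_range[label]
    r_lo, r_hi = params.lesion_radius_range[label]
    disp = params.dispersion[label]
    n_lesions = int(rng.integers(count_lo, count_hi + 1))

    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_lesions):
        base_r = rng.uniform(r_lo, r_hi)
        radii = base_r * rng.uniform(0.9, 1.1, size=3)
        # lesion centre inside the brain, pulled inward by the max radius
        for _attempt in range(64):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = rng.uniform() ** (1 / 3)
            offset = disp * rad * u * (brain_radii - radii.max() - 1.0)
            c = center + offset
            q = ((c - center) / (brain_radii - radii.max() - 1.0)) ** 2
            if q.sum() <= 1.0:
                break
        mask |= _ellipsoid_mask(shape, c, radii, _random_rotation(rng))
    mask &= brain

    volume = np.full(shape, params.background_intensity, dtype=np.float32)
    volume[brain] = params.brain_intensity
    volume[mask] += params.lesion_intensity
    if params.noise_sd > 0:
        volume = volume + rng.normal(0.0, params.noise_sd,
                                     size=shape).astype(np.float32)
    if case_id is None:
        case_id = f"case_l{label}_s{seed}"
    return CaseSample(volume.astype(np.float32), mask.astype(np.uint8),
                      int(label), case_id)


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(n_per_class: int, params: PhantomParams,
                     seed: int) -> list[CaseSample]:
    """Balanced dataset of 2*n_per_class phantoms with derived per-case seeds."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    cases = []
    for i in range(2 * n_per_class):
        label = i % 2
        child = _child_seed(seed, i)
        cases.append(generate_case(label, params, child,
                                   case_id=f"case_{i:04d}"))
    return cases


def dataset_manifest(cases: list[CaseSample]) -> pd.DataFrame:
    return pd.DataFrame({
        "case_id": [c.case_id for c in cases],
        "label": [c.label for c in cases],
    })


def save_dataset(cases: list[CaseSample], out_dir: str | Path) -> pd.DataFrame:
    """Write NIfTI volume+mask per case plus a manifest CSV; returns manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cases:
        vpath = out / f"{c.case_id}_vol.nii.gz"
        mpath = out / f"{c.case_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(c.volume, np.eye(4)), vpath)
        nib.save(nib.Nifti1Image(c.mask.astype(np.uint8), np.eye(4)), mpath)
        rows.append({"case_id": c.case_id, "label": c.label,
                     "volume": str(vpath), "mask": str(mpath)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[CaseSample]:
    import nibabel as nib

    manifest = pd.read_csv(manifest_path)
    cases = []
    for row in manifest.itertuples():
        vol = np.asarray(nib.load(row.volume).dataobj, dtype=np.float32)
        mask = np.asarray(nib.load(row.mask).dataobj).astype(np.uint8)
        cases.append(CaseSample(vol, mask, int(row.label), str(row.case_id)))
    return cases


def augment(sample: CaseSample, p: float = 0.5, rng_seed: int = 0,
            free_angle: bool = False) -> CaseSample:
    """Random flip + rotation, identical transform on volume and mask.

    Flip and rotation are gated independently, each with probability ``p``.
    Default rotations are 90-degree multiples about a random axis so the
    mask stays exactly binary; ``free_angle`` enables continuous-angle
    rotation (trilinear volume, nearest-neighbour mask).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    vol, mask = sample.volume, sample.mask
    if rng.random() < p:
        axis = int(rng.integers(3))
        vol = np.flip(vol, axis=axis)
        mask = np.flip(mask, axis=axis)
    if rng.random() < p:
        axis = int(rng.integers(3))
        plane = tuple(a for a in range(3) if a != axis)
        if free_angle:
            angle = float(rng.uniform(0.0, 360.0))
            vol = ndimage.rotate(vol, angle, axes=plane, reshape=False,
                                 order=1, mode="nearest")
            mask = ndimage.rotate(mask, angle, axes=plane, reshape=False,
                                  order=0, mode="nearest")
        else:
            k = int(rng.integers(1, 4))
            vol = np.rot90(vol, k=k, axes=plane)
            mask = np.rot90(mask, k=k, axes=plane)
    return CaseSample(np.ascontiguousarray(vol),
                      np.ascontiguousarray(mask).astype(np.uint8),
                      sample.label, sample.case_id)
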