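"""NIfTI I/O, dataset manifests, and the synthetic phantom generator.

The phantom generator emulates the essential geometry of contrast-enhanced
breast MRI at the single, maximally enhanced phase: a smooth tissue-like
background texture, zero or more bright ellipsoidal lesions with irregular
margins, additive acquisition noise, an exact binary lesion mask, and a
per-volume lesion-present label for the auxiliary classification task.  It
makes no attempt to model contrast kinetics, coil inhomogeneity, or
anatomy beyond "soft-tissue field with bright blobs" — see docs/methods.md
for what that does and does not validate.

Axis convention: arrays are ordered ``(depth, height, width)``; depth is the
slice axis, and in-plane rotations act on the height-width plane.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class VolumeSample:
    """One volume with its aligned mask and lesion-present label."""

    volume: np.ndarray
    mask: np.ndarray
    has_lesion: bool
    sample_id: str
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.volume.shape != self.mask.shape:
            raise ValueError(f"volume {self.volume.shape} and mask "
                             f"{self.mask.shape} shapes differ")
        if bool(self.mask.any()) != bool(self.has_lesion):
            raise ValueError("has_lesion inconsistent with mask content")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom dataset.

    Defaults are the package's desk-scale study conditions: 32 volumes of
    32 x 48 x 48 isotropic-millimetre voxels, most containing one or two
    bright lesions of 4-9 voxel radius at twice the background intensity.
    """

    n_volumes: int = 32
    slices_per_volume: int = 32
    in_plane_extent: int = 48
    lesion_probability: float = 0.8
    lesions_per_volume: tuple[int, int] = (1, 2)
    lesion_radius_range: tuple[float, float] = (4.0, 9.0)
    lesion_contrast: float = 2.0
    background_smoothness: float = 6.0
    boundary_irregularity: float = 0.2
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_volumes < 1 or self.slices_per_volume < 1 or self.in_plane_extent < 1:
            raise ValueError("volume counts and extents must be positive")
        if not 0.0 <= self.lesion_probability <= 1.0:
            raise ValueError("lesion_probability must lie in [0, 1]")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid lesion radius range")
        if 2 * hi >= min(self.slices_per_volume, self.in_plane_extent):
            raise ValueError("lesion radii must fit inside the volume")
        if self.lesion_contrast <= 0 or self.noise_sd < 0:
            raise ValueError("contrast must be positive, noise non-negative")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    return (f / sd if sd > 0 else f).astype(np.float32)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    return q * np.sign(np.diag(r))


def ellipsoid_mask(shape, center, radii, rotation, irregularity: float = 0.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Support of a rotated ellipsoid, optionally with a perturbed margin.

    The margin perturbation multiplies the unit-radius threshold by
    ``1 + irregularity * s(x)`` with ``s`` a smooth unit-variance field, so
    the expected volume stays close to the analytic ``4/3 pi a b c``.
    """
    grids = np.indices(shape, dtype=np.float32)
    rel = np.stack([g - c for g, c in zip(grids, center)])
    local = np.tensordot(np.asarray(rotation, dtype=np.float32).T, rel, axes=(1, 0))
    q = sum((local[i] / radii[i]) ** 2 for i in range(3))
    thresh = np.float32(1.0)
    if irregularity > 0:
        if rng is None:
            raise ValueError("rng required for an irregular margin")
        s = _smooth_field(rng, shape, sigma=3.0)
        thresh = (1.0 + irregularity * s).astype(np.float32) ** 2
    return q <= thresh


def generate_phantom_volume(spec: PhantomSpec, rng: np.random.Generator,
                            sample_id: str = "phantom") -> VolumeSample:
    """Draw one synthetic volume with its exact lesion mask."""
    shape = (spec.slices_per_volume, spec.in_plane_extent, spec.in_plane_extent)
    background = 1.0 + 0.15 * _smooth_field(rng, shape, spec.background_smoothness)
    background = np.clip(background, 0.2, None)
    mask = np.zeros(shape, dtype=bool)
    if rng.random() < spec.lesion_probability:
        lo, hi = spec.lesions_per_volume
        n_lesions = int(rng.integers(lo, hi + 1))
        rmax = spec.lesion_radius_range[1]
        for _ in range(max(n_lesions, 1)):
            radii = rng.uniform(*spec.lesion_radius_range, size=3)
            center = [rng.uniform(rmax, s - rmax) for s in shape]
            mask |= ellipsoid_mask(shape, center, radii, _random_rotation(rng),
                                   spec.boundary_irregularity, rng)
    volume = np.where(mask, background * spec.lesion_contrast, background)
    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, shape)
    return VolumeSample(volume=volume.astype(np.float32),
                        mask=mask.astype(np.uint8),
                        has_lesion=bool(mask.any()),
                        sample_id=sample_id)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_volume(array: np.ndarray, path: str | Path,
                 voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 is_mask: bool = False) -> Path:
    """Write a (depth, height, width) array as NIfTI-1 with header spacing.

    Masks are stored as unsigned 8-bit, images as 32-bit float.
    """
    array = np.asarray(array)
    if not np.isfinite(array).all():
        raise ValueError("refusing to write non-finite values")
    dtype = np.uint8 if is_mask else np.float32
    affine = np.diag(list(voxel_spacing) + [1.0])
    img = nib.Nifti1Image(array.astype(dtype), affine)
    img.header.set_zooms(voxel_spacing)
    path = Path(path)
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI-1 volume as a (depth, height, width) array plus spacing."""
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3-D single-phase volume, got shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_sample(image_path: str | Path, mask_path: str | Path,
                sample_id: str) -> VolumeSample:
    vol, spacing = read_volume(image_path)
    mask, _ = read_volume(mask_path)
    return VolumeSample(volume=vol, mask=mask, has_lesion=bool(np.asarray(mask).any()),
                        sample_id=sample_id, voxel_spacing=spacing)


# ---------------------------------------------------------------------------
# dataset manifesting
# ---------------------------------------------------------------------------

def generate_phantom_dataset(spec: PhantomSpec, output_dir: str | Path,
                             metadata_only: bool = False) -> pd.DataFrame:
    """Write image/mask pairs plus a manifest; reproducible from the seed.

    ``metadata_only`` skips the voxel data and records only the manifest —
    used when only dataset bookkeeping (e.g. total slice counts) is needed.
    Returns the manifest with columns sample_id, image_path, mask_path,
    has_lesion, num_slices.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_volumes):
        sid = f"phantom_{i:04d}"
        img_path = output_dir / f"{sid}_image.nii.gz"
        msk_path = output_dir / f"{sid}_mask.nii.gz"
        if metadata_only:
            has_lesion = bool(rng.random() < spec.lesion_probability)
        else:
            sample = generate_phantom_volume(spec, rng, sample_id=sid)
            write_volume(sample.volume, img_path, sample.voxel_spacing)
            write_volume(sample.mask, msk_path, sample.voxel_spacing, is_mask=True)
            has_lesion = sample.has_lesion
        rows.append({"sample_id": sid, "image_path": str(img_path),
                     "mask_path": str(msk_path), "has_lesion": has_lesion,
                     "num_slices": spec.slices_per_volume})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(output_dir / "manifest.csv", index=False)
    sidecar = asdict(spec)
    sidecar["total_slices"] = int(manifest["num_slices"].sum())
    sidecar["metadata_only"] = metadata_only
    (output_dir / "phantom_spec.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    if p.is_dir():
        p = p / "manifest.csv"
    return pd.read_csv(p)


def total_slice_count(manifest: pd.DataFrame) -> int:
    """Total number of 2-D slice images across the manifest."""
    return int(manifest["num_slices"].sum())
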