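"""Volume I/O, preprocessing, augmentation and the synthetic phantom generator.

Real volumes are read and written as NIfTI (via nibabel) or HDF5 (datasets
``image``/``label``, attribute ``spacing``), the layout common to the public
left-atrium benchmark distributions.  The phantom generator builds volumes
that deliberately contain *hard regions*: an ellipsoidal body with thin
curved tubular branches, blurred boundaries and additive noise, so that
per-voxel class membership near boundaries and inside branches is genuinely
ambiguous — the situations the entropy-driven losses are designed to target.

Coordinate convention throughout: 0-based voxel indices, axis order
``(H, W, D)``; in-plane rotations act on the (H, W) axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import nibabel as nib
import numpy as np
from scipy import ndimage

from .entropy_masks import InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

AUGMENT_POLICIES = ("none", "random_flip", "rot90", "rot180", "rot270", "random_rot")


@dataclass
class VolumeSample:
    """One image volume with optional integer labels and voxel spacing (mm)."""

    image: np.ndarray
    label: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    identifier: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 3:
            raise InvalidInputError(f"image must be 3D, got shape {self.image.shape}")
        if self.label is not None:
            self.label = np.asarray(self.label).astype(np.int64)
            if self.label.shape != self.image.shape:
                raise InvalidInputError(
                    f"label shape {self.label.shape} != image shape {self.image.shape}"
                )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be 3 positive reals, got {self.spacing}")

    def without_label(self) -> "VolumeSample":
        """Image-only view handed to the trainer for unlabeled volumes."""
        return VolumeSample(self.image, None, self.spacing, self.identifier)


# ---------------------------------------------------------------------------
# File formats


def load_volume(path, format: str | None = None) -> VolumeSample:
    """Read a volume from NIfTI (``.nii``/``.nii.gz``) or HDF5 (``.h5``)."""
    path = str(path)
    if format is None:
        format = "nifti" if path.endswith((".nii", ".nii.gz")) else "hdf5"
    try:
        if format == "nifti":
            img = nib.load(path)
            data = np.asarray(img.dataobj, dtype=np.float32)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            return VolumeSample(data, None, spacing, identifier=path)
        with h5py.File(path, "r") as f:
            image = np.asarray(f["image"], dtype=np.float32)
            label = np.asarray(f["label"]).astype(np.int64) if "label" in f else None
            if "spacing" in f.attrs:
                spacing = tuple(float(s) for s in f.attrs["spacing"])
            else:
                spacing = (1.0, 1.0, 1.0)
                logger.warning("%s has no spacing attribute; defaulting to (1,1,1)", path)
            return VolumeSample(image, label, spacing, identifier=path)
    except (OSError, KeyError) as exc:
        raise OSError(f"cannot read volume from {path}: {exc}") from exc


def save_volume(sample: VolumeSample, path, format: str | None = None) -> None:
    """Write a volume as NIfTI (image only) or HDF5 (image + label + spacing)."""
    path = str(path)
    if format is None:
        format = "nifti" if path.endswith((".nii", ".nii.gz")) else "hdf5"
    if format == "nifti":
        affine = np.diag(list(sample.spacing) + [1.0])
        nib.save(nib.Nifti1Image(sample.image.astype(np.float32), affine), path)
        return
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across runs
        f.create_dataset("image", data=sample.image.astype(np.float32),
                         track_times=False)
        if sample.label is not None:
            f.create_dataset("label", data=sample.label.astype(np.int64),
                             track_times=False)
        f.attrs["spacing"] = np.asarray(sample.spacing, dtype=np.float64)


# ---------------------------------------------------------------------------
# Preprocessing and augmentation


def preprocess_ct(sample: VolumeSample, hu_window: tuple[float, float] = (-125.0, 275.0),
                  target_spacing: float = 1.0) -> VolumeSample:
    """CT preprocessing: HU clipping, isotropic resampling, min–max scaling.

    Intensities are clipped to ``hu_window`` Hounsfield units, the volume is
    resampled trilinearly (labels nearest-neighbour) to ``target_spacing`` mm
    isotropic, and the image is scaled to [0, 1].
    """
    lo, hi = hu_window
    image = np.clip(sample.image, lo, hi)
    zoom = tuple(s / target_spacing for s in sample.spacing)
    if not np.allclose(zoom, 1.0):
        image = ndimage.zoom(image, zoom, order=1)
        label = (ndimage.zoom(sample.label, zoom, order=0)
                 if sample.label is not None else None)
    else:
        label = sample.label
    image = (image - lo) / (hi - lo)
    return VolumeSample(image, label, (target_spacing,) * 3, sample.identifier)


def normalize_zscore(sample: VolumeSample) -> VolumeSample:
    """Per-volume z-scoring (zero mean, unit variance) for MRI intensities.

    CT volumes get the HU-window pipeline in :func:`preprocess_ct`; for MRI
    no windowing convention exists, so per-volume standardisation is applied
    as this package's choice.
    """
    image = sample.image
    sd = float(image.std())
    image = (image - float(image.mean())) / (sd if sd > 0 else 1.0)
    return VolumeSample(image, sample.label, sample.spacing, sample.identifier)


def random_crop(sample: VolumeSample, crop: tuple[int, int, int],
                rng: np.random.Generator, pad_if_needed: bool = False) -> VolumeSample:
    """Uniformly random aligned sub-volume of image and label."""
    crop = tuple(int(c) for c in crop)
    shape = sample.image.shape
    if any(c > s for c, s in zip(crop, shape)):
        if not pad_if_needed:
            raise InvalidInputError(f"crop {crop} exceeds volume shape {shape}")
        pads = [(0, max(0, c - s)) for c, s in zip(crop, shape)]
        image = np.pad(sample.image, pads, mode="reflect")
        label = np.pad(sample.label, pads, mode="reflect") if sample.label is not None else None
        sample = VolumeSample(image, label, sample.spacing, sample.identifier)
        shape = sample.image.shape
    offset = tuple(int(rng.integers(0, s - c + 1)) for c, s in zip(crop, shape))
    sl = tuple(slice(o, o + c) for o, c in zip(offset, crop))
    label = sample.label[sl] if sample.label is not None else None
    return VolumeSample(sample.image[sl], label, sample.spacing, sample.identifier)


def augment(sample: VolumeSample, rng: np.random.Generator,
            policy: str = "random_rot") -> VolumeSample:
    """In-plane rotation / flip augmentation applied identically to image and label."""
    if policy not in AUGMENT_POLICIES:
        raise InvalidConfigError(f"unknown augmentation policy {policy!r}")
    if policy == "none":
        return sample
    if policy == "random_flip":
        ops = [("flip", int(rng.integers(0, 2)))]
    elif policy == "random_rot":
        ops = [("rot", int(rng.integers(0, 4)))]
        if rng.integers(0, 2):
            ops.append(("flip", int(rng.integers(0, 2))))
    else:
        ops = [("rot", {"rot90": 1, "rot180": 2, "rot270": 3}[policy])]

    def apply(a: np.ndarray) -> np.ndarray:
        for kind, k in ops:
            if kind == "rot":
                a = np.rot90(a, k=k, axes=(0, 1))
            else:
                a = np.flip(a, axis=k)
        return np.ascontiguousarray(a)

    label = apply(sample.label) if sample.label is not None else None
    return VolumeSample(apply(sample.image), label, sample.spacing, sample.identifier)


# ---------------------------------------------------------------------------
# Synthetic phantoms


@dataclass
class PhantomSpec:
    """Recipe for one synthetic volume with controllable hard regions.

    The body is a jittered ellipsoid; ``branch_count`` thin curved tubes of
    radius ``branch_radius_voxels`` sprout from its surface (the analogue of
    fine anatomical branches), ``boundary_blur_sigma`` smears the object
    boundary and ``noise_sd`` adds Gaussian noise plus a smooth background
    texture of the same amplitude, so boundary voxels become genuinely
    ambiguous under intensity thresholding.
    """

    size: tuple[int, int, int] = (32, 32, 32)
    branch_count: int = 3
    branch_radius_voxels: float = 1.5
    boundary_blur_sigma: float = 1.0
    noise_sd: float = 0.1
    intensity_contrast: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.size = tuple(int(s) for s in self.size)
        if any(s % 16 for s in self.size):
            raise InvalidConfigError(f"phantom size {self.size} must be divisible by 16")


def _rasterize_tube(label: np.ndarray, points: np.ndarray, radius: float) -> None:
    """Mark voxels within `radius` of the sampled curve points."""
    r = int(np.ceil(radius))
    grid = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    ball = np.argwhere((grid ** 2).sum(axis=0) <= radius ** 2) - r
    shape = np.asarray(label.shape)
    for p in np.unique(np.round(points).astype(int), axis=0):
        vox = p + ball
        keep = np.all((vox >= 0) & (vox < shape), axis=1)  # clip at volume boundary
        v = vox[keep]
        label[v[:, 0], v[:, 1], v[:, 2]] = 1


def generate_phantom(spec: PhantomSpec) -> VolumeSample:
    """Deterministically generate one phantom volume from its spec."""
    rng = np.random.default_rng(spec.seed)
    size = np.asarray(spec.size, dtype=float)
    h, w, d = spec.size
    center = size / 2 + rng.uniform(-0.05, 0.05, 3) * size
    radii = size * rng.uniform(0.22, 0.32, 3)
    hh, ww, dd = np.mgrid[0:h, 0:w, 0:d].astype(np.float32)
    dist2 = (((hh - center[0]) / radii[0]) ** 2
             + ((ww - center[1]) / radii[1]) ** 2
             + ((dd - center[2]) / radii[2]) ** 2)
    label = (dist2 <= 1.0).astype(np.int64)

    for _ in range(spec.branch_count):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start = center + direction * radii * 0.9
        length = float(rng.uniform(0.2, 0.35) * size.min())
        end = start + direction * length
        bend = rng.normal(size=3)
        bend -= bend @ direction * direction
        bend *= rng.uniform(0.1, 0.3) * length / max(np.linalg.norm(bend), 1e-9)
        ctrl = (start + end) / 2 + bend
        t = np.linspace(0, 1, 64)[:, None]
        curve = ((1 - t) ** 2 * start + 2 * t * (1 - t) * ctrl + t ** 2 * end)
        _rasterize_tube(label, curve, spec.branch_radius_voxels)

    image = spec.intensity_contrast * label.astype(np.float32)
    if spec.boundary_blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.boundary_blur_sigma)
    if spec.noise_sd > 0:
        texture = ndimage.gaussian_filter(rng.normal(size=spec.size), 4.0)
        texture *= spec.noise_sd / max(texture.std(), 1e-9)
        image = image + texture + rng.normal(0.0, spec.noise_sd, spec.size)
    return VolumeSample(image.astype(np.float32), label,
                        identifier=f"phantom-{spec.seed}")


@dataclass
class PhantomDataset:
    """Seeded three-way split of generated phantoms.

    ``unlabeled`` samples are image-only views; their ground truth is kept in
    ``unlabeled_truth`` for diagnostics and is never given to the trainer.
    """

    labeled: list[VolumeSample]
    unlabeled: list[VolumeSample]
    test: list[VolumeSample]
    unlabeled_truth: list[VolumeSample] = field(default_factory=list, repr=False)

    def __iter__(self):
        return iter((self.labeled, self.unlabeled, self.test))


def make_phantom_dataset(n: int, labeled_fraction: float, spec: PhantomSpec,
                         seed: int, n_test: int = 4) -> PhantomDataset:
    """Generate ``n`` training phantoms split into labeled/unlabeled, plus a test set."""
    if not 0 < labeled_fraction < 1:
        raise InvalidConfigError(f"labeled_fraction must be in (0,1), got {labeled_fraction}")
    n_labeled = int(n * labeled_fraction)
    if n_labeled < 1:
        raise InvalidConfigError(
            f"n={n} at labeled_fraction={labeled_fraction} leaves no labeled volumes"
        )
    seeds = np.random.SeedSequence(seed).generate_state(n + n_test) % (2 ** 31)
    samples = []
    for i, s in enumerate(seeds):
        sample = generate_phantom(replace(spec, seed=int(s)))
        sample.identifier = f"phantom-{i:03d}"
        samples.append(sample)
    order = np.random.default_rng(seed).permutation(n)
    labeled = [samples[i] for i in order[:n_labeled]]
    unlabeled_full = [samples[i] for i in order[n_labeled:]]
    return PhantomDataset(
        labeled=labeled,
        unlabeled=[s.without_label() for s in unlabeled_full],
        test=samples[n:],
        unlabeled_truth=unlabeled_full,
    )
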