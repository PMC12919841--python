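"""Synthetic stained blood-smear image generation and augmentation.

The generator emulates Giemsa-like single- and multi-cell white-blood-cell
images: a pale, lightly textured background field, a lighter cytoplasm disc
(slightly elliptical, purple/pink palette), and a darker, irregular nucleus
whose boundary is a low-order radial Fourier perturbation and whose interior
carries a smooth chromatin texture.  Classes differ by their morphology
distributions — cell radius, nucleus-to-cell area ratio, boundary
irregularity, chromatin amplitude and stain hue — so label-conditional pixel
statistics are separable by construction.  It is a rendering model, not a
physical cytology simulation: no staining chemistry, no focus/illumination
artifacts, no touching-cell occlusion geometry.

Everything is deterministic under the dataset seed: image ``i`` is drawn
from ``default_rng([seed, i])``, so regeneration does not depend on order.

The augmentation suite mirrors a standard smear-classification recipe:
brightness scaling, horizontal/vertical flips, shifts up to +-0.2 of the
image size, rotation, down-scaling in [0.5, 1] and shearing in [0.1, 0.9],
all size-preserving.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "ClassMorphology", "SyntheticDatasetSpec", "SyntheticDataset",
    "AugmentationSpec", "generate_dataset", "augment", "apply_affine",
    "expand_dataset",
    "hflip", "vflip", "write_dataset", "default_benchmark_spec",
    "multi_cell_spec",
]


@dataclass(frozen=True)
class ClassMorphology:
    """Per-class rendering distributions (radius as a fraction of min(H, W))."""

    name: str
    cell_radius: tuple = (0.20, 0.02)        # (mean, std) fraction
    nucleus_ratio: tuple = (0.50, 0.05)      # nucleus-to-cell area ratio
    irregularity: float = 0.10               # radial boundary perturbation
    chromatin: float = 0.08                  # texture amplitude inside nucleus
    nucleus_hue: tuple = (0.42, 0.28, 0.60)  # dark purple
    cytoplasm_hue: tuple = (0.85, 0.74, 0.90)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Class definitions, geometry, noise model and seed for the generator."""

    classes: tuple                    # tuple of ClassMorphology
    per_class_counts: tuple
    image_size: tuple = (224, 224)
    cells_per_image: tuple = (1, 1)   # inclusive range
    background: tuple = (0.93, 0.91, 0.95)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.classes) != len(self.per_class_counts):
            raise ValueError("per_class_counts must match the number of classes")
        if any(c < 1 for c in self.per_class_counts):
            raise ValueError("per-class counts must be positive")
        if self.cells_per_image[0] < 1 or self.cells_per_image[1] < self.cells_per_image[0]:
            raise ValueError("cells_per_image must be a nonempty positive range")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_images(self) -> int:
        return int(sum(self.per_class_counts))


@dataclass
class SyntheticDataset:
    """Rendered images (uint8 NHWC), integer labels, and cell geometry."""

    images: np.ndarray
    labels: np.ndarray
    spec: SyntheticDatasetSpec
    geometry: list = field(default_factory=list)  # per image: list of (cy, cx, radius)
    provenance: list = field(default_factory=list)  # per image: dict

    def __len__(self):
        return len(self.labels)

    def cell_mask(self, index: int) -> np.ndarray:
        """Boolean union of cell discs for one image, from stored geometry."""
        h, w = self.images.shape[1:3]
        yy, xx = np.mgrid[0:h, 0:w]
        mask = np.zeros((h, w), dtype=bool)
        for cy, cx, r in self.geometry[index]:
            mask |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= r ** 2
        return mask


def default_benchmark_spec(seed: int = 0, image_size=(64, 64),
                           per_class=(500, 500)) -> SyntheticDatasetSpec:
    """Two-class single-cell benchmark: blast-like (large cell, high
    nucleus-to-cell ratio, irregular chromatin-rich nucleus) versus
    mature-lymphocyte-like (smaller cell, compact round nucleus)."""
    blast = ClassMorphology(
        name="blast", cell_radius=(0.28, 0.03), nucleus_ratio=(0.75, 0.05),
        irregularity=0.22, chromatin=0.12,
        nucleus_hue=(0.38, 0.24, 0.58), cytoplasm_hue=(0.82, 0.70, 0.90))
    lymphocyte = ClassMorphology(
        name="lymphocyte", cell_radius=(0.17, 0.02), nucleus_ratio=(0.45, 0.05),
        irregularity=0.06, chromatin=0.05,
        nucleus_hue=(0.46, 0.32, 0.62), cytoplasm_hue=(0.87, 0.77, 0.91))
    return SyntheticDatasetSpec(classes=(blast, lymphocyte),
                                per_class_counts=tuple(per_class),
                                image_size=tuple(image_size), seed=seed)


def multi_cell_spec(seed: int = 0, n_classes: int = 4, per_class: int = 50,
                    image_size=(96, 96)) -> SyntheticDatasetSpec:
    """Multi-cell spec in the style of a bone-marrow field with several WBCs."""
    base = default_benchmark_spec(seed).classes
    classes = []
    for i in range(n_classes):
        proto = base[i % 2]
        classes.append(replace(
            proto, name=f"class{i}",
            cell_radius=(0.12 + 0.04 * i, 0.015),
            nucleus_ratio=(0.40 + 0.12 * (i % 3), 0.05)))
    return SyntheticDatasetSpec(classes=tuple(classes),
                                per_class_counts=(per_class,) * n_classes,
                                image_size=tuple(image_size),
                                cells_per_image=(2, 4), seed=seed)


def _smooth_noise(rng, shape, sigma_px: float) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, size=shape)
    return ndimage.gaussian_filter(noise, sigma=sigma_px)


def _render_image(spec: SyntheticDatasetSpec, morph: ClassMorphology, rng):
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        img[..., c] = spec.background[c]
    img += _smooth_noise(rng, (h, w), 2.0)[..., None] * 0.015
    img += rng.normal(0.0, spec.noise_sigma, size=(h, w, 3))

    n_cells = int(rng.integers(spec.cells_per_image[0], spec.cells_per_image[1] + 1))
    geometry = []
    for _ in range(n_cells):
        radius = max(3.0, rng.normal(*morph.cell_radius) * min(h, w))
        # keep the cell inside the field; retry a few times to avoid overlap
        for _attempt in range(20):
            cy = rng.uniform(radius, h - radius) if h > 2 * radius else h / 2
            cx = rng.uniform(radius, w - radius) if w > 2 * radius else w / 2
            if all((cy - gy) ** 2 + (cx - gx) ** 2 > (0.8 * (radius + gr)) ** 2
                   for gy, gx, gr in geometry):
                break
        geometry.append((cy, cx, radius))

        # cytoplasm: slightly elliptical disc with a soft edge
        ecc = rng.uniform(0.85, 1.0)
        theta0 = rng.uniform(0, math.pi)
        ct, st = math.cos(theta0), math.sin(theta0)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        dist = np.sqrt((xr / radius) ** 2 + (yr / (radius * ecc)) ** 2)
        cyto = np.clip(1.0 - (dist - 0.92) / 0.08, 0.0, 1.0)
        hue = np.asarray(morph.cytoplasm_hue) + rng.normal(0, 0.02, size=3)
        img = img * (1 - cyto[..., None]) + cyto[..., None] * hue

        # nucleus: irregular radial boundary + chromatin texture
        ratio = float(np.clip(rng.normal(*morph.nucleus_ratio), 0.1, 0.95))
        rn = radius * math.sqrt(ratio) * math.sqrt(ecc)
        ang = np.arctan2(yr, xr)
        wobble = np.zeros_like(ang)
        for k in range(2, 6):
            wobble += rng.normal(0, 1) * np.cos(k * ang + rng.uniform(0, 2 * math.pi))
        boundary = rn * (1.0 + morph.irregularity * wobble / 4.0)
        rdist = np.sqrt(xr ** 2 + yr ** 2)
        nuc = np.clip(1.0 - (rdist - boundary) / 1.5, 0.0, 1.0)
        nhue = np.asarray(morph.nucleus_hue) + rng.normal(0, 0.02, size=3)
        chroma = _smooth_noise(rng, (h, w), 1.2) * morph.chromatin
        nuc_col = np.clip(nhue[None, None, :] + chroma[..., None], 0.0, 1.0)
        img = img * (1 - nuc[..., None]) + nuc[..., None] * nuc_col

    img = np.clip(img, 0.0, 1.0)
    return (img * 255.0 + 0.5).astype(np.uint8), geometry


def generate_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Render the full labeled image set for a spec (deterministic by seed)."""
    h, w = spec.image_size
    n = spec.n_images
    images = np.empty((n, h, w, 3), dtype=np.uint8)
    labels = np.empty(n, dtype=np.int64)
    geometry, provenance = [], []
    idx = 0
    for label, count in enumerate(spec.per_class_counts):
        for _ in range(count):
            rng = np.random.default_rng([spec.seed, idx])
            images[idx], geo = _render_image(spec, spec.classes[label], rng)
            labels[idx] = label
            geometry.append(geo)
            provenance.append({"source": "generated", "index": idx, "seed": [spec.seed, idx]})
            idx += 1
    return SyntheticDataset(images=images, labels=labels, spec=spec,
                            geometry=geometry, provenance=provenance)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    """Sampled-transform ranges; zero ranges and cleared flags give identity."""

    brightness: tuple = (0.8, 1.2)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    shift: float = 0.2               # max |shift| as a fraction of the size
    rotation: float = 45.0           # max |rotation| in degrees
    scale: tuple = (0.5, 1.0)
    shear: tuple = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.shift <= 0.5):
            raise ValueError("shift fraction must lie in [0, 0.5]")
        if not (0.0 < self.scale[0] <= self.scale[1] <= 1.0):
            raise ValueError("scale range must be inside (0, 1]")
        if self.brightness[0] > self.brightness[1] or self.brightness[0] < 0:
            raise ValueError("invalid brightness range")
        if self.shear[0] > self.shear[1]:
            raise ValueError("invalid shear range")
        if self.rotation < 0:
            raise ValueError("rotation must be a nonnegative half-range")

    def identity(self) -> bool:
        return (self.brightness == (1.0, 1.0) and not self.horizontal_flip
                and not self.vertical_flip and self.shift == 0.0
                and self.rotation == 0.0 and self.scale == (1.0, 1.0)
                and self.shear == (0.0, 0.0))


IDENTITY_AUGMENTATION = AugmentationSpec(
    brightness=(1.0, 1.0), horizontal_flip=False, vertical_flip=False,
    shift=0.0, rotation=0.0, scale=(1.0, 1.0), shear=(0.0, 0.0))


def hflip(image: np.ndarray) -> np.ndarray:
    return image[:, ::-1].copy()


def vflip(image: np.ndarray) -> np.ndarray:
    return image[::-1].copy()


def apply_affine(image: np.ndarray, scale: float = 1.0, rotation: float = 0.0,
                 shear: float = 0.0, tx: float = 0.0, ty: float = 0.0) -> np.ndarray:
    """Size-preserving affine warp about the image center (rotation in
    radians, translation in pixels); bilinear interpolation, edge padding."""
    h, w = image.shape[:2]
    out = image.astype(np.float64)
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (sktransform.AffineTransform(translation=-center)
          + sktransform.AffineTransform(scale=scale, rotation=rotation, shear=shear)
          + sktransform.AffineTransform(translation=center)
          + sktransform.AffineTransform(translation=(tx, ty)))
    out = sktransform.warp(np.ascontiguousarray(out), tf.inverse,
                           order=1, mode="edge", preserve_range=True)
    return out


def augment(image: np.ndarray, spec: AugmentationSpec, rng=None) -> np.ndarray:
    """One sampled augmentation of an HWC uint8 image; size preserved."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HWC RGB image")
    if spec.identity():
        return image.copy()
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    h, w = image.shape[:2]
    out = image.astype(np.float64) / 255.0

    if spec.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if spec.vertical_flip and rng.random() < 0.5:
        out = out[::-1]

    scale = rng.uniform(*spec.scale)
    rot = math.radians(rng.uniform(-spec.rotation, spec.rotation))
    shear = rng.uniform(*spec.shear) if spec.shear != (0.0, 0.0) else 0.0
    tx = rng.uniform(-spec.shift, spec.shift) * w
    ty = rng.uniform(-spec.shift, spec.shift) * h

    if (scale, rot, shear, tx, ty) != (1.0, 0.0, 0.0, 0.0, 0.0):
        out = apply_affine(out, scale, rot, shear, tx, ty)

    bright = rng.uniform(*spec.brightness)
    out = np.clip(out * bright, 0.0, 1.0)
    return (out * 255.0 + 0.5).astype(np.uint8)


def expand_dataset(dataset: SyntheticDataset, target_n: int,
                   aug_spec: AugmentationSpec) -> SyntheticDataset:
    """Grow a dataset to ``target_n`` images by augmented copies.

    Originals are kept; extra copies are allocated per class in proportion to
    the class shares (largest-remainder rounding) and drawn round-robin over
    each class's originals.  Provenance records the source index and the copy
    seed for every augmented image.
    """
    n = len(dataset)
    if target_n < n:
        raise ValueError("target_n must be >= the current dataset size")
    extra = target_n - n
    labels = dataset.labels
    classes = np.unique(labels)
    shares = np.array([np.sum(labels == c) for c in classes], dtype=float) / n
    alloc = np.floor(shares * extra).astype(int)
    remainder = extra - alloc.sum()
    order = np.argsort(-(shares * extra - alloc))
    for i in range(remainder):
        alloc[order[i % len(classes)]] += 1

    new_images, new_labels, new_geo, new_prov = [], [], [], []
    for ci, c in enumerate(classes):
        src_idx = np.flatnonzero(labels == c)
        for j in range(alloc[ci]):
            src = int(src_idx[j % len(src_idx)])
            rng = np.random.default_rng([aug_spec.seed, int(c), j])
            new_images.append(augment(dataset.images[src], aug_spec, rng))
            new_labels.append(int(c))
            new_geo.append(dataset.geometry[src])
            new_prov.append({"source": "augmented", "source_index": src,
                             "seed": [aug_spec.seed, int(c), j]})

    images = np.concatenate([dataset.images, np.asarray(new_images, dtype=np.uint8)]) \
        if new_images else dataset.images.copy()
    return SyntheticDataset(
        images=images,
        labels=np.concatenate([labels, np.asarray(new_labels, dtype=np.int64)])
        if new_labels else labels.copy(),
        spec=dataset.spec,
        geometry=dataset.geometry + new_geo,
        provenance=dataset.provenance + new_prov)


def write_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """Write class-folder PNG trees plus a manifest CSV; returns the root."""
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    names = [m.name for m in dataset.spec.classes]
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "class", "provenance"])
        for i, (img, label) in enumerate(zip(dataset.images, dataset.labels)):
            cls = names[label]
            cdir = root / cls
            cdir.mkdir(exist_ok=True)
            path = cdir / f"{i:05d}.png"
            Image.fromarray(img).save(path)
            writer.writerow([str(path.relative_to(root)), int(label), cls,
                             repr(dataset.provenance[i])])
    return root
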