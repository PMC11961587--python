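"""Seeded generator of multi-scale, multi-class segmentation scenes.

Scenes emulate the size heterogeneity that motivates multi-scale
attention in medical images: a "large-organ" class of big ellipses and a
"small-lesion" class of tiny ones, placed without overlap on a dark
background, rendered with per-object intensity jitter and additive
Gaussian noise.  In the default spec the organ and lesion classes share
the same intensity distribution, so object *scale and context* — not
brightness — is the only cue separating them: a segmenter must integrate
information over very different receptive fields to label them apart.

Images are quantized to the 8-bit grid at generation time, so the PNG
round trip (`read_dataset(write_dataset(x)) == x`) is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["ClassSpec", "SceneSpec", "SegmentationSample",
           "generate_dataset", "write_dataset", "read_dataset",
           "export_nifti", "PackingError"]


class PackingError(RuntimeError):
    """Raised when the requested objects cannot be placed without overlap."""


@dataclass
class ClassSpec:
    """One foreground class: object count range, size range, appearance."""

    count_range: tuple = (1, 2)
    radius_range: tuple = (12.0, 20.0)   # semi-axis range, pixels
    intensity: float = 0.75
    intensity_jitter: float = 0.08

    def validate(self):
        if self.radius_range[0] < 1:
            raise ValueError("object radii must be >= 1 pixel")
        if self.count_range[0] < 0 or self.count_range[0] > self.count_range[1]:
            raise ValueError(f"bad count range {self.count_range}")


@dataclass
class SceneSpec:
    """Full description of the scene distribution; same seed -> same data."""

    image_size: int = 64
    num_classes: int = 3
    classes: list = field(default_factory=list)   # one ClassSpec per fg class
    background_intensity: float = 0.2
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.classes:
            self.classes = self._default_classes()
        if len(self.classes) != self.num_classes - 1:
            raise ValueError(
                f"{len(self.classes)} class specs for {self.num_classes} "
                f"classes (background takes label 0)")
        for c in self.classes:
            c.validate()

    def _default_classes(self) -> list:
        # radii stated at the 64 px reference size, scaled with the image
        f = self.image_size / 64.0
        organ = ClassSpec(count_range=(1, 2),
                          radius_range=(12.0 * f, 20.0 * f),
                          intensity=0.75)
        lesion = ClassSpec(count_range=(2, 5),
                           radius_range=(max(1.5, 2.0 * f), max(2.5, 4.0 * f)),
                           intensity=0.75)
        defaults = [organ, lesion]
        if self.num_classes - 1 > 2:
            # additional classes interpolate the size spectrum
            for i in range(self.num_classes - 3):
                lo = 5.0 * f + 2 * i
                defaults.append(ClassSpec(count_range=(1, 3),
                                          radius_range=(lo, lo * 1.6),
                                          intensity=0.75))
        return defaults[:self.num_classes - 1]


@dataclass
class SegmentationSample:
    """A rendered scene: image in [0,1] with integer label mask."""

    image: np.ndarray      # float32 [1, H, W]
    mask: np.ndarray       # uint8 [H, W]
    case_id: str = ""


def _ellipse_mask(size: int, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / a
    v = (-x * st + y * ct) / b
    return (u * u + v * v) <= 1.0


def _place_objects(spec: SceneSpec, rng: np.random.Generator):
    """One packing attempt; returns (mask, object list) or None."""
    size = spec.image_size
    mask = np.zeros((size, size), dtype=np.uint8)
    occupied = np.zeros((size, size), dtype=bool)
    objects = []
    for label, cls in enumerate(spec.classes, start=1):
        count = int(rng.integers(cls.count_range[0], cls.count_range[1] + 1))
        for _ in range(count):
            placed = False
            for _ in range(200):
                a = rng.uniform(*cls.radius_range)
                b = rng.uniform(*cls.radius_range)
                theta = rng.uniform(0, np.pi)
                r = max(a, b)
                if 2 * r + 2 >= size:
                    continue
                cy = rng.uniform(r + 1, size - r - 1)
                cx = rng.uniform(r + 1, size - r - 1)
                blob = _ellipse_mask(size, cy, cx, a, b, theta)
                if not blob.any() or (blob & occupied).any():
                    continue
                mask[blob] = label
                occupied |= blob
                objects.append((label, cls, blob))
                placed = True
                break
            if not placed:
                return None
    return mask, objects


def _render_scene(spec: SceneSpec, rng: np.random.Generator,
                  scene_retries: int = 20) -> SegmentationSample:
    for _ in range(scene_retries):
        result = _place_objects(spec, rng)
        if result is not None:
            break
    else:
        raise PackingError(
            f"could not place the requested objects in a "
            f"{spec.image_size}x{spec.image_size} scene after "
            f"{scene_retries} attempts; reduce counts or radii")
    mask, objects = result
    image = np.full(mask.shape, spec.background_intensity, dtype=np.float64)
    for label, cls, blob in objects:
        jitter = rng.uniform(-cls.intensity_jitter, cls.intensity_jitter)
        image[blob] = cls.intensity + jitter
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    image = np.round(image * 255.0) / 255.0          # snap to the 8-bit grid
    return SegmentationSample(image=image[None].astype(np.float32), mask=mask)


def generate_dataset(spec: SceneSpec, n: int) -> list:
    """Generate ``n`` scenes, deterministic in ``(spec.seed, n)``."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(spec.seed)
    samples = []
    for i in range(n):
        sample = _render_scene(spec, rng)
        sample.case_id = f"case_{i:04d}"
        samples.append(sample)
    return samples


def _default_splits(n: int) -> list:
    """70/10/20 train/val/test split by case order."""
    n_train = int(round(0.7 * n))
    n_val = int(round(0.1 * n))
    return (["train"] * n_train + ["val"] * n_val
            + ["test"] * (n - n_train - n_val))


def write_dataset(samples, out_dir, num_classes: int | None = None,
                  splits=None):
    """Write PNG image/mask pairs plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if splits is None:
        splits = _default_splits(len(samples))
    if len(splits) != len(samples):
        raise ValueError("one split per sample required")
    if num_classes is None:
        num_classes = int(max(s.mask.max() for s in samples)) + 1
    cases = []
    for sample, split in zip(samples, splits):
        img8 = np.round(sample.image[0] * 255.0).astype(np.uint8)
        img_name = f"{sample.case_id}_image.png"
        mask_name = f"{sample.case_id}_mask.png"
        Image.fromarray(img8, mode="L").save(out_dir / img_name)
        Image.fromarray(sample.mask.astype(np.uint8), mode="L") \
            .save(out_dir / mask_name)
        cases.append({"id": sample.case_id, "split": split,
                      "image": img_name, "mask": mask_name})
    manifest = {
        "num_classes": num_classes,
        "image_size": int(samples[0].image.shape[-1]),
        "n": len(samples),
        "cases": cases,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_dataset(in_dir, split: str | None = None):
    """Read a dataset written by :func:`write_dataset`.

    Returns ``(samples, manifest)``; ``split`` filters by manifest split.
    """
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    samples = []
    for case in manifest["cases"]:
        if split is not None and case["split"] != split:
            continue
        img_path = in_dir / case["image"]
        mask_path = in_dir / case["mask"]
        if not img_path.exists() or not mask_path.exists():
            raise FileNotFoundError(
                f"manifest lists case {case['id']} but "
                f"{img_path.name} / {mask_path.name} is missing")
        image = np.asarray(Image.open(img_path), dtype=np.float32) / 255.0
        mask = np.asarray(Image.open(mask_path), dtype=np.uint8)
        samples.append(SegmentationSample(image=image[None], mask=mask,
                                          case_id=case["id"]))
    return samples, manifest


def export_nifti(samples, out_path):
    """Stack all scenes into one .nii.gz volume (requires nibabel)."""
    import nibabel as nib
    vol = np.stack([s.image[0] for s in samples], axis=-1)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)),
             str(out_path))
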