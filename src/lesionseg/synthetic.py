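"""Deterministic generator of dermoscopy-like labelled samples.

Real dermoscopic images pair a roughly elliptical pigmented lesion with an
irregular boundary against lighter skin, frequently crossed by dark hairs
and degraded by sensor noise and uneven illumination.  The generator
emulates exactly those ingredients so every other module can be exercised
without downloading data:

* a star-convex lesion: an ellipse whose radius is modulated by seeded
  random angular harmonics, filled into a binary mask;
* pigment contrast: the lesion region is darkened (channel-weighted, so it
  reads brownish) and textured with low-frequency value noise, giving the
  boundary a high-frequency cue;
* distractors: anti-aliased curvilinear hair strokes drawn over the image
  but never into the mask;
* global nuisance: a linear illumination gradient and additive Gaussian
  pixel noise.

Everything is driven by ``numpy.random.default_rng(seed)`` with a
counter-based seeding scheme (sample ``i`` of a dataset uses ``seed + i``),
so a (params, seed) pair reproduces a dataset bit-identically on any
platform.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "SceneParams",
    "LabeledSample",
    "GenerationError",
    "generate_sample",
    "generate_split",
    "augment",
    "save_dataset",
]


class GenerationError(RuntimeError):
    """Raised when a sample cannot satisfy its area constraint."""


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic scene.

    ``lesion_area_fraction`` is the closed interval the mask's foreground
    fraction must fall into; ``boundary_harmonics``/``boundary_amplitude``
    control how irregular the lesion outline is; ``lesion_contrast`` is the
    mean intensity drop inside the lesion; ``hair_count`` dark strokes of
    width ``hair_width_px`` are drawn over (not into) the mask;
    ``noise_sd`` is the additive Gaussian noise level and
    ``background_gradient`` the peak-to-peak illumination ramp.
    """

    image_size: tuple[int, int] = (128, 128)
    lesion_area_fraction: tuple[float, float] = (0.08, 0.40)
    boundary_harmonics: int = 6
    boundary_amplitude: float = 0.12
    lesion_contrast: float = 0.35
    hair_count: int = 5
    hair_width_px: float = 1.5
    noise_sd: float = 0.02
    background_gradient: float = 0.08

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        if rows < 16 or cols < 16:
            raise ValueError("image_size must be at least 16x16")
        lo, hi = self.lesion_area_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("lesion_area_fraction must be an interval inside (0,1)")
        for name in ("boundary_amplitude", "lesion_contrast", "hair_width_px",
                     "noise_sd", "background_gradient"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.boundary_harmonics < 0 or self.hair_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class LabeledSample:
    """An RGB image in [0,1], shape (3, rows, cols), with its binary mask."""

    image: np.ndarray
    mask: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError("image must be (3, rows, cols)")
        if self.mask.shape != self.image.shape[1:]:
            raise ValueError("mask spatial dims must equal the image's")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be strictly binary")


def _low_freq_noise(rng: np.random.Generator, shape: tuple[int, int],
                    grid: int, amplitude: float) -> np.ndarray:
    """Smooth value noise: a coarse Gaussian grid bilinearly blown up."""
    coarse = rng.normal(0.0, 1.0, size=(grid, grid))
    zoom = (shape[0] / grid, shape[1] / grid)
    return amplitude * ndimage.zoom(coarse, zoom, order=1, grid_mode=True,
                                    mode="nearest")


def _lesion_mask(rng: np.random.Generator, params: SceneParams) -> np.ndarray:
    """Star-convex mask whose area fraction lies inside the configured band."""
    rows, cols = params.image_size
    lo, hi = params.lesion_area_fraction
    target = rng.uniform(lo, hi)

    cy = rows * (0.5 + rng.uniform(-0.08, 0.08))
    cx = cols * (0.5 + rng.uniform(-0.08, 0.08))
    aspect = rng.uniform(0.7, 1.3)
    tilt = rng.uniform(0.0, np.pi)

    nh = params.boundary_harmonics
    if nh > 0:
        sd = params.boundary_amplitude / np.sqrt(nh)
        cos_amp = rng.normal(0.0, sd, size=nh)
        sin_amp = rng.normal(0.0, sd, size=nh)
        orders = np.arange(2, nh + 2)
    else:
        cos_amp = sin_amp = orders = np.zeros(0)

    yy, xx = np.mgrid[0:rows, 0:cols]
    u = (xx - cx) * np.cos(tilt) + (yy - cy) * np.sin(tilt)
    v = -(xx - cx) * np.sin(tilt) + (yy - cy) * np.cos(tilt)

    r0 = np.sqrt(target * rows * cols / np.pi)
    a, b = r0 * np.sqrt(aspect), r0 / np.sqrt(aspect)
    theta = np.arctan2(v / b, u / a)
    modulation = np.ones_like(theta)
    for k, ca, sa in zip(orders, cos_amp, sin_amp):
        modulation += ca * np.cos(k * theta) + sa * np.sin(k * theta)
    modulation = np.maximum(modulation, 0.2)

    scale = 1.0
    for _ in range(12):
        rho = np.sqrt((u / (a * scale)) ** 2 + (v / (b * scale)) ** 2)
        mask = (rho <= modulation).astype(np.uint8)
        frac = mask.mean()
        if lo <= frac <= hi:
            return mask
        if frac <= 0:
            scale *= 1.5
            continue
        scale *= np.sqrt(target / frac)
    raise GenerationError(
        f"could not reach area fraction in [{lo}, {hi}] (last fraction {frac:.4f})")


def _draw_hairs(rng: np.random.Generator, image: np.ndarray,
                params: SceneParams) -> None:
    """Blend dark quadratic-Bezier strokes into `image` (in place)."""
    rows, cols = image.shape[1:]
    n_pts = 2 * max(rows, cols)
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    yy, xx = np.mgrid[0:rows, 0:cols]
    for _ in range(params.hair_count):
        p0 = rng.uniform([0, 0], [rows, cols])
        p2 = rng.uniform([0, 0], [rows, cols])
        mid = (p0 + p2) / 2 + rng.uniform(-0.4, 0.4, size=2) * [rows, cols]
        curve = ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * mid + t ** 2 * p2
        d2 = np.min(
            (yy[None] - curve[:, 0, None, None]) ** 2
            + (xx[None] - curve[:, 1, None, None]) ** 2,
            axis=0,
        )
        alpha = np.clip(1.0 + params.hair_width_px / 2.0 - np.sqrt(d2), 0.0, 1.0)
        alpha *= rng.uniform(0.5, 0.85)
        shade = rng.uniform(0.05, 0.2)
        image *= 1.0 - alpha[None]
        image += shade * alpha[None]


def generate_sample(params: SceneParams, seed: int) -> LabeledSample:
    """One seeded image/mask pair; identical (params, seed) -> identical bits."""
    rng = np.random.default_rng(seed)
    rows, cols = params.image_size

    # background: light skin tone + linear illumination ramp + smooth mottle
    base = np.array([0.80, 0.62, 0.52]) + rng.uniform(-0.05, 0.05, size=3)
    image = np.broadcast_to(base[:, None, None], (3, rows, cols)).copy()
    direction = rng.uniform(0.0, 2 * np.pi)
    yy, xx = np.mgrid[0:rows, 0:cols]
    ramp = (np.cos(direction) * xx / cols + np.sin(direction) * yy / rows)
    image += params.background_gradient * (ramp - ramp.mean())[None]
    image += _low_freq_noise(rng, (rows, cols), 8, 0.02)[None]

    mask = _lesion_mask(rng, params)

    # pigment: channel-weighted darkening + low-frequency texture inside
    channel_weight = np.array([1.0, 1.1, 1.2]) * params.lesion_contrast
    image -= channel_weight[:, None, None] * mask[None]
    texture = _low_freq_noise(rng, (rows, cols), 16, 0.05)
    image += (texture * mask)[None]

    if params.hair_count:
        _draw_hairs(rng, image, params)

    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)

    meta = asdict(params)
    meta["seed"] = int(seed)
    return LabeledSample(image=image, mask=mask, meta=meta)


def generate_split(params: SceneParams, n: int, seed: int
                   ) -> tuple[list[LabeledSample], list[LabeledSample],
                              list[LabeledSample], list[dict]]:
    """Seeded train/val/test datasets in a 7:2:1 ratio.

    Sample ``i`` uses seed ``seed + i``; the first round(0.7 n) go to the
    training set, the next round(0.2 n) to validation, the remainder to
    test.  Returns the three lists plus a manifest recording the
    assignment.
    """
    if n < 10:
        raise ValueError("need at least 10 samples to honour the 7:2:1 split")
    n_train = round(0.7 * n)
    n_val = round(0.2 * n)
    splits = (["train"] * n_train + ["val"] * n_val
              + ["test"] * (n - n_train - n_val))
    sets: dict[str, list[LabeledSample]] = {"train": [], "val": [], "test": []}
    manifest: list[dict] = []
    for i, split in enumerate(splits):
        sample = generate_sample(params, seed + i)
        sets[split].append(sample)
        manifest.append({
            "index": i,
            "split": split,
            "seed": seed + i,
            "area_fraction": float(sample.mask.mean()),
        })
    return sets["train"], sets["val"], sets["test"], manifest


def augment(sample: LabeledSample, seed: int, *, max_angle_deg: float = 30.0,
            noise_sd: float = 0.01) -> LabeledSample:
    """Seeded random rotation (image and mask together) plus image noise.

    The mask is rotated with bilinear interpolation and re-binarised at
    0.5; noise touches the image only.  ``max_angle_deg=0`` with
    ``noise_sd=0`` is the identity.
    """
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-max_angle_deg, max_angle_deg) if max_angle_deg else 0.0
    image, mask = sample.image, sample.mask
    if angle != 0.0:
        image = np.stack([
            ndimage.rotate(ch, angle, reshape=False, order=1, mode="nearest")
            for ch in image])
        mask = (ndimage.rotate(mask.astype(float), angle, reshape=False,
                               order=1, mode="constant") >= 0.5).astype(np.uint8)
    else:
        image = image.copy()
        mask = mask.copy()
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    meta = dict(sample.meta)
    meta.update({"augment_seed": int(seed), "augment_angle_deg": float(angle),
                 "augment_noise_sd": float(noise_sd)})
    return LabeledSample(image=image, mask=mask, meta=meta)


def save_dataset(samples_by_split: dict[str, list[LabeledSample]],
                 out_dir) -> Path:
    """Write PNG image/mask pairs plus a CSV manifest; returns the manifest
    path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "mask_path", "split", "seed", "area_fraction"])
        counter = 0
        for split, samples in samples_by_split.items():
            for sample in samples:
                stem = f"sample_{counter:04d}"
                img_path = out_dir / f"{stem}.png"
                mask_path = out_dir / f"{stem}_mask.png"
                rgb = np.round(sample.image * 255).astype(np.uint8).transpose(1, 2, 0)
                iio.imwrite(img_path, rgb)
                iio.imwrite(mask_path, (sample.mask * 255).astype(np.uint8))
                writer.writerow([img_path.name, mask_path.name, split,
                                 sample.meta.get("seed", ""),
                                 f"{sample.mask.mean():.6f}"])
                counter += 1
    return manifest_path
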