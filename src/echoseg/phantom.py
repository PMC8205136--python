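"""Synthetic ultrasound-like phantoms with labelled benign/malignant lesions.

Real breast-ultrasound lesions are hypoechoic (darker than surrounding
tissue), sit on a speckled background, and differ morphologically: benign
masses tend to be smooth, roughly elliptical, with blurred margins, while
malignant masses are irregular with internal bright (hyperechoic) spots.
The generator emulates exactly those cues on a mid-grey background with
correlated multiplicative speckle, and returns pixel-exact ordinary label
maps derived from the rendered lesion footprints.  It makes no claim of
acoustic fidelity — there is no point-spread-function or attenuation model —
and exists so the whole training/evaluation pipeline can be exercised and
tested without clinical data.

Geometric augmentation (flips, small rotations, translations, zooms) applies
one identical transform to the image and its mask, with nearest-neighbour
interpolation on the mask so labels stay in {0, 1, 2}.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import ndimage
from skimage import draw

from . import labels as _labels

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset", "augment",
           "apply_transform"]

_BACKGROUND_LEVEL = 0.55
_BENIGN_LEVEL = 0.20
_MALIGNANT_LEVEL = 0.14
_BRIGHT_SPOT_LEVEL = 0.85


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of a synthetic phantom set.

    Defaults: 64 images at 64x64 with an ~88.5% benign fraction (the
    approximate benign:malignant imbalance of clinical breast-ultrasound
    series), moderate speckle, and lesion radii of 8–16 pixels.
    """

    image_size: tuple[int, int] = (64, 64)
    n_images: int = 64
    benign_fraction: float = 0.885
    speckle_strength: float = 0.25
    lesion_size_range: tuple[int, int] = (8, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.benign_fraction <= 1.0:
            raise ValueError("benign_fraction must be in [0, 1]")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be >= 0")
        lo, hi = self.lesion_size_range
        if not 1 <= lo <= hi:
            raise ValueError("lesion_size_range must satisfy 1 <= lo <= hi")
        h, w = self.image_size
        if 2 * hi + 2 >= min(h, w):
            raise ValueError(
                f"largest lesion (diameter {2 * hi}) does not fit in a "
                f"{h}x{w} image with a margin")


def _lesion_center(rng: np.random.Generator, shape: tuple[int, int],
                   radius: float) -> tuple[float, float]:
    h, w = shape
    margin = radius + 1
    return (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))


def _render_benign(rng: np.random.Generator, echo: np.ndarray,
                   mask: np.ndarray, radius: float) -> None:
    cy, cx = _lesion_center(rng, echo.shape, radius)
    r_minor = radius * rng.uniform(0.6, 0.9)
    rot = rng.uniform(0, np.pi)
    rr, cc = draw.ellipse(cy, cx, radius, r_minor, shape=echo.shape,
                          rotation=rot)
    echo[rr, cc] = _BENIGN_LEVEL
    mask[rr, cc] = 1


def _render_malignant(rng: np.random.Generator, echo: np.ndarray,
                      mask: np.ndarray, radius: float) -> None:
    cy, cx = _lesion_center(rng, echo.shape, radius)
    n_vertices = rng.integers(8, 14)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = radius * rng.uniform(0.55, 1.0, n_vertices)
    rr, cc = draw.polygon(cy + radii * np.sin(angles),
                          cx + radii * np.cos(angles), shape=echo.shape)
    echo[rr, cc] = _MALIGNANT_LEVEL
    mask[rr, cc] = 2
    # internal hyperechoic spots, a malignancy cue the decoder must preserve
    inside = np.stack([rr, cc], axis=1)
    if len(inside):
        for _ in range(int(rng.integers(2, 5))):
            sy, sx = inside[rng.integers(len(inside))]
            sr, sc = draw.disk((sy, sx), rng.uniform(1.0, 2.0),
                               shape=echo.shape)
            keep = mask[sr, sc] == 2
            echo[sr[keep], sc[keep]] = _BRIGHT_SPOT_LEVEL


def generate_phantom(cfg: PhantomConfig) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield ``cfg.n_images`` seeded (image, ordinary-mask) pairs.

    Images are uint8 greyscale; masks are uint8 with values in {0, 1, 2}.
    Regeneration with the same config is bit-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    lo, hi = cfg.lesion_size_range
    for _ in range(cfg.n_images):
        echo = np.full((h, w), _BACKGROUND_LEVEL)
        mask = np.zeros((h, w), dtype=np.uint8)
        radius = rng.uniform(lo, hi)
        benign = rng.random() < cfg.benign_fraction
        if benign:
            _render_benign(rng, echo, mask, radius)
            echo = ndimage.gaussian_filter(echo, sigma=1.5)  # blurred margin
        else:
            _render_malignant(rng, echo, mask, radius)
            echo = ndimage.gaussian_filter(echo, sigma=0.8)
        if cfg.speckle_strength > 0:
            k = 1.0 / cfg.speckle_strength ** 2
            speckle = rng.gamma(shape=k, scale=1.0 / k, size=(h, w))
            speckle = ndimage.gaussian_filter(speckle, sigma=0.7)
            echo = echo * speckle
        img = np.clip(echo, 0.0, 1.0)
        yield (np.rint(img * 255).astype(np.uint8), mask)


def generate_dataset(cfg: PhantomConfig, out_dir, augment_factor: int = 0) -> list[dict]:
    """Write paired ``img_####.png`` / ``msk_####.png`` files plus a manifest.

    ``augment_factor`` extra geometrically augmented copies are written per
    phantom.  Returns the manifest rows (filename stem, class content, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2 ** 31))
    rows = []
    idx = 0

    def emit(img: np.ndarray, mask: np.ndarray, origin: str) -> None:
        nonlocal idx
        stem = f"{idx:04d}"
        import imageio.v3 as iio

        iio.imwrite(out / f"img_{stem}.png", img)
        _labels.write_mask(out / f"msk_{stem}.png", mask)
        present = sorted(int(v) for v in np.unique(mask) if v > 0)
        content = {(): "normal", (1,): "benign", (2,): "malignant",
                   (1, 2): "benign+malignant"}[tuple(present)]
        rows.append({"stem": stem, "content": content, "origin": origin,
                     "seed": cfg.seed})
        idx += 1

    for i, (img, mask) in enumerate(generate_phantom(cfg)):
        emit(img, mask, origin=f"phantom_{i}")
        for j in range(augment_factor):
            aug_img, aug_mask = augment(img, mask, rng=rng)
            emit(aug_img, aug_mask, origin=f"phantom_{i}_aug{j}")

    with open(out / "manifest.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["stem", "content", "origin", "seed"],
                                delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    return rows


def _affine_params(rng: np.random.Generator, shape: tuple[int, int],
                   max_rotation: float, max_translation: float,
                   zoom_range: tuple[float, float]) -> tuple:
    angle = np.deg2rad(rng.uniform(-max_rotation, max_rotation))
    zoom = rng.uniform(*zoom_range)
    h, w = shape
    ty = rng.uniform(-max_translation, max_translation) * h
    tx = rng.uniform(-max_translation, max_translation) * w
    flip_h = bool(rng.random() < 0.5)
    flip_v = bool(rng.random() < 0.5)
    return angle, zoom, ty, tx, flip_h, flip_v


def apply_transform(image: np.ndarray, mask: np.ndarray, *,
                    flip_h: bool = False, flip_v: bool = False,
                    angle_deg: float = 0.0, ty: float = 0.0, tx: float = 0.0,
                    zoom: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Apply one explicit geometric transform identically to image and mask.

    Flips are applied first, then a rotation of ``angle_deg`` about the image
    centre, a zoom, and a translation of (``ty``, ``tx``) pixels.  The image
    is interpolated bilinearly with reflected borders; the mask uses
    nearest-neighbour so labels stay in {0, 1, 2}.  The default arguments are
    the identity transform.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if flip_h:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if flip_v:
        image, mask = image[::-1, :], mask[::-1, :]
    angle = np.deg2rad(angle_deg)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]]) / zoom  # output -> input mapping
    center = (np.asarray(image.shape) - 1) / 2.0
    offset = center - rot @ (center + np.array([ty, tx]))
    img_out = ndimage.affine_transform(image.astype(float), rot, offset=offset,
                                       order=1, mode="reflect")
    msk_out = ndimage.affine_transform(mask, rot, offset=offset,
                                       order=0, mode="constant", cval=0)
    img_out = np.clip(np.rint(img_out), 0, 255).astype(image.dtype)
    return img_out, msk_out.astype(mask.dtype)


def augment(image: np.ndarray, mask: np.ndarray,
            rng: np.random.Generator | int | None = None, *,
            max_rotation: float = 15.0, max_translation: float = 0.10,
            zoom_range: tuple[float, float] = (0.9, 1.1)) -> tuple[np.ndarray, np.ndarray]:
    """Apply one randomly sampled geometric transform to an image/mask pair.

    The transform combines horizontal/vertical flips, a rotation of up to
    ±``max_rotation`` degrees, a translation of up to ±``max_translation`` of
    each side, and a zoom in ``zoom_range``; see :func:`apply_transform`.
    """
    image = np.asarray(image)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    angle, zoom, ty, tx, flip_h, flip_v = _affine_params(
        rng, image.shape, max_rotation, max_translation, zoom_range)
    return apply_transform(image, mask, flip_h=flip_h, flip_v=flip_v,
                           angle_deg=np.rad2deg(angle), ty=ty, tx=tx, zoom=zoom)
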