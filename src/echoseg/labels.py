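"""Conversions between ordinary class masks and grey-level probability labels.

The three tissue classes of a breast-ultrasound mask are encoded three ways:

==============  ==============  =======================  =======================
Class           Ordinary label  Three-channel grey       Grey-level probability
==============  ==============  =======================  =======================
Normal tissue   0               (0, 0, 0)                (0.0, 0.0, 0.0)
Benign          1               (127.5, 127.5, 127.5)    (0.5, 0.5, 0.5)
Malignant       2               (255, 255, 255)          (1.0, 1.0, 1.0)
==============  ==============  =======================  =======================

Grey values are normalized by 255 so that 127.5 maps exactly to 0.5.  On disk,
masks are stored as single-channel 8-bit PNGs holding the ordinary labels
{0, 1, 2} (127.5 is not representable in 8 bits); the 0.5/127.5 encodings are
produced in memory only.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GREY_LEVELS",
    "PROBABILITY_LEVELS",
    "ordinary_to_grey",
    "ordinary_to_grey_probability",
    "grey_probability_to_ordinary",
    "prediction_to_grey_map",
    "read_mask",
    "write_mask",
    "read_image",
    "write_grey_png",
]

#: Per-class grey value of the three-channel grey label (8-bit scale).
GREY_LEVELS = np.array([0.0, 127.5, 255.0])

#: Per-class grey-level probability (grey value / 255).
PROBABILITY_LEVELS = np.array([0.0, 0.5, 1.0])

_CLASSES = (0, 1, 2)


def _validate_ordinary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"ordinary label map must be 2-D, got shape {mask.shape}")
    bad = ~np.isin(mask, _CLASSES)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid class value {mask[r, c]!r} at pixel (row={r}, col={c}); "
            f"ordinary labels must be in {{0, 1, 2}}")
    return mask.astype(np.int64)


def ordinary_to_grey_probability(mask: np.ndarray) -> np.ndarray:
    """Expand an (H, W) class mask to the (H, W, 3) grey-level probability label.

    Class 0 -> (0, 0, 0); class 1 -> (0.5, 0.5, 0.5); class 2 -> (1, 1, 1).
    """
    mask = _validate_ordinary(mask)
    return np.repeat(PROBABILITY_LEVELS[mask][..., None], 3, axis=-1)


def ordinary_to_grey(mask: np.ndarray) -> np.ndarray:
    """Expand an (H, W) class mask to the (H, W, 3) grey label (0/127.5/255)."""
    mask = _validate_ordinary(mask)
    return np.repeat(GREY_LEVELS[mask][..., None], 3, axis=-1)


def _validate_three_channel(label: np.ndarray, name: str) -> np.ndarray:
    label = np.asarray(label, dtype=float)
    if label.ndim != 3 or label.shape[-1] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {label.shape}")
    if not (label[..., 0] == label[..., 1]).all() or not (
            label[..., 0] == label[..., 2]).all():
        bad = np.argwhere((label[..., 0] != label[..., 1])
                          | (label[..., 0] != label[..., 2]))[0]
        raise ValueError(
            f"{name} channels differ at pixel (row={bad[0]}, col={bad[1]}): "
            f"{tuple(label[bad[0], bad[1]])}")
    return label


def grey_probability_to_ordinary(label: np.ndarray) -> np.ndarray:
    """Invert :func:`ordinary_to_grey_probability` exactly."""
    label = _validate_three_channel(label, "grey-level probability label")
    chan = label[..., 0]
    mask = np.full(chan.shape, -1, dtype=np.int64)
    for cls, level in zip(_CLASSES, PROBABILITY_LEVELS):
        mask[chan == level] = cls
    if (mask < 0).any():
        r, c = np.argwhere(mask < 0)[0]
        raise ValueError(
            f"invalid probability value {chan[r, c]!r} at pixel (row={r}, col={c}); "
            f"expected one of {{0.0, 0.5, 1.0}}")
    return mask


def prediction_to_grey_map(pred: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) prediction map to a grey image on the 0–255 scale.

    The displayed grey value of a pixel is the mean of its three channel
    probabilities times 255 — the convention under which a uniform benign
    optimum (1/3, 1/3, 1/3) lands at grey 85, inside the expected benign band.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.ndim != 3 or pred.shape[-1] != 3:
        raise ValueError(f"prediction map must have shape (H, W, 3), got {pred.shape}")
    if pred.min() < -1e-12 or pred.max() > 1 + 1e-12:
        raise ValueError(
            f"prediction channels must lie in [0, 1]; got range "
            f"[{pred.min():.4g}, {pred.max():.4g}]")
    return pred.mean(axis=-1) * 255.0


# -- PNG input/output ------------------------------------------------------

def read_mask(path, remap: bool = False) -> np.ndarray:
    """Read an 8-bit single-channel mask PNG with ordinary labels {0, 1, 2}.

    With ``remap=True``, masks stored at display levels {0, 128, 255} are
    remapped to {0, 1, 2} first.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if remap:
        out = np.full(arr.shape, -1, dtype=np.int64)
        for cls, level in ((0, 0), (1, 128), (2, 255)):
            out[arr == level] = cls
        if (out < 0).any():
            r, c = np.argwhere(out < 0)[0]
            raise ValueError(
                f"mask {path} value {arr[r, c]} at (row={r}, col={c}) is not in "
                f"{{0, 128, 255}}; cannot remap")
        arr = out
    return _validate_ordinary(arr)


def write_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, _validate_ordinary(mask).astype(np.uint8))


def read_image(path) -> np.ndarray:
    """Read an 8-bit greyscale image as floats in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(float) / 255.0


def write_grey_png(path, grey: np.ndarray) -> None:
    """Write a grey map on the 0–255 scale as an 8-bit PNG (rounded)."""
    import imageio.v3 as iio

    grey = np.asarray(grey, dtype=float)
    if grey.min() < -1e-9 or grey.max() > 255 + 1e-9:
        raise ValueError("grey values must lie in [0, 255]")
    iio.imwrite(path, np.clip(np.rint(grey), 0, 255).astype(np.uint8))
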