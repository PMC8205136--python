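"""Grey-mass Dice/IOU evaluation of grey-level output maps.

A trained network that predicts grey-level probability labels emits a grey
map, not a hard mask, so overlap metrics are computed on *grey mass* rather
than on pixel sets.  For one class on one image:

* ``x_t`` — total ground-truth grey mass: the encoding grey level of the
  class (127.5 benign, 255 malignant) summed over the true region;
* ``x_p`` — predicted grey mass: the sum of grey values over the pixels of
  the output map whose grey falls in the class's expected band;
* ``alpha`` — the grey reduction rate relating the two (benign ≈ 0.667
  because a softmax head places the benign optimum at grey 85 = 0.667x127.5;
  malignant 1.0);
* ``delta_x = alpha * x_t - x_p`` — the grey-mass discrepancy.

The scalar analogues of the Dice and IOU coefficients are then, with
m = min(alpha*x_t, x_p) and M = max(alpha*x_t, x_p),

    dice = 2m / (alpha*x_t + x_p),        iou = m / M,

the unique scalar reading of the coefficients' geometric meaning that keeps
dice = 2*iou / (1 + iou).  Classical set-overlap Dice/IOU are provided for
comparison.

The per-class grey tolerance ``delta`` is the per-pixel deviation that
generates the expected bands: benign 85 ± 5 -> (80, 90); malignant
255 - 85 -> (170, 255).  Band membership is half-open, ``lo < g <= hi``, so
the exact malignant ground-truth grey 255 is counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .labels import GREY_LEVELS

__all__ = [
    "ClassGreyModel",
    "BENIGN_MODEL",
    "MALIGNANT_MODEL",
    "CLASS_MODELS",
    "GreyOverlapReport",
    "grey_histogram",
    "extract_class_region",
    "mass_dice_iou",
    "grey_dice_iou",
    "classical_dice_iou",
    "render_expected_grey",
]


@dataclass(frozen=True)
class ClassGreyModel:
    """Per-class constants used by grey-mass evaluation."""

    class_id: int                 #: ordinary label (1 benign, 2 malignant)
    name: str
    alpha: float                  #: grey reduction rate
    delta: float                  #: per-pixel grey tolerance
    band: tuple[float, float]     #: accepted grey interval (lo, hi]

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        lo, hi = self.band
        if not (0.0 <= lo < hi <= 255.0):
            raise ValueError("band must be an interval within [0, 255]")

    @property
    def truth_grey(self) -> float:
        """Ground-truth grey level of this class (label-encoding scale)."""
        return float(GREY_LEVELS[self.class_id])


BENIGN_MODEL = ClassGreyModel(class_id=1, name="benign", alpha=85.0 / 127.5,
                              delta=5.0, band=(80.0, 90.0))
MALIGNANT_MODEL = ClassGreyModel(class_id=2, name="malignant", alpha=1.0,
                                 delta=85.0, band=(170.0, 255.0))
CLASS_MODELS = {1: BENIGN_MODEL, 2: MALIGNANT_MODEL}


@dataclass(frozen=True)
class GreyOverlapReport:
    """Grey-mass comparison of one class on one image."""

    class_id: int
    x_t: float               #: ground-truth grey mass
    x_p: float               #: predicted grey mass within the class band
    delta_x: float           #: alpha * x_t - x_p
    dice: float
    iou: float
    within_tolerance: bool   #: Δx inside the class's tolerance interval


def _validate_grey(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"grey map must be 2-D, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("grey map is empty")
    if img.min() < 0 or img.max() > 255:
        raise ValueError(
            f"grey values must lie in [0, 255]; got range "
            f"[{img.min():.4g}, {img.max():.4g}]")
    return img


def grey_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin grey histogram; bin i counts values in [i, i+1) (255 included)."""
    img = _validate_grey(img)
    counts, _ = np.histogram(img, bins=256, range=(0.0, 256.0))
    return counts


def extract_class_region(img: np.ndarray,
                         model: ClassGreyModel) -> tuple[np.ndarray, float]:
    """Pixels of a grey map inside the class band, and their grey mass x_p."""
    img = _validate_grey(img)
    lo, hi = model.band
    mask = (img > lo) & (img <= hi)
    return mask, float(img[mask].sum())


def mass_dice_iou(target_mass: float, predicted_mass: float) -> tuple[float, float]:
    """Scalar grey-mass Dice/IOU of two non-negative masses.

    With m = min and M = max of the two masses, dice = 2m / (sum) and
    iou = m / M — symmetric in the two arguments and tied by
    dice = 2*iou / (1 + iou).
    """
    if target_mass < 0 or predicted_mass < 0:
        raise ValueError("grey masses must be non-negative")
    total = target_mass + predicted_mass
    if total == 0:
        return 1.0, 1.0
    m = min(target_mass, predicted_mass)
    return 2.0 * m / total, m / max(target_mass, predicted_mass)


def grey_dice_iou(truth_mask: np.ndarray, pred_grey: np.ndarray,
                  model: ClassGreyModel) -> GreyOverlapReport:
    """Grey-mass Dice/IOU of one class.

    ``truth_mask`` is the ordinary (H, W) class mask; the ground-truth grey
    mass uses the class's encoding grey level over its true region.  ``pred_grey``
    is the 2-D grey output map on the 0–255 scale.
    """
    truth_mask = np.asarray(truth_mask)
    if truth_mask.shape != np.asarray(pred_grey).shape:
        raise ValueError(
            f"truth shape {truth_mask.shape} does not match prediction shape "
            f"{np.asarray(pred_grey).shape}")
    n_true = int((truth_mask == model.class_id).sum())
    x_t = model.truth_grey * n_true
    _, x_p = extract_class_region(pred_grey, model)
    target = model.alpha * x_t
    delta_x = target - x_p

    if x_t == 0.0:
        warnings.warn(
            f"no {model.name} tissue in the ground truth; grey-mass scores are "
            f"degenerate", stacklevel=2)
        score = 1.0 if x_p == 0.0 else 0.0
        return GreyOverlapReport(model.class_id, x_t, x_p, delta_x,
                                 dice=score, iou=score,
                                 within_tolerance=x_p == 0.0)

    dice, iou = mass_dice_iou(target, x_p)
    if target > 0 and x_p == 0.0:
        dice = iou = 0.0  # total miss, not the two-empty-masses convention
    # tolerance interval scaled by the size of the true region (delta is a
    # per-pixel grey tolerance)
    bound = model.delta * n_true
    if model.class_id == 2:
        ok = 0.0 <= delta_x <= bound
    else:
        ok = abs(delta_x) <= bound
    return GreyOverlapReport(model.class_id, x_t, x_p, delta_x,
                             dice=float(dice), iou=float(iou),
                             within_tolerance=bool(ok))


def render_expected_grey(mask: np.ndarray) -> np.ndarray:
    """Grey map an ideal grey-level prediction would produce for a mask.

    Each lesion class is rendered at its expected output grey — the class's
    ground-truth grey level times its grey reduction rate (benign
    0.667 x 127.5 = 85, malignant 1.0 x 255 = 255) — and normal tissue at 0.
    Evaluating this map against its own mask gives grey-mass Dice/IOU of 1.
    """
    mask = np.asarray(mask)
    out = np.zeros(mask.shape, dtype=float)
    for class_id, model in CLASS_MODELS.items():
        out[mask == class_id] = model.alpha * model.truth_grey
    return out


def classical_dice_iou(truth_mask: np.ndarray,
                       pred_mask: np.ndarray) -> tuple[float, float]:
    """Set-overlap Dice = 2|A∩B|/(|A|+|B|) and IOU = |A∩B|/|A∪B|."""
    a = np.asarray(truth_mask).astype(bool)
    b = np.asarray(pred_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    sa, sb = a.sum(), b.sum()
    if sa == 0 and sb == 0:
        warnings.warn("both masks are empty; Dice/IOU defined as 1.0",
                      stacklevel=2)
        return 1.0, 1.0
    union = sa + sb - inter
    return float(2.0 * inter / (sa + sb)), float(inter / union)
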