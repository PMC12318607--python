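"""Reproducible patch quantification: darkness and three-class pixel counts.

Replaces the original manual magic-wand workflow with a deterministic
per-pixel decision rule:

* darkness — convert to grayscale with Rec. 601 luma weights and average
  ``1 - luminance / 255`` over the patch, so 0 is white and 1 is black;
* classification — in HSV space, a pixel is **black** if its value
  (brightness) is at most `v_max`; otherwise **yellow** if its hue falls
  in the yellow band and its saturation is at least `s_min`; otherwise
  **clear**.  The black rule is checked first: dark yellows count as
  black, as melanin overlying a xanthophore reads as dark.

All thresholds are config-exposed; defaults mirror the visual criteria
(dark melanophores, chromatic yellow xanthophores, pale background).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2hsv

__all__ = [
    "ClassifierConfig",
    "crop_patch",
    "compute_darkness",
    "classify_pixels",
    "quantify_batch",
    "load_image",
]

REC601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the HSV pixel-classification rule.

    `v_max` — maximum HSV value for the black (melanophore) class;
    `hue_range_deg` — hue band for yellow, in degrees on [0, 360);
    `s_min` — minimum saturation for yellow;
    `gray_weights` — RGB luma weights for the darkness proxy.
    """

    v_max: float = 0.35
    hue_range_deg: tuple = (30.0, 75.0)
    s_min: float = 0.35
    gray_weights: tuple = REC601_WEIGHTS

    def validate(self) -> None:
        lo, hi = self.hue_range_deg
        if not (0.0 <= self.v_max <= 1.0 and 0.0 <= self.s_min <= 1.0):
            raise ValueError("v_max and s_min must lie in [0, 1]")
        if not (0.0 <= lo < hi <= 360.0):
            raise ValueError("hue range must satisfy 0 <= lo < hi <= 360")
        if len(self.gray_weights) != 3 or abs(sum(self.gray_weights) - 1) > 1e-6:
            raise ValueError("gray_weights must be 3 weights summing to 1")

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def _as_rgb_array(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an RGB image array (H, W, 3)")
    return arr[..., :3]


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def crop_patch(image, origin: tuple, width: int, height: int) -> np.ndarray:
    """Extract the half-open rectangle [x, x+width) x [y, y+height).

    `origin` is the (x, y) top-left corner, 0-based, x rightward and y
    downward.  The rectangle must lie fully inside the image.
    """
    arr = _as_rgb_array(image)
    x, y = origin
    if width <= 0 or height <= 0:
        raise ValueError("crop size must be positive")
    img_h, img_w = arr.shape[:2]
    if x < 0 or y < 0 or x + width > img_w or y + height > img_h:
        raise ValueError(
            f"crop [{x}:{x + width}) x [{y}:{y + height}) exceeds "
            f"image extent {img_w} x {img_h}"
        )
    return arr[y : y + height, x : x + width]


def compute_darkness(patch, weights=REC601_WEIGHTS) -> float:
    """Mean per-pixel darkness of a patch, 0 = white to 1 = black."""
    arr = _as_rgb_array(patch).astype(float)
    if arr.size == 0:
        raise ValueError("empty patch")
    lum = arr @ np.asarray(weights, float)
    return float(np.clip(1.0 - lum.mean() / 255.0, 0.0, 1.0))


def label_pixels(patch, config: ClassifierConfig | None = None) -> np.ndarray:
    """Per-pixel class labels: 0 = clear, 1 = black, 2 = yellow."""
    config = config or ClassifierConfig()
    config.validate()
    arr = _as_rgb_array(patch)
    hsv = rgb2hsv(arr)
    hue_deg = hsv[..., 0] * 360.0
    sat, val = hsv[..., 1], hsv[..., 2]

    labels = np.zeros(arr.shape[:2], dtype=np.uint8)
    black = val <= config.v_max
    lo, hi = config.hue_range_deg
    yellow = ~black & (hue_deg >= lo) & (hue_deg <= hi) & (sat >= config.s_min)
    labels[black] = 1
    labels[yellow] = 2
    return labels


def classify_pixels(patch, config: ClassifierConfig | None = None) -> dict:
    """Count black/yellow/clear pixels in a patch.

    Returns a dict with keys ``n_black, n_yellow, n_clear, total``; the
    three class counts always sum to `total`, the patch pixel count.
    """
    labels = label_pixels(patch, config)
    n_black = int((labels == 1).sum())
    n_yellow = int((labels == 2).sum())
    total = labels.size
    return {
        "n_black": n_black,
        "n_yellow": n_yellow,
        "n_clear": total - n_black - n_yellow,
        "total": total,
    }


def quantify_batch(
    manifest: pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify every image in a manifest table.

    `manifest` needs a ``path`` column; all other columns (larva_id and
    design metadata) are carried through.  Returns ``(observations,
    errors)``: one observation row per readable image with darkness,
    class counts and provenance (file and config hashes), plus a list of
    per-row error records for unreadable images.
    """
    config = config or ClassifierConfig()
    config.validate()
    rows, errors = [], []
    for _, rec in manifest.iterrows():
        try:
            img = load_image(rec["path"])
            with open(rec["path"], "rb") as fh:
                file_hash = hashlib.sha256(fh.read()).hexdigest()[:12]
            counts = classify_pixels(img, config)
            row = rec.drop(labels=["path"]).to_dict()
            row.update(
                darkness=compute_darkness(img, config.gray_weights),
                **{k: v for k, v in counts.items() if k != "total"},
                file_sha256=file_hash,
                config_sha256=config.digest(),
            )
            rows.append(row)
        except (OSError, ValueError) as exc:
            errors.append({"path": rec.get("path"), "error": str(exc)})
    return pd.DataFrame(rows), errors
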