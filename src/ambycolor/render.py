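"""Render synthetic skin patches with exact per-pixel ground truth.

A rendered patch imitates the standardized cheek crop: a pale unpigmented
background scattered with dark melanophore spots and yellow xanthophore
spots.  Spots are disks with random centres and radii and may merge;
melanophores are painted last so melanin overlying a xanthophore reads as
dark, matching how the classifier breaks ties.  After disk painting, a
pixel-level correction makes the label-mask class counts equal the
requested composition exactly, so the mask is a perfect oracle for the
classifier.  Only the counts are contractual; the spot texture is
aesthetic.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk

__all__ = [
    "CLEAR_RGB",
    "BLACK_RGB",
    "YELLOW_RGB",
    "LABEL_CLEAR",
    "LABEL_BLACK",
    "LABEL_YELLOW",
    "render_patch",
]

# class prototype colours (8-bit RGB)
CLEAR_RGB = (214, 208, 196)  # pale unpigmented skin
BLACK_RGB = (30, 28, 26)  # melanophore
YELLOW_RGB = (235, 200, 60)  # xanthophore

LABEL_CLEAR, LABEL_BLACK, LABEL_YELLOW = 0, 1, 2

_PROTO = {
    LABEL_CLEAR: CLEAR_RGB,
    LABEL_BLACK: BLACK_RGB,
    LABEL_YELLOW: YELLOW_RGB,
}


def _paint_disks(mask, label, target, radius_range, rng, max_iter=100_000):
    """Add random disks of `label` until its pixel count reaches `target`."""
    h, w = mask.shape
    lo, hi = radius_range
    for _ in range(max_iter):
        count = int((mask == label).sum())
        if count >= target:
            return
        r = rng.integers(lo, hi + 1)
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        rr, cc = disk((cy, cx), r, shape=mask.shape)
        mask[rr, cc] = label
    raise RuntimeError("disk painting did not converge")  # pragma: no cover


def render_patch(
    counts,
    width: int = 420,
    height: int = 250,
    spot_radius_range: tuple = (4, 14),
    seed: int = 0,
):
    """Render an RGB patch whose mask matches `counts` exactly.

    Parameters
    ----------
    counts : (n_black, n_yellow, n_clear)
        Requested pixel counts; must be non-negative and sum to
        ``width * height``.
    width, height : int
        Patch size in pixels (the study standard is 420 x 250).
    spot_radius_range : (min_r, max_r)
        Disk radii in pixels.
    seed : int
        Seeds spot placement and the count correction.

    Returns
    -------
    (image, mask)
        `image` is a ``(height, width, 3)`` uint8 array painted with the
        pure class prototype colours; `mask` is ``(height, width)`` uint8
        with labels 0 = clear, 1 = black, 2 = yellow.
    """
    n_black, n_yellow, n_clear = (int(c) for c in counts)
    if min(n_black, n_yellow, n_clear) < 0:
        raise ValueError("counts must be non-negative")
    total = width * height
    if n_black + n_yellow + n_clear != total:
        raise ValueError(
            f"counts must sum to width*height = {total}, "
            f"got {n_black + n_yellow + n_clear}"
        )

    rng = np.random.default_rng(seed)
    mask = np.full((height, width), LABEL_CLEAR, dtype=np.uint8)
    # yellow first, black second: melanophores overpaint xanthophores
    _paint_disks(mask, LABEL_YELLOW, n_yellow, spot_radius_range, rng)
    _paint_disks(mask, LABEL_BLACK, n_black, spot_radius_range, rng)

    # pixel-level correction to the exact requested counts
    target = {LABEL_BLACK: n_black, LABEL_YELLOW: n_yellow, LABEL_CLEAR: n_clear}
    flat = mask.ravel()
    for _ in range(3):
        current = {lab: int((flat == lab).sum()) for lab in target}
        deficits = [lab for lab in target if current[lab] < target[lab]]
        if not deficits:
            break
        for lab in deficits:
            need = target[lab] - current[lab]
            surplus = [s for s in target if current[s] > target[s]]
            for s in surplus:
                give = min(need, current[s] - target[s])
                if give <= 0:
                    continue
                idx = np.flatnonzero(flat == s)
                flat[rng.choice(idx, size=give, replace=False)] = lab
                current[s] -= give
                current[lab] += give
                need -= give

    image = np.empty((height, width, 3), dtype=np.uint8)
    for lab, rgb in _PROTO.items():
        image[mask == lab] = rgb
    return image, mask
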