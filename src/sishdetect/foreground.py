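"""Background removal and rough nuclei-region masks.

Nuclei are darker than the pale tissue background in SISH brightfield
images.  Contrast is enhanced (luminance + full-range histogram
equalization), then foreground is the union of a global Otsu cut and a
local mean-threshold cut, cleaned up by morphological opening and
small-hole filling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import ParameterError

DEFAULT_LOCAL_BLOCK = 51
DEFAULT_LOCAL_OFFSET = 10.0
DEFAULT_MIN_HOLE = 32
DEFAULT_OPEN_RADIUS = 1
DEFAULT_MIN_AREA = 30


def enhance_contrast(image: np.ndarray) -> np.ndarray:
    """Luminance conversion followed by full-range histogram equalization.

    Uses Rec. 601 weights (0.299, 0.587, 0.114).  Equalization maps the
    luminance CDF onto 0..255 so any image with at least two distinct
    luminance levels spans the full range; a constant image is returned
    unchanged (degenerate histogram).
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ParameterError("empty image")
    if img.ndim == 3:
        lum = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    else:
        lum = img.astype(float)
    g = np.clip(np.round(lum), 0, 255).astype(np.uint8)
    hist = np.bincount(g.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[int(g.min())]
    denom = g.size - cdf_min
    if denom == 0:  # single luminance level
        return g
    lut = np.round((cdf - cdf_min) / denom * 255.0).clip(0, 255).astype(np.uint8)
    return lut[g]


def compute_foreground_mask(
    gray: np.ndarray,
    local_block: int = DEFAULT_LOCAL_BLOCK,
    min_hole: int = DEFAULT_MIN_HOLE,
    open_radius: int = DEFAULT_OPEN_RADIUS,
    local_offset: float = DEFAULT_LOCAL_OFFSET,
) -> np.ndarray:
    """Binary nuclei/tissue mask: global Otsu OR offset local-mean threshold.

    Pixels darker than either threshold are foreground; opening with a
    disk of ``open_radius`` removes speckle and holes smaller than
    ``min_hole`` px^2 are filled.  A constant image yields an empty mask.
    """
    if local_block < 3 or local_block % 2 == 0:
        raise ParameterError("local_block must be odd and >= 3")
    g = np.asarray(gray, dtype=float)
    if g.min() == g.max():
        return np.zeros(g.shape, dtype=bool)
    global_cut = g < threshold_otsu(g)
    local_mean = ndi.uniform_filter(g, size=local_block, mode="reflect")
    local_cut = g < local_mean - local_offset
    fg = global_cut | local_cut
    if open_radius > 0:
        fg = ndi.binary_opening(fg, structure=disk(open_radius))
    if min_hole > 0:
        fg = _fill_small_holes(fg, min_hole)
    return fg


def _fill_small_holes(mask: np.ndarray, min_hole: int) -> np.ndarray:
    """Fill enclosed background components with area < min_hole."""
    lab, n = ndi.label(~mask)
    if n == 0:
        return mask
    border_labels = np.unique(
        np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
    )
    areas = np.bincount(lab.ravel())
    fill = np.flatnonzero(areas < min_hole)
    fill = np.setdiff1d(fill, border_labels)
    out = mask.copy()
    out[np.isin(lab, fill[fill > 0])] = True
    return out


def scene_foreground(image: np.ndarray, **kwargs) -> np.ndarray:
    """Foreground mask of an RGB scene.

    Thresholds operate on the raw luminance: equalization spreads the
    dominant pale background across the intensity range (its histogram
    becomes flat by construction), which makes a global Otsu cut
    meaningless; the enhanced image is for contrast/visual inspection.
    """
    img = np.asarray(image, dtype=float)
    lum = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return compute_foreground_mask(lum, **kwargs)


def remove_small_regions(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_area`` px^2.

    Works for boolean masks and for integer instance masks; surviving
    instance labels keep their ids.  The boundary is inclusive: a
    component of exactly ``min_area`` pixels survives.
    """
    if min_area < 0:
        raise ParameterError("min_area must be >= 0")
    mask = np.asarray(mask)
    if min_area == 0:
        return mask.copy()
    out = mask.copy()
    structure = np.ones((3, 3), dtype=bool)
    if mask.dtype == bool:
        lab, n = ndi.label(mask, structure=structure)
        if n == 0:
            return out
        areas = np.bincount(lab.ravel())
        kill = np.flatnonzero(areas < min_area)
        out[np.isin(lab, kill[kill > 0])] = False
        return out
    # instance mask: a component is an 8-connected region of one label;
    # each same-label piece is judged on its own
    for value in np.unique(mask[mask > 0]):
        sel = mask == value
        lab, n = ndi.label(sel, structure=structure)
        if n == 0:
            continue
        areas = np.bincount(lab.ravel())
        kill = np.flatnonzero(areas < min_area)
        out[np.isin(lab, kill[kill > 0])] = 0
    return out
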