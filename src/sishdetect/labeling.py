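"""Stage-1 pseudo-labels, the watershed baseline, and patch curation.

The two-stage training recipe needs instance labels before any model
exists.  Here the bootstrap segmenter is marker-controlled watershed on
the foreground's Euclidean distance transform; its output is cleaned
(foreground-majority filter, small-region removal) into pseudo-labels,
then images and labels are cut into fixed-size training patches with
flip/rotation augmentation.  Any instance segmenter with the same
signature can replace the watershed bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import ParameterError
from .foreground import remove_small_regions

DEFAULT_MARKER_SEPARATION = 7
DEFAULT_MIN_AREA = 30
DEFAULT_PATCH_SIZE = 256
DEFAULT_MIN_FOREGROUND = 0.02


@dataclass
class Patch:
    """One training patch with its provenance."""

    image: np.ndarray  # patch_size x patch_size x 3
    mask: np.ndarray  # patch_size x patch_size instance labels
    source_id: str
    offset: tuple[int, int]  # (row, col) in the padded source image


def watershed_baseline(
    image: np.ndarray,
    foreground: np.ndarray,
    marker_separation: int = DEFAULT_MARKER_SEPARATION,
) -> np.ndarray:
    """Marker-controlled watershed segmentation of the foreground.

    Markers are local maxima of the Euclidean distance transform with a
    minimum separation of ``marker_separation`` px; flooding runs on the
    negated distance map restricted to the foreground.  The ``image``
    argument is accepted for segmenter-interface compatibility; the
    classical method needs only the binary foreground.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if image is not None and image.shape[:2] != foreground.shape:
        raise ParameterError("image and foreground shapes disagree")
    if not foreground.any():
        return np.zeros(foreground.shape, dtype=np.int32)
    edt = ndi.distance_transform_edt(foreground)
    peaks = peak_local_max(
        edt,
        min_distance=marker_separation,
        exclude_border=False,
        labels=foreground,
    )
    if len(peaks) == 0:
        return np.zeros(foreground.shape, dtype=np.int32)
    marker_img = np.zeros(foreground.shape, dtype=np.int32)
    marker_img[tuple(peaks.T)] = 1
    markers, _ = ndi.label(marker_img)
    return watershed(-edt, markers=markers, mask=foreground).astype(np.int32)


def pseudo_label(
    image: np.ndarray,
    segmenter,
    foreground: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
) -> np.ndarray:
    """Run a segmenter and clean its labels into training pseudo-labels.

    Instances whose pixel-majority lies outside the foreground are
    dropped, components smaller than ``min_area`` are removed, and labels
    are renumbered consecutively from 1.
    """
    seg = np.asarray(segmenter(image))
    if seg.shape != foreground.shape:
        raise ParameterError("segmenter output shape disagrees with foreground")
    foreground = np.asarray(foreground, dtype=bool)
    out = seg.astype(np.int32).copy()
    for lab in np.unique(out[out > 0]):
        sel = out == lab
        if np.count_nonzero(sel & foreground) * 2 <= np.count_nonzero(sel):
            out[sel] = 0
    out = remove_small_regions(out, min_area)
    return relabel_consecutive(out)


def relabel_consecutive(mask: np.ndarray) -> np.ndarray:
    """Renumber surviving labels to 1..n preserving their order."""
    labels = np.unique(mask[mask > 0])
    out = np.zeros_like(mask, dtype=np.int32)
    for new, lab in enumerate(labels, start=1):
        out[mask == lab] = new
    return out


def patchify(
    image: np.ndarray,
    mask: np.ndarray,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int | None = None,
    min_foreground: float = DEFAULT_MIN_FOREGROUND,
    source_id: str = "image",
) -> list[Patch]:
    """Grid-crop an image/mask pair into training patches.

    The pair is reflect-padded at the right/bottom so the grid covers it
    completely; patches whose mask-foreground fraction is below
    ``min_foreground`` are dropped.  Instances clipped by a patch border
    keep their clipped shape.
    """
    if stride is None:
        stride = patch_size
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ParameterError("image and mask shapes disagree")
    h, w = mask.shape
    n_r = max(1, -(-max(h - patch_size, 0) // stride) + 1)
    n_c = max(1, -(-max(w - patch_size, 0) // stride) + 1)
    ph = (n_r - 1) * stride + patch_size
    pw = (n_c - 1) * stride + patch_size
    img_p = np.pad(image, ((0, ph - h), (0, pw - w), (0, 0)), mode="reflect")
    mask_p = np.pad(mask, ((0, ph - h), (0, pw - w)), mode="reflect")
    patches = []
    for i in range(n_r):
        for j in range(n_c):
            r0, c0 = i * stride, j * stride
            mp = mask_p[r0 : r0 + patch_size, c0 : c0 + patch_size]
            if np.count_nonzero(mp) / mp.size < min_foreground:
                continue
            patches.append(
                Patch(
                    image=img_p[r0 : r0 + patch_size, c0 : c0 + patch_size].copy(),
                    mask=mp.copy(),
                    source_id=source_id,
                    offset=(r0, c0),
                )
            )
    return patches


def augment(
    patch: tuple[np.ndarray, np.ndarray], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random k*90-degree rotation plus independent flips, image and mask alike."""
    image, mask = patch
    if image.shape[0] != image.shape[1]:
        raise ParameterError("augmentation requires square patches")
    rng = np.random.default_rng(seed)
    k = int(rng.integers(4))
    flip_h = bool(rng.integers(2))
    flip_v = bool(rng.integers(2))
    img, m = np.rot90(image, k), np.rot90(mask, k)
    if flip_h:
        img, m = img[:, ::-1], m[:, ::-1]
    if flip_v:
        img, m = img[::-1], m[::-1]
    return np.ascontiguousarray(img), np.ascontiguousarray(m)
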