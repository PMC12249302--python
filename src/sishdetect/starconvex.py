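"""Star-convex polygon geometry: training targets, candidates, NMS, rasterization.

A nucleus is represented by per-pixel radial distances to its boundary
along ``n_rays`` fixed directions (angles 2*pi*k/n_rays), together with an
object-probability map that peaks at the nucleus centre.  Detection turns
dense per-pixel polygon candidates into an instance mask via greedy
non-maximum suppression on polygon IoU, then score-priority painting.

Distances follow a unit-pixel ray-marching rule: from a pixel's centre,
step 1 px at a time along the ray and count the steps that stay on the
pixel's own instance label; stepping outside the image counts as leaving
the instance.  The measured distance therefore reaches the centre of the
last interior pixel; rasterization adds half a pixel so polygon edges sit
on the true instance boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError

DEFAULT_N_RAYS = 32
DEFAULT_PROB_THRESH = 0.5
DEFAULT_IOU_THRESH = 0.4

# measured distances reach the last interior pixel centre; the physical
# boundary lies ~half a pixel further out
RASTER_RADIUS_OFFSET = 0.5


@dataclass
class PolygonCandidate:
    """One candidate star-convex polygon anchored at a pixel centre."""

    center: tuple[float, float]  # (row, col)
    radii: np.ndarray  # length n_rays, px
    score: float

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii < 0):
            raise ParameterError("radii must be >= 0")
        if not 0 <= self.score <= 1:
            raise ParameterError("score must lie in [0, 1]")


@dataclass
class RadialGroundTruth:
    """Training target: object probability and per-ray boundary distances."""

    prob: np.ndarray  # H x W in [0, 1]
    dist: np.ndarray  # H x W x n_rays, px


@dataclass
class DetectionSet:
    """Kept polygons, their centroids and the rasterized instance mask."""

    polygons: list[PolygonCandidate]
    centroids: list[tuple[float, float]]
    instance_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.polygons)


def ray_directions(n_rays: int) -> np.ndarray:
    """(n_rays, 2) unit (drow, dcol) steps at angles 2*pi*k/n_rays."""
    theta = 2 * np.pi * np.arange(n_rays) / n_rays
    return np.stack([np.sin(theta), np.cos(theta)], axis=1)


def compute_radial_distances(mask: np.ndarray, n_rays: int = DEFAULT_N_RAYS) -> np.ndarray:
    """Unit-step ray-marched distances to the instance boundary.

    For each foreground pixel and each ray, the distance is the number of
    consecutive 1-px steps from the pixel centre that remain on the same
    instance label.  Background pixels get 0 on all rays.
    """
    if n_rays < 8:
        raise ParameterError("n_rays must be >= 8")
    h, w = mask.shape
    out = np.zeros((h, w, n_rays), dtype=np.float32)
    coords = np.argwhere(mask > 0)
    if len(coords) == 0:
        return out
    labels = mask[coords[:, 0], coords[:, 1]]
    dirs = ray_directions(n_rays)
    t_max = int(np.ceil(np.hypot(h, w))) + 1
    for k in range(n_rays):
        dr, dc = dirs[k]
        alive = np.ones(len(coords), dtype=bool)
        dist = np.zeros(len(coords), dtype=np.float32)
        for t in range(1, t_max):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            rr = np.floor(coords[idx, 0] + t * dr + 0.5).astype(np.intp)
            cc = np.floor(coords[idx, 1] + t * dc + 0.5).astype(np.intp)
            inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            same = np.zeros(idx.size, dtype=bool)
            ii = np.flatnonzero(inside)
            same[ii] = mask[rr[ii], cc[ii]] == labels[idx[ii]]
            dist[idx[same]] = t
            alive[idx[~same]] = False
        out[coords[:, 0], coords[:, 1], k] = dist
    return out


def compute_object_probability(mask: np.ndarray) -> np.ndarray:
    """Normalized per-instance distance-to-boundary: 1 at the centre, 0 outside.

    Pixels near an instance centre are prioritised during training; the
    map is the Euclidean distance transform of each instance (other labels
    count as boundary), divided by its per-instance maximum.
    """
    prob = np.zeros(mask.shape, dtype=np.float32)
    for lab, sl in enumerate(ndi.find_objects(mask), start=1):
        if sl is None:
            continue
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, mask.shape)
        )
        inst = mask[sl] == lab
        edt = ndi.distance_transform_edt(inst)
        m = edt.max()
        if m > 0:
            region = prob[sl]
            region[inst] = (edt[inst] / m).astype(np.float32)
    return prob


def radial_ground_truth(mask: np.ndarray, n_rays: int = DEFAULT_N_RAYS) -> RadialGroundTruth:
    return RadialGroundTruth(
        prob=compute_object_probability(mask),
        dist=compute_radial_distances(mask, n_rays),
    )


def _smooth_radii(radii: np.ndarray) -> np.ndarray:
    """Circular 1-2-1 filter: removes the +-1 px jitter of integer stepping."""
    r = np.asarray(radii, dtype=float)
    return (np.roll(r, 1) + 2 * r + np.roll(r, -1)) / 4


def rasterize_polygon(
    cand: PolygonCandidate,
    shape: tuple[int, int],
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Boolean mask of the polygon on a grid of ``shape`` starting at ``origin``.

    A pixel belongs to the polygon iff its distance from the centre does
    not exceed the angularly interpolated (and 1-2-1 smoothed) ray radius
    plus the half-pixel boundary offset.  This polar-clipping rule is the
    package's overlap-resolution convention throughout.
    """
    n_rays = len(cand.radii)
    radii = _smooth_radii(cand.radii)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr + origin[0] - cand.center[0]
    dx = cc + origin[1] - cand.center[1]
    dist = np.hypot(dy, dx)
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    kf = ang / (2 * np.pi) * n_rays
    k0 = np.floor(kf).astype(int) % n_rays
    w = kf - np.floor(kf)
    rad = (1 - w) * radii[k0] + w * radii[(k0 + 1) % n_rays]
    return dist <= rad + RASTER_RADIUS_OFFSET


def polygon_iou(a: PolygonCandidate, b: PolygonCandidate) -> float:
    """IoU of the two rasterized polygons on the union of their bounding boxes."""
    rmax_a = float(np.max(a.radii, initial=0.0)) + RASTER_RADIUS_OFFSET + 1
    rmax_b = float(np.max(b.radii, initial=0.0)) + RASTER_RADIUS_OFFSET + 1
    r0 = np.floor(min(a.center[0] - rmax_a, b.center[0] - rmax_b))
    c0 = np.floor(min(a.center[1] - rmax_a, b.center[1] - rmax_b))
    shape = (
        int(np.ceil(max(a.center[0] + rmax_a, b.center[0] + rmax_b) - r0)) + 1,
        int(np.ceil(max(a.center[1] + rmax_a, b.center[1] + rmax_b) - c0)) + 1,
    )
    ma = rasterize_polygon(a, shape, origin=(r0, c0))
    mb = rasterize_polygon(b, shape, origin=(r0, c0))
    union = np.count_nonzero(ma | mb)
    if union == 0:
        return 0.0
    return np.count_nonzero(ma & mb) / union


def candidate_polygons(
    prob: np.ndarray,
    dist: np.ndarray,
    prob_thresh: float = DEFAULT_PROB_THRESH,
) -> list[PolygonCandidate]:
    """One candidate per super-threshold pixel, in deterministic row-major order."""
    if prob.shape != dist.shape[:2]:
        raise ParameterError("prob and dist spatial shapes differ")
    coords = np.argwhere(prob > prob_thresh)
    return [
        PolygonCandidate(
            center=(float(r), float(c)),
            radii=dist[r, c].astype(float),
            score=float(prob[r, c]),
        )
        for r, c in coords
    ]


def greedy_nms(
    candidates: list[PolygonCandidate],
    iou_thresh: float = DEFAULT_IOU_THRESH,
) -> list[PolygonCandidate]:
    """Keep candidates by descending score whose IoU with every kept one is < thresh.

    Ties in score are broken by smaller row, then smaller column, making the
    result invariant to the input ordering.
    """
    if not 0 < iou_thresh < 1:
        raise ParameterError("iou_thresh must lie strictly between 0 and 1")
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i].score, candidates[i].center[0], candidates[i].center[1]),
    )
    kept: list[PolygonCandidate] = []
    kept_centers: list[np.ndarray] = []
    kept_rmax: list[float] = []
    for i in order:
        c = candidates[i]
        rmax = float(c.radii.max(initial=0.0)) + RASTER_RADIUS_OFFSET
        ok = True
        for k, ctr, krm in zip(kept, kept_centers, kept_rmax):
            # disjoint supports cannot overlap: skip the rasterized IoU
            if np.hypot(ctr[0] - c.center[0], ctr[1] - c.center[1]) > krm + rmax:
                continue
            if polygon_iou(c, k) >= iou_thresh:
                ok = False
                break
        if ok:
            kept.append(c)
            kept_centers.append(np.asarray(c.center))
            kept_rmax.append(rmax)
    return kept


def rasterize_detections(
    kept: list[PolygonCandidate], shape: tuple[int, int]
) -> DetectionSet:
    """Paint kept polygons, higher scores winning contested pixels.

    Polygons are painted in order of increasing score (and reversed
    acceptance order within ties) so that the highest-score polygon owns
    every contested pixel.  Instances that end up empty are dropped and
    labels renumbered consecutively.
    """
    mask = np.zeros(shape, dtype=np.int32)
    # among equal scores, later acceptance paints first -> earlier wins
    order = sorted(range(len(kept)), key=lambda i: (kept[i].score, -i))
    for i in order:
        poly = kept[i]
        rmax = float(np.max(poly.radii, initial=0.0)) + RASTER_RADIUS_OFFSET + 1
        r0 = max(int(np.floor(poly.center[0] - rmax)), 0)
        c0 = max(int(np.floor(poly.center[1] - rmax)), 0)
        r1 = min(int(np.ceil(poly.center[0] + rmax)) + 1, shape[0])
        c1 = min(int(np.ceil(poly.center[1] + rmax)) + 1, shape[1])
        if r1 <= r0 or c1 <= c0:
            continue
        local = rasterize_polygon(poly, (r1 - r0, c1 - c0), origin=(r0, c0))
        mask[r0:r1, c0:c1][local] = i + 1
    polygons: list[PolygonCandidate] = []
    centroids: list[tuple[float, float]] = []
    out = np.zeros(shape, dtype=np.int32)
    next_label = 0
    for i in range(len(kept)):
        sel = mask == i + 1
        if not sel.any():
            continue
        next_label += 1
        out[sel] = next_label
        coords = np.argwhere(sel)
        polygons.append(kept[i])
        centroids.append((float(coords[:, 0].mean()), float(coords[:, 1].mean())))
    return DetectionSet(polygons=polygons, centroids=centroids, instance_mask=out)
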