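"""Independent brute-force reference implementations used only by tests.

Each function re-implements a package operation with deliberately naive
scalar code (loops, enumeration) so agreement is meaningful.  They share
the package's documented conventions but none of its code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ray_distance_oracle(mask: np.ndarray, row: int, col: int, n_rays: int) -> np.ndarray:
    """Scalar unit-step ray marching for a single pixel."""
    h, w = mask.shape
    lab = mask[row, col]
    out = np.zeros(n_rays)
    if lab == 0:
        return out
    for k in range(n_rays):
        theta = 2 * math.pi * k / n_rays
        dr, dc = math.sin(theta), math.cos(theta)
        t = 0
        while True:
            tt = t + 1
            rr = math.floor(row + tt * dr + 0.5)
            cc = math.floor(col + tt * dc + 0.5)
            if not (0 <= rr < h and 0 <= cc < w) or mask[rr, cc] != lab:
                break
            t = tt
            if t > h + w:
                break
        out[k] = t
    return out


def rasterize_polygon_oracle(
    center: tuple[float, float], radii: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Scalar polar-clipping rasterizer (1-2-1 smoothing + 0.5 px offset)."""
    n = len(radii)
    sm = [
        (radii[(k - 1) % n] + 2 * radii[k] + radii[(k + 1) % n]) / 4.0
        for k in range(n)
    ]
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            dy, dx = r - center[0], c - center[1]
            dist = math.hypot(dy, dx)
            ang = math.atan2(dy, dx) % (2 * math.pi)
            kf = ang / (2 * math.pi) * n
            k0 = int(math.floor(kf)) % n
            wgt = kf - math.floor(kf)
            rad = (1 - wgt) * sm[k0] + wgt * sm[(k0 + 1) % n]
            if dist <= rad + 0.5:
                out[r, c] = True
    return out


def polygon_iou_oracle(a, b) -> float:
    """Pixel-set IoU of two polygons on a common grid via the scalar rasterizer."""
    rmax_a = float(np.max(a.radii, initial=0.0)) + 2
    rmax_b = float(np.max(b.radii, initial=0.0)) + 2
    r0 = math.floor(min(a.center[0] - rmax_a, b.center[0] - rmax_b))
    c0 = math.floor(min(a.center[1] - rmax_a, b.center[1] - rmax_b))
    r1 = math.ceil(max(a.center[0] + rmax_a, b.center[0] + rmax_b))
    c1 = math.ceil(max(a.center[1] + rmax_a, b.center[1] + rmax_b))
    shape = (int(r1 - r0) + 1, int(c1 - c0) + 1)
    ma = rasterize_polygon_oracle((a.center[0] - r0, a.center[1] - c0), a.radii, shape)
    mb = rasterize_polygon_oracle((b.center[0] - r0, b.center[1] - c0), b.radii, shape)
    union = int(np.count_nonzero(ma | mb))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(ma & mb)) / union


def nms_oracle(candidates, iou_thresh: float, iou_fn) -> list[int]:
    """Sequential greedy suppression; returns indices into ``candidates``."""
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i].score, candidates[i].center[0], candidates[i].center[1]),
    )
    kept: list[int] = []
    for i in order:
        if all(iou_fn(candidates[i], candidates[j]) < iou_thresh for j in kept):
            kept.append(i)
    return kept


def match_instances_oracle(pred: np.ndarray, gt: np.ndarray, iou_thresh: float):
    """Exhaustive one-to-one assignment maximizing total IoU (<= ~6 labels).

    Enumerates every injective map from prediction subsets to ground-truth
    labels whose pairs all clear the threshold and keeps the one with the
    largest summed IoU (ties broken toward more pairs).
    """
    pred_ids = sorted(set(pred[pred > 0].tolist()))
    gt_ids = sorted(set(gt[gt > 0].tolist()))

    def iou(p, g):
        ps, gs = pred == p, gt == g
        u = np.count_nonzero(ps | gs)
        return np.count_nonzero(ps & gs) / u if u else 0.0

    table = {(p, g): iou(p, g) for p in pred_ids for g in gt_ids}
    best_tp, best_total = 0, 0.0
    for size in range(min(len(pred_ids), len(gt_ids)) + 1):
        for p_sub in itertools.combinations(pred_ids, size):
            for g_perm in itertools.permutations(gt_ids, size):
                if any(table[p, g] < iou_thresh for p, g in zip(p_sub, g_perm)):
                    continue
                total = sum(table[p, g] for p, g in zip(p_sub, g_perm))
                if total > best_total + 1e-12 or (
                    abs(total - best_total) <= 1e-12 and size > best_tp
                ):
                    best_tp, best_total = size, total
    return best_tp, len(pred_ids) - best_tp, len(gt_ids) - best_tp


def ssim_oracle(a: np.ndarray, b: np.ndarray, data_range: float = 255.0) -> float:
    """Direct per-window SSIM, uniform 7x7, standard constants."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, w = a.shape
    vals = []
    for r in range(h - 6):
        for c in range(w - 6):
            wa = a[r : r + 7, c : c + 7].ravel()
            wb = b[r : r + 7, c : c + 7].ravel()
            mua, mub = wa.mean(), wb.mean()
            # unbiased (n-1) moments, matching the standard implementation
            va = wa.var(ddof=1)
            vb = wb.var(ddof=1)
            cov = ((wa - mua) * (wb - mub)).sum() / (wa.size - 1)
            vals.append(
                ((2 * mua * mub + c1) * (2 * cov + c2))
                / ((mua**2 + mub**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


def remove_small_oracle(mask: np.ndarray, min_area: int) -> np.ndarray:
    """BFS flood fill over 8-neighbourhoods; drop pieces below min_area."""
    mask = np.asarray(mask)
    visited = np.zeros(mask.shape, dtype=bool)
    out = mask.copy()
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] == 0 or visited[r, c]:
                continue
            val = mask[r, c]
            stack, comp = [(r, c)], []
            visited[r, c] = True
            while stack:
                rr, cc = stack.pop()
                comp.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < h and 0 <= nc < w
                            and not visited[nr, nc]
                            and mask[nr, nc] == val
                        ):
                            visited[nr, nc] = True
                            stack.append((nr, nc))
            if len(comp) < min_area:
                for rr, cc in comp:
                    out[rr, cc] = 0
    return out


def match_points_oracle(mask: np.ndarray, centroids, points):
    """Containment matching with nearest-centroid tie-breaks, scalar version."""
    by_instance: dict[int, list[int]] = {}
    fn = 0
    for i, (r, c) in enumerate(points):
        inst = int(mask[int(round(r)), int(round(c))])
        if inst == 0:
            fn += 1
        else:
            by_instance.setdefault(inst, []).append(i)
    tp = 0
    for inst, idxs in by_instance.items():
        dists = [
            math.hypot(centroids[inst - 1][0] - points[i][0],
                       centroids[inst - 1][1] - points[i][1])
            for i in idxs
        ]
        tp += 1
        fn += len(idxs) - 1
        del dists  # the winner's identity does not change the counts
    fp = int(mask.max()) - len(by_instance)
    return tp, fp, fn
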