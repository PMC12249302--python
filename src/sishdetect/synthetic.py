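"""Seeded generator of SISH-like histology scenes with full ground truth.

Real HER2-SISH slides show bluish-purple tumour nuclei on a pale tissue
background, with black HER2 signals and red CEN17 signals as small dots
inside the nuclei.  This module renders miniature scenes with the same
structure — star-convex nuclei, overlapping clusters, border-touching
nuclei, in-nucleus dot signals — through a known optical-density stain
matrix, so that stain estimation, foreground extraction, training and
evaluation can all be validated against exact ground truth.

Scenes are a pure function of their :class:`SceneConfig` (including the
seed): two calls with the same config produce byte-identical images and
masks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import GenerationError, ParameterError

# Columns are unit-L2-norm OD vectors: a haematoxylin-like nuclear stain
# (absorbs red/green -> bluish-purple nuclei) and a broader pinkish
# counterstain with enough red absorption that stained tissue passes the
# OD transparency threshold in all three channels.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.650, 0.300],
     [0.704, 0.850],
     [0.286, 0.450]]
)
DEFAULT_STAIN_MATRIX /= np.linalg.norm(DEFAULT_STAIN_MATRIX, axis=0, keepdims=True)

# CEN17 (red) and HER2 (black) dots are rendered as concentration
# mixtures of the scene's two stains (dense counterstain-dominant for
# red, dense in both for black), so their OD directions lie inside the
# stain fan by construction and cannot distort stain estimation.  They
# exist to drive the expert-criteria filter, not signal quantification.
RED_DOT_CONC = np.array([0.3, 1.6])
BLACK_DOT_CONC = np.array([1.6, 1.6])

_MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene; the seed makes it fully reproducible."""

    height: int = 128
    width: int = 128
    n_nuclei: int = 12
    radius_range: tuple[float, float] = (5.0, 9.0)
    irregularity: float = 0.22
    overlap_fraction: float = 0.15
    border_fraction: float = 0.1
    red_signal_range: tuple[int, int] = (1, 3)
    black_signal_range: tuple[int, int] = (0, 4)
    stain_matrix: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_STAIN_MATRIX.copy()
    )
    stain_gain: tuple[float, float] = (1.0, 1.0)
    background_intensity: float = 220.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] < 3:
            raise ParameterError("radius_range minimum must be >= 3 px")
        if self.radius_range[0] > self.radius_range[1]:
            raise ParameterError("radius_range must be (min, max)")
        if not 0 <= self.overlap_fraction + self.border_fraction <= 1:
            raise ParameterError(
                "overlap_fraction + border_fraction must lie in [0, 1]"
            )
        m = np.asarray(self.stain_matrix, dtype=float)
        if m.shape != (3, 2) or np.any(m < 0):
            raise ParameterError("stain_matrix must be 3x2 with non-negative entries")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ParameterError("stain_matrix columns must have unit L2 norm")
        object.__setattr__(self, "stain_matrix", m)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stain_matrix"] = np.asarray(self.stain_matrix).tolist()
        d["radius_range"] = list(self.radius_range)
        d["red_signal_range"] = list(self.red_signal_range)
        d["black_signal_range"] = list(self.black_signal_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "stain_matrix" in d:
            d["stain_matrix"] = np.asarray(d["stain_matrix"], dtype=float)
        for key in ("radius_range", "red_signal_range", "black_signal_range", "stain_gain"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticScene:
    """A rendered scene with its instance mask and per-nucleus metadata."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W int32 instance labels, 0 = background
    nuclei: pd.DataFrame  # label,row,col,area,red_signals,black_signals,...
    config: SceneConfig


def make_star_convex_blob(
    center: tuple[float, float],
    mean_radius: float,
    irregularity: float,
    seed: int,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Rasterize a random star-convex region about ``center``.

    The boundary is a smooth single-valued radius function of angle,
    r(theta) = mean_radius * (1 + irregularity * g(theta)) with g built
    from a few low-order harmonics, so every ray from the center crosses
    the boundary exactly once.  ``irregularity=0`` gives the exact
    rasterized disk (pixels whose center lies within ``mean_radius``).
    """
    if not 0 <= irregularity <= 0.5:
        raise ParameterError("irregularity must lie in [0, 0.5]")
    if mean_radius < 3:
        raise ParameterError("mean_radius must be >= 3 px")
    rng = np.random.default_rng(seed)
    n_theta = 720
    theta = np.arange(n_theta) * (2 * np.pi / n_theta)
    if irregularity == 0:
        radius = np.full(n_theta, float(mean_radius))
    else:
        profile = np.zeros(n_theta)
        # low-order harmonics only: keeps |dr/dtheta| small so the pixel
        # rasterization stays star-convex along discrete rays
        for k in (2, 3, 4):
            profile += (rng.uniform(0.3, 1.0) / k) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        profile /= np.max(np.abs(profile))
        radius = mean_radius * (1 + irregularity * profile)
    rmax = float(radius.max())
    if shape is None:
        shape = (
            int(np.ceil(center[0] + rmax)) + 2,
            int(np.ceil(center[1] + rmax)) + 2,
        )
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    dist = np.hypot(dy, dx)
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    bins = np.minimum((ang / (2 * np.pi) * n_theta).astype(int), n_theta - 1)
    return dist <= radius[bins]


def _place_nuclei(config: SceneConfig, rng: np.random.Generator):
    """Sample centers/radii satisfying the free/overlap/border quotas.

    Returns a list of dicts with center, radius, blob seed, and the
    intended placement category.  Raises :class:`GenerationError` when a
    constraint cannot be met within a bounded number of retries.
    """
    h, w = config.height, config.width
    n = config.n_nuclei
    n_border = int(round(config.border_fraction * n))
    n_overlap = int(round(config.overlap_fraction * n))
    if n_border + n_overlap > n:
        n_overlap = n - n_border
    n_free = n - n_border - n_overlap
    rmin, rmax = config.radius_range
    # margin accounts for the irregularity-driven radius excursion
    excess = 1.0 + config.irregularity

    placed: list[dict] = []

    def far_from_all(r0, c0, rad):
        for p in placed:
            # 2 px clearance so "free" nuclei never touch a neighbour
            if np.hypot(p["row"] - r0, p["col"] - c0) < (p["radius"] + rad) * excess + 2:
                return False
        return True

    for _ in range(n_free):
        for _try in range(_MAX_PLACEMENT_TRIES):
            rad = rng.uniform(rmin, rmax)
            lim = rad * excess + 2
            if 2 * lim >= min(h, w):
                continue
            r0 = rng.uniform(lim, h - lim)
            c0 = rng.uniform(lim, w - lim)
            if far_from_all(r0, c0, rad):
                placed.append(
                    {"row": r0, "col": c0, "radius": rad, "kind": "free"}
                )
                break
        else:
            raise GenerationError(
                "could not place a non-overlapping interior nucleus; "
                "reduce n_nuclei or radius_range"
            )

    hosts = [p for p in placed if p["kind"] == "free"]
    if n_overlap > 0 and not hosts:
        raise GenerationError(
            "overlap_fraction > 0 requires at least one interior host nucleus"
        )
    free_hosts = list(hosts)
    for _ in range(n_overlap):
        for _try in range(_MAX_PLACEMENT_TRIES):
            if not free_hosts:
                raise GenerationError("not enough hosts for requested overlaps")
            host = free_hosts[rng.integers(len(free_hosts))]
            rad = rng.uniform(rmin, rmax)
            # partial overlap: centers closer than the radius sum but far
            # enough that neither nucleus is swallowed by z-order
            d = rng.uniform(0.75, 0.95) * (host["radius"] + rad)
            phi = rng.uniform(0, 2 * np.pi)
            r0 = host["row"] + d * np.sin(phi)
            c0 = host["col"] + d * np.cos(phi)
            lim = rad * excess + 2
            if not (lim <= r0 <= h - lim and lim <= c0 <= w - lim):
                continue
            ok = True
            for p in placed:
                if p is host:
                    continue
                if np.hypot(p["row"] - r0, p["col"] - c0) < (p["radius"] + rad) * excess + 2:
                    ok = False
                    break
            if ok:
                placed.append({"row": r0, "col": c0, "radius": rad, "kind": "overlap"})
                free_hosts.remove(host)
                break
        else:
            raise GenerationError("could not place an overlapping nucleus")

    for _ in range(n_border):
        for _try in range(_MAX_PLACEMENT_TRIES):
            rad = rng.uniform(rmin, rmax)
            side = rng.integers(4)
            # center offset < rmin so the blob is guaranteed to be clipped
            off = rng.uniform(0.2, 0.6) * rad
            if side == 0:
                r0, c0 = off, rng.uniform(rad * excess + 2, w - rad * excess - 2)
            elif side == 1:
                r0, c0 = h - 1 - off, rng.uniform(rad * excess + 2, w - rad * excess - 2)
            elif side == 2:
                r0, c0 = rng.uniform(rad * excess + 2, h - rad * excess - 2), off
            else:
                r0, c0 = rng.uniform(rad * excess + 2, h - rad * excess - 2), w - 1 - off
            if far_from_all(r0, c0, rad):
                placed.append({"row": r0, "col": c0, "radius": rad, "kind": "border"})
                break
        else:
            raise GenerationError("could not place a border-touching nucleus")

    return placed


def _render(mask: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Render the instance mask to RGB through the configured stain matrix."""
    h, w = mask.shape
    m = config.stain_matrix
    i0 = 255.0
    fg = mask > 0
    c_nuc = np.zeros((h, w))
    for lab in np.unique(mask[fg]):
        base = rng.uniform(0.65, 1.0)
        sel = mask == lab
        c_nuc[sel] = base + rng.normal(0, 0.04, int(sel.sum()))
    c_nuc = np.clip(c_nuc, 0, None)
    # background counterstain concentration chosen so the mean rendered
    # background intensity matches config.background_intensity
    c_bg_base = np.log10(i0 / config.background_intensity) / float(m[:, 1].mean())
    field = ndi.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=12)
    if field.std() > 0:
        field = field / field.std()
    c_bg = np.clip(c_bg_base * (1 + 0.12 * field), 0, None)
    # a few darker stroma patches of pure counterstain (~3-5% of the image):
    # a pale background alone never exceeds the OD transparency threshold,
    # so these are what make the second stain vector estimable
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(max(3, (h * w) // 4000)):
        sr, sc_ = rng.uniform(0, h), rng.uniform(0, w)
        sig = rng.uniform(5, 9)
        amp = rng.uniform(0.5, 0.75)
        c_bg += amp * np.exp(-((rr - sr) ** 2 + (cc - sc_) ** 2) / (2 * sig**2))
    c_bg[fg] *= 0.25  # faint counterstain inside nuclei
    # per-stain multiplicative gain: emulates staining-intensity variability
    c_nuc = c_nuc * config.stain_gain[0]
    c_bg = c_bg * config.stain_gain[1]
    conc = np.stack([c_nuc.ravel(), c_bg.ravel()])  # 2 x N
    od = m @ conc  # 3 x N
    img = i0 * np.power(10.0, -od)
    return img.T.reshape(h, w, 3)


def _draw_dots(
    img: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    counts: dict[int, tuple[int, int]],
    stain_matrix: np.ndarray,
    stain_gain: tuple[float, float],
    rng: np.random.Generator,
) -> None:
    """Paint red/black signal dots (1-2 px disks) inside each nucleus, in place."""
    i0 = 255.0
    gain = np.asarray(stain_gain, dtype=float)
    red_rgb = i0 * np.power(10.0, -(stain_matrix @ (gain * RED_DOT_CONC)))
    black_rgb = i0 * np.power(10.0, -(stain_matrix @ (gain * BLACK_DOT_CONC)))
    eroded = {}
    for lab in labels:
        sel = ndi.binary_erosion(mask == lab, iterations=2)
        if not sel.any():
            sel = mask == lab
        eroded[lab] = np.argwhere(sel)
    rr, cc = np.mgrid[-1:2, -1:2]
    disk = (rr**2 + cc**2) <= 1.3  # 5-px plus shape, ~1 px radius
    h, w = mask.shape
    for lab in labels:
        pix = eroded[lab]
        n_red, n_black = counts[lab]
        for color, k in ((red_rgb, n_red), (black_rgb, n_black)):
            for _ in range(k):
                r0, c0 = pix[rng.integers(len(pix))]
                rs = np.clip(r0 + rr[disk], 0, h - 1)
                cs = np.clip(c0 + cc[disk], 0, w - 1)
                img[rs, cs] = color


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate one fully reproducible scene from its config.

    The instance mask is a partition: overlaps between nuclei are resolved
    by z-order (the later-placed nucleus keeps contested pixels) while the
    ``overlaps_neighbor`` flag is recorded from the pre-resolution blobs.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    mask = np.zeros((h, w), dtype=np.int32)

    if config.n_nuclei == 0:
        image = _finalize_image(_render(mask, config, rng), config, rng)
        return SyntheticScene(image, mask, _empty_table(), config)

    placed = _place_nuclei(config, rng)
    blobs = []
    for i, p in enumerate(placed):
        blob = make_star_convex_blob(
            (p["row"], p["col"]),
            p["radius"],
            config.irregularity,
            seed=int(rng.integers(2**31)),
            shape=(h, w),
        )
        if not blob.any():
            raise GenerationError("a nucleus rasterized to zero area")
        blobs.append(blob)
        mask[blob] = i + 1

    labels = np.arange(1, len(placed) + 1)
    present = np.unique(mask[mask > 0])
    if len(present) != len(placed):
        raise GenerationError("z-order resolution erased a nucleus; retry with a new seed")

    overlap_flag = np.zeros(len(placed), dtype=bool)
    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            if np.any(blobs[i] & blobs[j]):
                overlap_flag[i] = overlap_flag[j] = True

    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touches = np.array([np.any((mask == lab) & border) for lab in labels])

    image = _render(mask, config, rng)
    counts = {
        int(lab): (
            int(rng.integers(config.red_signal_range[0], config.red_signal_range[1] + 1)),
            int(rng.integers(config.black_signal_range[0], config.black_signal_range[1] + 1)),
        )
        for lab in labels
    }
    _draw_dots(image, mask, labels, counts, config.stain_matrix, config.stain_gain, rng)
    image = _finalize_image(image, config, rng)

    rows = []
    for i, lab in enumerate(labels):
        sel = np.argwhere(mask == lab)
        rows.append(
            {
                "label": int(lab),
                "row": float(sel[:, 0].mean()),
                "col": float(sel[:, 1].mean()),
                "area": int(len(sel)),
                "red_signals": counts[int(lab)][0],
                "black_signals": counts[int(lab)][1],
                "touches_border": bool(touches[i]),
                "overlaps_neighbor": bool(overlap_flag[i]),
            }
        )
    return SyntheticScene(image, mask, pd.DataFrame(rows), config)


def _finalize_image(img: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_sd > 0:
        img = img + rng.normal(0, config.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "label", "row", "col", "area",
            "red_signals", "black_signals",
            "touches_border", "overlaps_neighbor",
        ]
    )


def save_scene(scene: SyntheticScene, out_dir: str | Path) -> None:
    """Write image.png, mask.tiff (16-bit), nuclei.csv and scene.json."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "image.png", scene.image)
    tifffile.imwrite(out / "mask.tiff", scene.mask.astype(np.uint16))
    scene.nuclei.to_csv(out / "nuclei.csv", index=False)
    (out / "scene.json").write_text(json.dumps(scene.config.to_dict(), indent=2))
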