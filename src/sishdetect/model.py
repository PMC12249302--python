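"""Trainable predictor of object probability and radial distances.

The network is a small pure-numpy convolutional encoder-decoder
(:mod:`sishdetect.nn`).  Training follows the detection recipe: binary
cross-entropy on the object-probability map plus a mean-absolute-error
distance term weighted by the ground-truth object probability, optimized
with SGD + momentum; augmentation is restricted to 90-degree rotations
and flips so radial distance targets transform exactly (by ray-index
permutation) without interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .errors import CheckpointError, ConfigError, ParameterError
from .nn import SGD, StarConvexNet
from .starconvex import DEFAULT_N_RAYS, RadialGroundTruth

F32 = np.float32


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the full-scale recipe (SGD, lr 1e-4, momentum 0.9,
    batch 4, 256-px patches, 100 epochs, 80:20 train-validation split);
    tests and the demo pipeline shrink epochs, patch size and the
    architecture, and raise the learning rate accordingly.
    """

    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 4
    epochs: int = 100
    patch_size: int = 256
    val_fraction: float = 0.2
    dist_loss_weight: float = 0.2
    n_rays: int = DEFAULT_N_RAYS
    depth: int = 3
    base_filters: int = 32
    dist_scale: float = 5.0
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ConfigError("val_fraction must lie strictly between 0 and 1")
        if self.patch_size % 2**self.depth:
            raise ConfigError("patch_size must be a multiple of 2^depth")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


@dataclass
class TrainingRecord:
    """Per-epoch loss bookkeeping; best epoch = argmin validation loss."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_prob_loss: list[float] = field(default_factory=list)
    train_dist_loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)  # 1 - thresholded prob error

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss))

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "train_prob_loss": self.train_prob_loss,
            "train_dist_loss": self.train_dist_loss,
            "accuracy": self.accuracy,
            "best_epoch": self.best_epoch,
        }


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Scale intensities to ~[0,1] by the 1st/99th percentile of the image."""
    x = np.asarray(image, dtype=F32)
    lo, hi = np.percentile(x, (1, 99))
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


class Predictor:
    """Wraps the network with input normalization and shape padding."""

    def __init__(self, net: StarConvexNet):
        self.net = net

    @property
    def n_rays(self) -> int:
        return self.net.n_rays

    def predict(
        self, image: np.ndarray, norm: tuple[float, float] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """RGB image (H,W,3) -> (prob (H,W) in [0,1], dist (H,W,R) >= 0).

        ``norm`` fixes the (low, high) intensity range used for scaling;
        tiled inference passes the whole image's percentiles so every
        tile sees the same normalization.
        """
        if norm is None:
            x = normalize_image(image)
        else:
            lo, hi = norm
            x = (np.asarray(image, dtype=F32) - lo) / max(hi - lo, 1e-6)
        h, w = x.shape[:2]
        m = 2**self.net.depth
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        xb = np.ascontiguousarray(x.transpose(2, 0, 1)[None]).astype(F32)
        logits, dist = self.net.forward(xb)
        prob = expit(logits[0])
        return prob[:h, :w], dist[0].transpose(1, 2, 0)[:h, :w]


def build_predictor(config: TrainConfig) -> Predictor:
    """Seeded construction; same config + seed gives identical parameters."""
    net = StarConvexNet(
        n_rays=config.n_rays,
        depth=config.depth,
        base_filters=config.base_filters,
        seed=config.seed,
        dist_scale=config.dist_scale,
    )
    return Predictor(net)


def loss_terms(
    prob_logits: np.ndarray,
    dist_pred: np.ndarray,
    target: RadialGroundTruth,
    dist_loss_weight: float,
) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """Combined loss and gradients for one (batched) prediction.

    prob term: mean binary cross-entropy between sigmoid(logits) and the
    binarized foreground (target.prob > 0).  dist term: mean absolute
    error over rays, weighted per-pixel by target.prob and normalized by
    the total weight; background pixels contribute nothing.
    """
    tprob = target.prob
    tdist = target.dist
    fg = (tprob > 0).astype(F32)
    n = fg.size
    p = expit(prob_logits)
    eps = 1e-7
    bce = float(-np.mean(fg * np.log(p + eps) + (1 - fg) * np.log(1 - p + eps)))
    dlogits = (p - fg) / n

    w = tprob.astype(F32)
    wsum = float(w.sum())
    diff = dist_pred - tdist
    if wsum > 0:
        dist_term = float((w[..., None] * np.abs(diff)).sum() / (wsum * diff.shape[-1]))
        ddist = dist_loss_weight * w[..., None] * np.sign(diff) / (wsum * diff.shape[-1])
    else:
        dist_term = 0.0
        ddist = np.zeros_like(diff)
    total = bce + dist_loss_weight * dist_term
    return total, bce, dist_term, dlogits.astype(F32), ddist.astype(F32)


def loss(
    pred: tuple[np.ndarray, np.ndarray],
    target: RadialGroundTruth,
    dist_loss_weight: float = 0.2,
) -> float:
    """Combined scalar loss for probabilities (not logits) and distances."""
    prob, dist = pred
    prob = np.clip(np.asarray(prob, dtype=F32), 1e-6, 1 - 1e-6)
    logits = np.log(prob) - np.log1p(-prob)
    if prob.shape != target.prob.shape or dist.shape != target.dist.shape:
        raise ParameterError("prediction and target shapes disagree")
    total, _, _, _, _ = loss_terms(logits, np.asarray(dist, dtype=F32), target, dist_loss_weight)
    return total


# -- augmentation ----------------------------------------------------------

def _ray_permutation(n_rays: int, rot_k: int, flip_h: bool, flip_v: bool) -> np.ndarray:
    """Index map: new ray k' draws from old ray perm[k'].

    Angles are theta_k = 2*pi*k/R with direction (sin, cos) in (row, col).
    Under np.rot90 (CCW), theta -> theta + pi/2; under left-right flip,
    theta -> pi - theta; under up-down flip, theta -> -theta.
    """
    # spatial ops apply rot -> flip_h -> flip_v; channel maps compose in
    # the opposite order (innermost transform acts on the index first)
    k = np.arange(n_rays)
    if flip_v:
        k = (-k) % n_rays
    if flip_h:
        k = (n_rays // 2 - k) % n_rays
    if rot_k % 4:
        k = (k + (rot_k % 4) * (n_rays // 4)) % n_rays
    return k


def augment_sample(
    image: np.ndarray,
    target: RadialGroundTruth,
    rot_k: int,
    flip_h: bool,
    flip_v: bool,
) -> tuple[np.ndarray, RadialGroundTruth]:
    """Apply a k*90-degree rotation and flips to an (image, target) pair.

    The distance maps are transformed spatially and by the exact ray-index
    permutation, which equals recomputing them from the transformed mask
    (the pixel lattice maps onto itself, so ray marching commutes with the
    transform).
    """
    if image.shape[0] != image.shape[1]:
        raise ParameterError("augmentation requires square patches")
    n_rays = target.dist.shape[-1]
    if n_rays % 4:
        raise ParameterError("n_rays must be divisible by 4 for 90-degree rotations")
    img, prob, dist = image, target.prob, target.dist
    if rot_k % 4:
        img = np.rot90(img, rot_k)
        prob = np.rot90(prob, rot_k)
        dist = np.rot90(dist, rot_k)
    if flip_h:
        img = img[:, ::-1]
        prob = prob[:, ::-1]
        dist = dist[:, ::-1]
    if flip_v:
        img = img[::-1]
        prob = prob[::-1]
        dist = dist[::-1]
    perm = _ray_permutation(n_rays, rot_k, flip_h, flip_v)
    dist = dist[..., perm]
    return np.ascontiguousarray(img), RadialGroundTruth(
        prob=np.ascontiguousarray(prob), dist=np.ascontiguousarray(dist)
    )


# -- training --------------------------------------------------------------

def _stack_batch(samples: list[tuple[np.ndarray, RadialGroundTruth]]):
    xs = np.stack([normalize_image(im).transpose(2, 0, 1) for im, _ in samples]).astype(F32)
    probs = np.stack([t.prob for _, t in samples]).astype(F32)
    dists = np.stack([t.dist.transpose(2, 0, 1) for _, t in samples]).astype(F32)
    return xs, RadialGroundTruth(prob=probs, dist=dists)


def _eval_loss(net: StarConvexNet, samples, lam: float) -> tuple[float, float]:
    """(mean loss, mean thresholded-prob accuracy) without gradients."""
    tot, acc = 0.0, 0.0
    for im, tgt in samples:
        xs, t = _stack_batch([(im, tgt)])
        logits, dist = net.forward(xs)
        dist = np.transpose(dist, (0, 2, 3, 1))
        t_im = RadialGroundTruth(prob=t.prob, dist=np.transpose(t.dist, (0, 2, 3, 1)))
        total, _, _, _, _ = loss_terms(logits, dist, t_im, lam)
        tot += total
        acc += float(np.mean((logits[0] > 0) == (t.prob[0] > 0)))
    return tot / len(samples), acc / len(samples)


def train(
    patches: list[tuple[np.ndarray, RadialGroundTruth]],
    config: TrainConfig,
) -> tuple[Predictor, TrainingRecord]:
    """SGD training with seeded shuffling/augmentation.

    Returns the parameters of the best validation epoch together with the
    full loss record.  Deterministic for a fixed config on a single CPU.
    """
    if len(patches) < 5:
        raise ParameterError("need at least 5 patches to train")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * len(patches))))
    order = rng.permutation(len(patches))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ParameterError("validation split left no training patches")
    val_set = [patches[i] for i in val_idx]
    train_set = [patches[i] for i in train_idx]

    predictor = build_predictor(config)
    net = predictor.net
    opt = SGD(net, lr=config.learning_rate, momentum=config.momentum)
    record = TrainingRecord()
    lam = config.dist_loss_weight
    best_val = np.inf
    best_weights = net.get_weights()

    for epoch in range(config.epochs):
        perm = rng.permutation(len(train_set))
        ep_tot, ep_bce, ep_dist, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            samples = []
            for i in idx:
                im, tgt = train_set[i]
                if config.augment:
                    samples.append(
                        augment_sample(
                            im, tgt,
                            rot_k=int(rng.integers(4)),
                            flip_h=bool(rng.integers(2)),
                            flip_v=bool(rng.integers(2)),
                        )
                    )
                else:
                    samples.append((im, tgt))
            xs, t = _stack_batch(samples)
            logits, dist = net.forward(xs)
            dist_hw = np.transpose(dist, (0, 2, 3, 1))
            t_hw = RadialGroundTruth(prob=t.prob, dist=np.transpose(t.dist, (0, 2, 3, 1)))
            total, bce, dterm, dlogits, ddist = loss_terms(logits, dist_hw, t_hw, lam)
            if not np.isfinite(total):
                raise ArithmeticError(
                    f"non-finite loss at epoch {epoch}: bce={bce} dist={dterm}; "
                    "reduce the learning rate"
                )
            net.zero_grad()
            net.backward(dlogits, np.transpose(ddist, (0, 3, 1, 2)))
            opt.step()
            ep_tot += total
            ep_bce += bce
            ep_dist += dterm
            n_batches += 1
        val, acc = _eval_loss(net, val_set, lam)
        record.train_loss.append(ep_tot / n_batches)
        record.train_prob_loss.append(ep_bce / n_batches)
        record.train_dist_loss.append(ep_dist / n_batches)
        record.val_loss.append(val)
        record.accuracy.append(acc)
        if val < best_val:
            best_val = val
            best_weights = net.get_weights()
    net.set_weights(best_weights)
    return predictor, record


# -- checkpoint I/O --------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    predictor: Predictor,
    config: TrainConfig,
    record: TrainingRecord | None = None,
) -> None:
    """Write <path>.json (architecture + record) and <path>.npz (weights)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_rays": predictor.net.n_rays,
        "depth": predictor.net.depth,
        "base_filters": predictor.net.base_filters,
        "in_channels": predictor.net.in_channels,
        "dist_scale": predictor.net.dist_scale,
        "train_config": {
            k: getattr(config, k)
            for k in TrainConfig.__dataclass_fields__
        },
        "record": record.to_dict() if record is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(path.with_suffix(".npz"), weights=predictor.net.flat_weights())


def load_checkpoint(path: str | Path) -> tuple[Predictor, dict]:
    path = Path(path)
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
        blob = np.load(path.with_suffix(".npz"))
        net = StarConvexNet(
            n_rays=meta["n_rays"],
            depth=meta["depth"],
            base_filters=meta["base_filters"],
            in_channels=meta["in_channels"],
            dist_scale=meta.get("dist_scale", 5.0),
        )
        net.set_flat_weights(blob["weights"])
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"cannot load checkpoint {path}: {exc}") from exc
    return Predictor(net), meta
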