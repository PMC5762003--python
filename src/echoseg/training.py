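"""Loss, Adam optimizer loop, diagnostics, and leave-one-patient-out runs.

The loss is a probabilistic (soft) Dice with label smoothing plus an L2
penalty on convolution kernels.  Training runs a fixed number of Adam
iterations over shuffled (image, operator-label) mini-batches, optionally
with on-the-fly affine augmentation, recording the loss each iteration
and, optionally, histograms of the last activation at a fixed cadence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import preprocess
from .network import Model, NetworkSpec, build_model, predict
from .postprocess import SegmentationMask, postprocess_probmap

__all__ = [
    "TrainConfig",
    "FoldResult",
    "soft_dice_loss",
    "soft_dice_loss_grad",
    "total_loss",
    "Adam",
    "train",
    "run_lopo",
]

logger = logging.getLogger(__name__)

DICE_STABILIZER = 1e-5


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    iterations: int = 3000
    label_smoothing: float = 0.1
    l2_weight: float = 1e-5
    seed: int = 0
    augment: bool = True
    affine_ranges: preprocess.AffineRanges = field(default_factory=preprocess.AffineRanges)
    frame_shape: tuple = preprocess.FRAME_SHAPE
    train_shape: tuple = preprocess.TRAIN_SHAPE
    histogram_every: int = 0  # 0 disables activation histograms
    record_test_dice_every: int = 0

    @classmethod
    def unet_dc_preset(cls, **kw):
        """Dilated-convolution preset: higher learning rate, small batches."""
        return cls(learning_rate=1e-3, batch_size=10, **kw)


@dataclass
class FoldResult:
    fold_id: str
    model: Model
    loss_trace: np.ndarray
    test_probmaps: dict = field(default_factory=dict)  # image_id -> prob map
    activation_hist: list = field(default_factory=list)  # (iteration, counts, bin_edges)
    test_dice_trace: list = field(default_factory=list)  # (iteration, mean dice)


def _smooth_labels(labels, eps):
    """Map binary labels to {eps, 1-eps}."""
    g = np.asarray(labels, dtype=np.float64)
    return g * (1.0 - 2.0 * eps) + eps


def soft_dice_loss(probs, labels, label_smoothing=0.0):
    """1 - soft Dice with label smoothing, averaged over the batch.

    Per sample: ``1 - (2*sum(p*g') + s) / (sum(p) + sum(g') + s)`` with the
    smoothed labels ``g' in {eps, 1-eps}`` and stabilizer ``s = 1e-5``.
    """
    if not 0.0 <= label_smoothing < 0.5:
        raise ValueError("label_smoothing must be in [0, 0.5)")
    p = np.asarray(probs, dtype=np.float64)
    g = _smooth_labels(labels, label_smoothing)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.ndim == 2:
        p, g = p[None], g[None]
    ax = tuple(range(1, p.ndim))
    s = DICE_STABILIZER
    num = 2.0 * (p * g).sum(axis=ax) + s
    den = p.sum(axis=ax) + g.sum(axis=ax) + s
    return float(np.mean(1.0 - num / den))


def soft_dice_loss_grad(probs, labels, label_smoothing=0.0):
    """Gradient of :func:`soft_dice_loss` with respect to ``probs``."""
    p = np.asarray(probs, dtype=np.float64)
    g = _smooth_labels(labels, label_smoothing)
    squeeze = p.ndim == 2
    if squeeze:
        p, g = p[None], g[None]
    ax = tuple(range(1, p.ndim))
    s = DICE_STABILIZER
    num = 2.0 * (p * g).sum(axis=ax, keepdims=True) + s
    den = p.sum(axis=ax, keepdims=True) + s + g.sum(axis=ax, keepdims=True)
    grad = -(2.0 * g * den - num) / den**2 / p.shape[0]
    return grad[0] if squeeze else grad


def total_loss(dice_loss, model, l2_weight):
    """dice_loss + l2_weight * sum of squared kernel weights.

    Biases and normalization parameters are excluded from the penalty.
    ``model`` may be a :class:`Model` or a bare parameter list of
    (name, array, grad, is_kernel) tuples.
    """
    if l2_weight < 0:
        raise ValueError("l2_weight must be >= 0")
    if hasattr(model, "l2_penalty"):
        pen = model.l2_penalty()
    else:
        pen = float(sum(np.sum(np.asarray(a, dtype=np.float64) ** 2) for _, a, _, k in model if k))
    return float(dice_loss) + l2_weight * pen


class Adam:
    """Adam with standard defaults (beta1 0.9, beta2 0.999)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (name, array, grad, is_kernel)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p[1]) for p in params]
        self.v = [np.zeros_like(p[1]) for p in params]
        self.t = 0

    def step(self, l2_weight=0.0):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (name, arr, grad, is_kernel), m, v in zip(self.params, self.m, self.v):
            g = grad
            if l2_weight and is_kernel:
                g = g + 2.0 * l2_weight * arr
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            arr -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _prepare_samples(dataset, config: TrainConfig):
    """Standardize+resize every (image, operator) pair to the train shape."""
    from .phantom import AnnotatedImage

    prepped = []
    for img in dataset:
        std_im, _ = preprocess.standardize_frame(img.image, config.frame_shape, kind="image")
        ops = []
        for om in img.operator_masks:
            std_mk, _ = preprocess.standardize_frame(om, config.frame_shape, kind="mask")
            im_s, mk_s = preprocess.resize_pair(std_im, std_mk, config.train_shape)
            ops.append(mk_s)
        im_s, _ = preprocess.resize_pair(
            std_im, np.zeros_like(std_im, dtype=bool), config.train_shape
        )
        prepped.append(
            AnnotatedImage(img.patient_id, img.image_id, img.stage, im_s.astype(np.float32),
                           img.spacing, np.zeros_like(im_s, dtype=bool), ops)
        )
    return prepped


def train(spec: NetworkSpec, trainset, config: TrainConfig, test_images=None):
    """Train a model for ``config.iterations`` Adam steps.

    ``trainset`` is a list of AnnotatedImages (any sizes); each is
    standardized to ``config.frame_shape`` and resized to
    ``config.train_shape`` once up front, with augmentation applied
    on-the-fly per sample.  Records the loss every iteration; optional
    activation histograms every ``config.histogram_every`` iterations and
    held-out Dice (against ``test_images`` true masks) at the configured
    cadence.  Fully deterministic for a fixed config.

    Raises
    ------
    FloatingPointError
        If the loss becomes non-finite (message names the iteration).
    """
    if not trainset:
        raise ValueError("empty trainset")
    model = build_model(spec, seed=config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    prepped = _prepare_samples(trainset, config)
    aug_rng = np.random.default_rng(config.seed + 7)

    result = FoldResult(fold_id="", model=model, loss_trace=np.zeros(config.iterations))
    it = 0
    epoch = 0
    while it < config.iterations:
        for batch in preprocess.make_minibatches(prepped, config.batch_size, seed=config.seed + epoch):
            if it >= config.iterations:
                break
            imgs, labs = batch.images, batch.labels
            if config.augment:
                aug_i, aug_l = [], []
                for im, lb in zip(imgs, labs):
                    s = int(aug_rng.integers(0, 2**31))
                    ai, al = preprocess.random_affine(im, lb, config.affine_ranges, seed=s)
                    aug_i.append(ai)
                    aug_l.append(al)
                imgs = np.stack(aug_i).astype(np.float32)
                labs = np.stack(aug_l)
            capture = config.histogram_every and (it + 1) % config.histogram_every == 0
            probs = model.forward(imgs, training=True, capture_last_selu=capture)
            dloss = soft_dice_loss(probs, labs, config.label_smoothing)
            loss = total_loss(dloss, model, config.l2_weight)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at iteration {it}")
            result.loss_trace[it] = loss
            model.backward(soft_dice_loss_grad(probs, labs, config.label_smoothing).astype(np.float32))
            opt.step(l2_weight=config.l2_weight)
            if capture:
                act = model.last_activation
                counts, edges = np.histogram(act, bins=50)
                result.activation_hist.append((it + 1, counts, edges))
                model.last_activation = None
            if (
                config.record_test_dice_every
                and test_images
                and (it + 1) % config.record_test_dice_every == 0
            ):
                result.test_dice_trace.append((it + 1, _mean_test_dice(model, test_images, config)))
            it += 1
        epoch += 1
    return result


def _mean_test_dice(model, test_images, config):
    from .metrics import region_metrics

    dices = []
    for img in test_images:
        mask = segment_image(model, img.image, config)
        dices.append(region_metrics(mask.grid, img.true_mask)[0])
    return float(np.mean(dices))


def segment_image(model, image, config: TrainConfig, spacing=1.0):
    """Full-resolution automatic segmentation of one raw frame.

    Standardize -> resize -> predict -> upsample the probability map to the
    frame shape -> morphological postprocess -> map back through the
    recorded crop/pad offsets to the original image size.
    """
    std_im, placement = preprocess.standardize_frame(image, config.frame_shape, kind="image")
    im_s, _ = preprocess.resize_pair(std_im, np.zeros_like(std_im, dtype=bool), config.train_shape)
    prob_small = predict(model, im_s.astype(np.float32))
    prob_frame, _ = preprocess.resize_pair(
        prob_small.astype(np.float64), np.zeros_like(prob_small, dtype=bool), config.frame_shape
    )
    mask_frame = postprocess_probmap(np.clip(prob_frame, 0.0, 1.0))
    full = preprocess.unstandardize_frame(mask_frame.grid.astype(np.uint8), placement).astype(bool)
    return SegmentationMask(full, spacing, "automatic")


def run_lopo(dataset, spec: NetworkSpec, config: TrainConfig, progress=False):
    """Leave-one-patient-out cross validation.

    One fold per patient: train on all other patients (fresh seeded
    initialization, seed = config.seed + fold index), then segment the
    left-out patient's images at full frame resolution.  Returns a list of
    ``(image_id, SegmentationMask)`` covering every image exactly once,
    plus the per-fold results, as ``(outputs, fold_results)``.
    """
    patients = []
    for img in dataset:
        if img.patient_id not in patients:
            patients.append(img.patient_id)
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    by_patient = {p: [im for im in dataset if im.patient_id == p] for p in patients}
    for p, imgs in by_patient.items():
        if not imgs:
            raise ValueError(f"patient {p!r} has no images")

    outputs = []
    folds = []
    for k, pid in enumerate(patients):
        trainset = [im for im in dataset if im.patient_id != pid]
        fold_cfg = replace(config, seed=config.seed + k)
        if progress:
            logger.info("LOPO fold %d/%d: leaving out %s", k + 1, len(patients), pid)
        res = train(spec, trainset, fold_cfg)
        res.fold_id = pid
        for img in by_patient[pid]:
            mask = segment_image(res.model, img.image, fold_cfg, spacing=img.spacing)
            res.test_probmaps[img.image_id] = mask
            outputs.append((img.image_id, mask))
        folds.append(res)
    return outputs, folds
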