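"""Trainable segmentation and edge-detection models plus augmentation.

The segmenter is a convolutional-feature pixel classifier: each pixel is
described by a fixed multiscale filter bank (Gaussian smoothings, gradient
magnitudes, a Laplacian of Gaussian, and normalized image coordinates) and
classified by a one-hidden-layer network with per-chamber sigmoid outputs,
trained with the Adam optimizer on soft Dice loss over image minibatches.
Gradients are derived analytically (the model is small enough that no
autodiff framework is needed) and every source of randomness is seeded, so
training is bit-reproducible.

The same model class doubles as the edge detector: trained on boundary
targets with a single output channel, its gradient-magnitude features make
edge probability directly learnable.

The A2C segmenter deliberately omits the lateral-coordinate feature: a model
that cannot see laterality, applied to a four-chamber view, marks *both*
ventricles as its ventricle class and both atria as its atrium class —
exactly the two-plus-two prediction the four-chamber relabelling stage
consumes.  The A4C model re-enables the feature to separate left from right.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage
import skimage.exposure
import skimage.transform

from .datatypes import Chamber, ChamberMaskSet, Provenance, UltrasoundFrame, View
from .errors import ModelError, ShapeError

__all__ = [
    "soft_dice_loss",
    "AugmentationPolicy",
    "augment_pair",
    "SegmenterConfig",
    "PixelSegmenter",
    "TrainResult",
    "predict_masks",
]


# --------------------------------------------------------------------------
# soft Dice loss
# --------------------------------------------------------------------------

def soft_dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss, averaged over channels.

    ``loss = 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)`` per channel;
    inputs are ``(..., C)`` probability and binary grids (or unchannelled
    2-D grids, treated as one channel).
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ShapeError("pred and target shapes differ")
    if p.ndim == 2:
        p = p[..., None]
        t = t[..., None]
    axes = tuple(range(p.ndim - 1))
    num = 2.0 * (p * t).sum(axis=axes) + smooth
    den = p.sum(axis=axes) + t.sum(axis=axes) + smooth
    return float(np.mean(1.0 - num / den))


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

@dataclass
class AugmentationPolicy:
    """Random training-time modifications applied to ~20% of examples.

    Geometric transforms are applied jointly to image and masks (nearest
    neighbour for masks, so they stay binary); photometric transforms touch
    the image only.  The edge-detector profile narrows zoom to +/-8% and
    drops the photometric set.
    """

    apply_fraction: float = 0.2
    rotation_max_deg: float = 10.0
    shift_fraction: float = 0.10
    zoom_fraction: float = 0.20
    shear_max: float = 0.03
    horizontal_flip: bool = True
    contrast_stretch: bool = True          # 2nd-98th percentile
    crop_size: Optional[int] = 160         # random crop, resized back
    downscale_range: tuple[float, float] = (0.25, 0.5)
    pixel_dropout: float = 0.1
    median_blur: bool = True
    noise_var_range: tuple[float, float] = (0.03, 0.2)
    clahe_clip: float = 0.02
    tone_curve_scale: float = 0.1
    photometric: bool = True

    @classmethod
    def edge_profile(cls) -> "AugmentationPolicy":
        return cls(
            zoom_fraction=0.08,
            contrast_stretch=False,
            crop_size=None,
            pixel_dropout=0.0,
            median_blur=False,
            clahe_clip=0.0,
            tone_curve_scale=0.0,
            photometric=False,
        )


def _warp_pair(img, masks, transform):
    shape = img.shape
    out_img = skimage.transform.warp(img, transform.inverse, order=1, preserve_range=True)
    out_masks = {
        ch: skimage.transform.warp(
            m.astype(np.float64), transform.inverse, order=0, preserve_range=True
        )
        > 0.5
        for ch, m in masks.items()
    }
    return np.clip(out_img, 0, 1), out_masks


def augment_pair(
    frame: UltrasoundFrame,
    masks: ChamberMaskSet,
    policy: Optional[AugmentationPolicy] = None,
    seed: int = 0,
) -> tuple[UltrasoundFrame, ChamberMaskSet]:
    """Jointly augment one (frame, masks) pair; deterministic in the seed."""
    policy = policy or AugmentationPolicy()
    rng = np.random.default_rng([seed, 55021])
    img = frame.pixels.copy()
    mdict = {ch: m.copy() for ch, m in masks.masks.items()}
    if rng.random() >= policy.apply_fraction:
        return frame, masks

    n = img.shape[0]
    center = np.array(img.shape)[::-1] / 2.0
    angle = np.deg2rad(rng.uniform(0, policy.rotation_max_deg))
    zoom = 1.0 + rng.uniform(-policy.zoom_fraction, policy.zoom_fraction)
    shear = rng.uniform(0, policy.shear_max)
    shift = rng.uniform(-policy.shift_fraction, policy.shift_fraction, size=2) * n
    tf = (
        skimage.transform.AffineTransform(translation=-center)
        + skimage.transform.AffineTransform(
            rotation=angle, scale=(zoom, zoom), shear=shear
        )
        + skimage.transform.AffineTransform(translation=center + shift)
    )
    img, mdict = _warp_pair(img, mdict, tf)
    if policy.horizontal_flip and rng.random() < 0.5:
        img = img[:, ::-1].copy()
        mdict = {ch: m[:, ::-1].copy() for ch, m in mdict.items()}
    if policy.crop_size and policy.crop_size < n and rng.random() < 0.5:
        c = policy.crop_size
        r0 = rng.integers(0, n - c)
        c0 = rng.integers(0, n - c)
        img = skimage.transform.resize(img[r0: r0 + c, c0: c0 + c], (n, n), order=1)
        mdict = {
            ch: skimage.transform.resize(
                m[r0: r0 + c, c0: c0 + c].astype(float), (n, n), order=0
            )
            > 0.5
            for ch, m in mdict.items()
        }

    if policy.photometric:
        if policy.contrast_stretch and rng.random() < 0.5:
            p2, p98 = np.percentile(img, (2, 98))
            if p98 > p2:
                img = np.clip((img - p2) / (p98 - p2), 0, 1)
        if rng.random() < 0.5:
            lo, hi = policy.downscale_range
            f = rng.uniform(lo, hi)
            small = skimage.transform.resize(img, (max(2, int(n * f)),) * 2, order=1)
            img = skimage.transform.resize(small, (n, n), order=1)
        if policy.pixel_dropout > 0 and rng.random() < 0.5:
            img = np.where(rng.random(img.shape) < policy.pixel_dropout, 0.0, img)
        if policy.median_blur and rng.random() < 0.5:
            img = scipy.ndimage.median_filter(img, size=3)
        if rng.random() < 0.5:
            var = rng.uniform(*policy.noise_var_range)
            img = np.clip(img + rng.normal(0, np.sqrt(var), img.shape), 0, 1)
        if policy.clahe_clip > 0 and rng.random() < 0.5:
            img = skimage.exposure.equalize_adapthist(
                np.clip(img, 0, 1), clip_limit=policy.clahe_clip
            )
        if policy.tone_curve_scale > 0 and rng.random() < 0.5:
            gamma = float(np.exp(rng.normal(0, policy.tone_curve_scale)))
            img = np.clip(img, 0, 1) ** gamma

    out_frame = frame.copy_with(pixels=np.clip(img, 0, 1))
    out_masks = ChamberMaskSet(
        masks=mdict,
        pixel_spacing=masks.pixel_spacing,
        provenance=masks.provenance,
        view=masks.view,
    )
    return out_frame, out_masks


# --------------------------------------------------------------------------
# the pixel-classifier segmenter
# --------------------------------------------------------------------------

@dataclass
class SegmenterConfig:
    """Segmenter hyperparameters.

    ``input_size`` 256 with the listed defaults mirrors the full
    segmentation profile (sigmoid output, Adam at 1e-4, soft Dice, batch
    32); the ``tiny`` profile shrinks the grid and raises the learning rate
    to suit the much smaller pixel-classifier trained for seconds on a CPU.
    ``use_lateral_feature`` gates the signed column coordinate (see module
    docstring).
    """

    chambers: tuple[Chamber, ...] = (Chamber.LV, Chamber.LA)
    input_size: int = 256
    hidden_width: int = 16
    learning_rate: float = 1e-4
    batch_size: int = 32
    smooth: float = 1.0
    use_lateral_feature: bool = False
    feature_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)
    seed: int = 0

    @classmethod
    def tiny(cls, chambers: Sequence[Chamber], **kw) -> "SegmenterConfig":
        defaults = dict(
            chambers=tuple(chambers),
            input_size=64,
            hidden_width=12,
            learning_rate=0.03,
            batch_size=8,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class TrainResult:
    """Per-epoch validation losses and checkpointed weights from a fit."""

    train_loss: np.ndarray
    validation_loss: np.ndarray
    checkpoints: list[dict] = field(default_factory=list, repr=False)


class PixelSegmenter:
    """Filter-bank pixel classifier with a one-hidden-layer head.

    ``fit`` checkpoints the weights at every epoch so the caller can rewind
    to the early-learning elbow after inspecting the validation loss curve.
    """

    def __init__(self, config: SegmenterConfig):
        self.config = config
        self._params: Optional[dict[str, np.ndarray]] = None
        self._norm: Optional[tuple[np.ndarray, np.ndarray]] = None  # feature mean/sd

    # -- features ----------------------------------------------------------
    def n_features(self) -> int:
        # raw, (gauss+grad) per sigma, LoG, depth, fan indicator, fan distance
        base = 1 + len(self.config.feature_sigmas) * 2 + 1 + 3
        return base + (1 if self.config.use_lateral_feature else 0)

    def extract_features(self, image: np.ndarray) -> np.ndarray:
        """(H, W, F) feature stack for one image.

        Beyond the intensity filter bank and the depth coordinate, two
        image-derived sector features — an inside-the-fan indicator (convex
        hull of above-background pixels) and the normalized distance to the
        fan boundary — separate dark blood pools from the dark corners
        outside the imaging sector without encoding laterality, so a model
        trained on one apical view transfers to the other.  The *signed*
        lateral coordinate is the optional feature that breaks left/right
        symmetry.
        """
        import skimage.morphology

        img = np.asarray(image, dtype=np.float64)
        feats = [img]
        for s in self.config.feature_sigmas:
            feats.append(scipy.ndimage.gaussian_filter(img, s))
            feats.append(scipy.ndimage.gaussian_gradient_magnitude(img, s))
        feats.append(scipy.ndimage.gaussian_laplace(img, self.config.feature_sigmas[1]))
        h, w = img.shape
        rows = np.broadcast_to(np.linspace(0, 1, h)[:, None], (h, w))
        feats.append(rows)
        bright = img > 0.02
        fan = (
            skimage.morphology.convex_hull_image(bright)
            if bright.any()
            else np.zeros_like(bright)
        )
        feats.append(fan.astype(np.float64))
        dist = scipy.ndimage.distance_transform_edt(fan) / (0.5 * max(h, w))
        feats.append(dist)
        if self.config.use_lateral_feature:
            cols = np.broadcast_to(np.linspace(-0.5, 0.5, w)[None, :], (h, w))
            feats.append(cols)
        return np.stack(feats, axis=-1)

    # -- forward / backward ------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        f, h, c = self.n_features(), self.config.hidden_width, len(self.config.chambers)
        # output biases start negative so every head begins near-empty: the
        # Dice gradient then grows each head from its own target region,
        # which keeps the per-chamber heads from collapsing onto one another
        return {
            "W1": rng.normal(0, np.sqrt(2.0 / f), size=(f, h)),
            "b1": np.zeros(h),
            "W2": rng.normal(0, np.sqrt(2.0 / h), size=(h, c)),
            "b2": np.full(c, -3.0),
        }

    @staticmethod
    def _forward(params, X):
        z1 = X @ params["W1"] + params["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ params["W2"] + params["b2"]
        p = 1.0 / (1.0 + np.exp(-z2))
        return z1, a1, p

    def _loss_and_grads(self, params, X, T):
        """Soft-Dice loss over a flattened pixel batch, with gradients."""
        eps = self.config.smooth
        z1, a1, p = self._forward(params, X)
        num = 2.0 * (p * T).sum(axis=0) + eps
        den = p.sum(axis=0) + T.sum(axis=0) + eps
        loss = float(np.mean(1.0 - num / den))
        C = T.shape[1]
        # d(loss)/dp = -(2*T*den - num) / den^2 / C
        dp = -(2.0 * T * den - num) / (den**2) / C
        dz2 = dp * p * (1.0 - p)
        grads = {
            "W2": a1.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        da1 = dz2 @ params["W2"].T
        dz1 = da1 * (z1 > 0)
        grads["W1"] = X.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return loss, grads

    # -- training ----------------------------------------------------------
    def fit(
        self,
        images: Sequence[np.ndarray],
        targets: Sequence[np.ndarray],
        val_images: Sequence[np.ndarray] = (),
        val_targets: Sequence[np.ndarray] = (),
        epochs: int = 20,
        augmentation: Optional[AugmentationPolicy] = None,
        seed: Optional[int] = None,
    ) -> TrainResult:
        """Train with Adam on soft Dice loss; checkpoint every epoch.

        ``targets`` are (H, W, C) binary stacks ordered as
        ``config.chambers``.  Validation loss is computed on the held-out
        pairs after each epoch (on the training set when none are given).
        """
        cfg = self.config
        if len(images) == 0:
            raise ModelError("no training images")
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng([seed, 77001])
        params = self._init_params(rng) if self._params is None else {
            k: v.copy() for k, v in self._params.items()
        }
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        step = 0

        feats = [self.extract_features(im) for im in images]
        if self._norm is None:
            flat = np.concatenate([f.reshape(-1, self.n_features()) for f in feats])
            self._norm = (flat.mean(axis=0), flat.std(axis=0) + 1e-6)
        mu, sd = self._norm
        feats = [(f - mu) / sd for f in feats]
        val_feats = [(self.extract_features(im) - mu) / sd for im in val_images]
        if not val_feats:
            val_feats, val_targets = feats, targets

        n = len(feats)
        train_hist, val_hist, checkpoints = [], [], []
        for _epoch in range(epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start: start + cfg.batch_size]
                X = np.concatenate([feats[i].reshape(-1, self.n_features()) for i in idx])
                T = np.concatenate(
                    [np.asarray(targets[i], dtype=np.float64).reshape(-1, len(cfg.chambers)) for i in idx]
                )
                loss, grads = self._loss_and_grads(params, X, T)
                epoch_losses.append(loss)
                step += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    params[k] = params[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
            train_hist.append(float(np.mean(epoch_losses)))
            val_hist.append(self._evaluate(params, val_feats, val_targets))
            checkpoints.append({k: p.copy() for k, p in params.items()})
        self._params = params
        return TrainResult(
            train_loss=np.asarray(train_hist),
            validation_loss=np.asarray(val_hist),
            checkpoints=checkpoints,
        )

    def _evaluate(self, params, feats, targets) -> float:
        losses = []
        for f, t in zip(feats, targets):
            _, _, p = self._forward(params, f.reshape(-1, self.n_features()))
            losses.append(
                soft_dice_loss(
                    p.reshape(f.shape[0], f.shape[1], -1),
                    np.asarray(t, dtype=np.float64),
                    smooth=self.config.smooth,
                )
            )
        return float(np.mean(losses))

    def load_checkpoint(self, checkpoint: dict) -> None:
        self._params = {k: np.asarray(p).copy() for k, p in checkpoint.items()}

    # -- inference ---------------------------------------------------------
    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """(H, W, C) per-chamber probabilities."""
        if self._params is None:
            raise ModelError("model is untrained")
        f = self.extract_features(image)
        if self._norm is not None:
            f = (f - self._norm[0]) / self._norm[1]
        _, _, p = self._forward(self._params, f.reshape(-1, self.n_features()))
        return p.reshape(image.shape[0], image.shape[1], -1)

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> Path:
        """Weights as NPZ plus a JSON manifest (config and layer shapes)."""
        if self._params is None:
            raise ModelError("nothing to save: model is untrained")
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        arrays = dict(self._params)
        if self._norm is not None:
            arrays["feat_mu"], arrays["feat_sd"] = self._norm
        np.savez(out / "weights.npz", **arrays)
        cfg = asdict(self.config)
        cfg["chambers"] = [c.value for c in self.config.chambers]
        manifest = {
            "config": cfg,
            "layers": {k: list(p.shape) for k, p in self._params.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return out

    @classmethod
    def load(cls, directory) -> "PixelSegmenter":
        root = Path(directory)
        with open(root / "manifest.json") as fh:
            manifest = json.load(fh)
        cfg = manifest["config"]
        cfg["chambers"] = tuple(Chamber(c) for c in cfg["chambers"])
        for key in ("feature_sigmas",):
            cfg[key] = tuple(cfg[key])
        model = cls(SegmenterConfig(**cfg))
        npz = np.load(root / "weights.npz")
        model._params = {k: npz[k] for k in npz.files if not k.startswith("feat_")}
        if "feat_mu" in npz.files:
            model._norm = (npz["feat_mu"], npz["feat_sd"])
        return model


def _largest_components(mask: np.ndarray, keep: int) -> np.ndarray:
    import skimage.measure

    labels = skimage.measure.label(mask)
    if labels.max() <= keep:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    top = np.argsort(sizes)[::-1][:keep] + 1
    return np.isin(labels, top)


def predict_masks(
    model: PixelSegmenter,
    frame: UltrasoundFrame,
    keep_components: int = 1,
) -> ChamberMaskSet:
    """Threshold model probabilities into a mask set (provenance: model).

    Probabilities are thresholded strictly above 0.5 (ties go to
    background); per chamber, the ``keep_components`` largest connected
    components are kept.
    """
    if frame.pixels.shape[0] != model.config.input_size:
        raise ModelError(
            f"frame grid {frame.pixels.shape} does not match model input "
            f"{model.config.input_size}"
        )
    proba = model.predict_proba(frame.pixels)
    masks = {}
    for i, ch in enumerate(model.config.chambers):
        binary = proba[..., i] > 0.5
        masks[ch] = _largest_components(binary, keep_components) if binary.any() else binary
    return ChamberMaskSet(
        masks=masks,
        pixel_spacing=frame.pixel_spacing,
        provenance=Provenance.MODEL,
        view=frame.view,
    )
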