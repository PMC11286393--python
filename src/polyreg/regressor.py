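"""Quadratic-transform parameter regression and its two-stage training.

The regressor is a compact CNN that maps a (fixed, moving) image pair —
stacked as two channels, scaled to [-1, 1] — to the 12 parameters of
the quadratic transform aligning them, expressed on the [0, 1]
normalized scale.  Training has two stages:

1. **Supervised pretraining on synthetic mask pairs.**  Binary
   field-of-view masks are warped by known random transforms and the
   network minimizes the hybrid MSLE + cosine loss against the exact
   normalized parameters.  Masks strip away local texture so the
   network learns the global geometry of the transformation family.

2. **Unsupervised fine-tuning on image pairs.**  No ground truth: the
   predicted parameters are denormalized, the moving image is warped
   through the differentiable polynomial transformation layer, and the
   network minimizes ``1 - NCC`` between the fixed and warped images.
   Gradients flow through the bilinear interpolation back to the
   parameters.

The default ``tiny_cnn`` backbone is 4 conv blocks + global max pooling
+ a linear 12-output head (~300k parameters), sized for CPU training.
Normalized coordinate channels (linear and quadratic) and
foreground-gated coordinate products are appended to the input before
the first convolution: global max pooling is translation-invariant, so
a shallow network needs an explicit positional basis to regress
position-dependent parameters (a very deep backbone can recover
position from padding effects; a 4-block one cannot), and the pooled
gated products act as support-function samples of each shape.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from typing import Iterator, Sequence

import numpy as np

from . import _nn
from .losses_metrics import HybridLossConfig, hybrid_loss_and_grad, ncc, ncc_and_grad
from .polywarp import (
    QuadraticTransform,
    bilinear_sample,
    denormalize_params,
    design_vector,
    rescale_transform,
    warp_image,
)
from .preprocess import PreprocessConfig, hybrid_preprocess, resize_and_scale
from .synthgen import ParameterRanges, RegistrationPair

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedRegressor",
    "build_model",
    "take_batches",
    "pretrain",
    "finetune",
    "predict",
    "predict_batch",
    "register",
    "save_checkpoint",
    "load_checkpoint",
]

_LOG_FLOOR = -0.999  # keep predictions inside the log1p domain of the MSLE term


def _lr_at(cfg: "TrainConfig", step: int, total_steps: int) -> float:
    """Learning rate at ``step``: the configured initial rate, optionally
    decayed along a cosine schedule to a 5% floor."""
    if cfg.lr_schedule == "constant" or total_steps <= 1:
        return cfg.learning_rate
    frac = min(step / max(total_steps - 1, 1), 1.0)
    cosine = 0.5 * (1 + np.cos(np.pi * frac))
    return cfg.learning_rate * (0.05 + 0.95 * cosine)


@dataclass
class ModelConfig:
    """Architecture settings for the parameter regressor."""

    backbone: str = "tiny_cnn"
    input_channels: int = 2
    input_size: tuple[int, int] = (64, 64)
    n_params: int = 12
    channels: tuple[int, ...] = (16, 32, 64, 128)
    convs_per_block: int = 1
    first_kernel: int = 3
    multiscale_head: bool = True
    coord_channels: bool = True
    quadratic_coords: bool = True
    product_channels: bool = True

    def __post_init__(self):
        if self.backbone not in ("tiny_cnn", "efficientnet_v2"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.input_channels != 2:
            raise ValueError("the regressor takes a 2-channel (fixed, moving) pair")


@dataclass
class TrainConfig:
    """Optimization settings shared by both training stages.

    An "epoch" of the on-the-fly stream is ``steps_per_epoch`` fresh
    batches; convergence is operationalized as patience-based early
    stopping on the validation loss.  ``finetune_lr_factor`` shrinks
    the learning rate when fine-tuning from pretrained weights.
    """

    learning_rate: float = 1e-3
    lr_schedule: str = "cosine"  # {"constant", "cosine"} decay from the initial rate
    batch_size: int = 32
    max_epochs: int = 50
    steps_per_epoch: int = 100
    patience: int = 10
    seed: int = 0
    omega: float = 0.5
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    finetune_lr_factor: float = 0.1
    clip_lo: float = -0.25
    clip_hi: float = 1.25

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


class _TinyCNN:
    """4 conv blocks + global max pooling + linear head, explicit backprop.

    Each block is ``convs_per_block`` 3x3 convolutions (the last one
    strided) with ReLUs.  With ``multiscale_head`` the head sees the
    concatenated global max pool of *every* block's output — coarse
    blocks summarize global geometry while early blocks retain the
    fine edge displacements the quadratic terms live in.  Coordinate
    channels (x, y and optionally x^2, y^2, xy, all scaled to [-1, 1])
    are appended to the input: global max pooling is
    translation-invariant, so a shallow network needs an explicit
    positional basis to regress position-dependent parameters.
    """

    def __init__(self, cfg: ModelConfig, seed: int):
        rng = np.random.default_rng(seed)
        n_coords = (2 + (3 if cfg.quadratic_coords else 0)) if cfg.coord_channels else 0
        n_products = 2 * n_coords if cfg.product_channels else 0
        c_in = cfg.input_channels + n_coords + n_products
        strides = (2,) * (len(cfg.channels) - 1) + (1,)
        self.blocks: list[list] = []
        prev = c_in
        for bi, (c, s) in enumerate(zip(cfg.channels, strides)):
            layers: list = []
            for ci in range(cfg.convs_per_block):
                k = cfg.first_kernel if (bi == 0 and ci == 0) else 3
                stride = s if ci == cfg.convs_per_block - 1 else 1
                layers += [_nn.Conv2d(prev, c, kernel=k, stride=stride, pad=k // 2,
                                      rng=rng),
                           _nn.ReLU()]
                prev = c
            self.blocks.append(layers)
        if cfg.multiscale_head:
            self.pools = [_nn.GlobalMaxPool() for _ in cfg.channels]
            head_in = sum(cfg.channels)
        else:
            self.pools = [_nn.GlobalMaxPool()]
            head_in = cfg.channels[-1]
        # bias at mid-range and small initial gain: normalized targets live in
        # [0, 1], so early predictions should hug 0.5 rather than the tails
        self.head = _nn.Linear(head_in, cfg.n_params, rng=rng, bias_init=0.5,
                               w_scale=0.1)
        self.cfg = cfg
        h, w = cfg.input_size
        if cfg.coord_channels:
            yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
            xn = xx / max(w - 1, 1) * 2 - 1
            yn = yy / max(h - 1, 1) * 2 - 1
            coords = [xn, yn]
            if cfg.quadratic_coords:
                coords += [xn**2 * 2 - 1, yn**2 * 2 - 1, xn * yn]
            self._coords = np.stack(coords)
        else:
            self._coords = None

    def _all_layers(self):
        for block in self.blocks:
            yield from block
        yield from self.pools
        yield self.head

    def named_params(self):
        out = []
        for i, layer in enumerate(self._all_layers()):
            for name in layer.params():
                out.append((f"{i}.{name}", layer, name))
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {key: layer.params()[name].copy()
                for key, layer, name in self.named_params()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.named_params():
            layer.params()[name][...] = state[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.cfg.input_channels \
                or x.shape[2:] != tuple(self.cfg.input_size):
            raise ValueError(
                f"expected input of shape (B, {self.cfg.input_channels}, "
                f"{self.cfg.input_size[0]}, {self.cfg.input_size[1]}), got {x.shape}")
        if self._coords is not None:
            coords = np.broadcast_to(self._coords, (x.shape[0],) + self._coords.shape)
            parts = [x, coords]
            if self.cfg.product_channels:
                # foreground-gated coordinate products: global max pooling of
                # these reads off support-function statistics of each image
                gates = (x + 1.0) * 0.5
                prods = gates[:, :, None, :, :] * self._coords[None, None, :, :, :]
                parts.append(prods.reshape(x.shape[0], -1, *x.shape[2:]))
            x = np.concatenate(parts, axis=1)
        feats = []
        for block in self.blocks:
            for layer in block:
                x = layer.forward(x)
            feats.append(x)
        if self.cfg.multiscale_head:
            z = np.concatenate([p.forward(f) for p, f in zip(self.pools, feats)], axis=1)
        else:
            z = self.pools[0].forward(feats[-1])
        return self.head.forward(z)

    def backward(self, dpred: np.ndarray) -> None:
        dz = self.head.backward(dpred.astype(np.float32))
        if self.cfg.multiscale_head:
            splits = np.cumsum(self.cfg.channels)[:-1]
            dzs = np.split(dz, splits, axis=1)
        else:
            dzs = [dz]
        dx = None
        for bi in range(len(self.blocks) - 1, -1, -1):
            if self.cfg.multiscale_head:
                dfeat = self.pools[bi].backward(np.ascontiguousarray(dzs[bi]))
            elif bi == len(self.blocks) - 1:
                dfeat = self.pools[0].backward(dzs[0])
            else:
                dfeat = 0.0
            d = dfeat if dx is None else dfeat + dx
            for layer in reversed(self.blocks[bi]):
                d = layer.backward(d)
            dx = d

    def n_parameters(self) -> int:
        return sum(p.size for p in self.get_state().values())


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> _TinyCNN:
    """Build an untrained regressor; deterministic given ``seed``."""
    cfg = cfg or ModelConfig()
    if cfg.backbone == "efficientnet_v2":
        raise NotImplementedError(
            "the 'efficientnet_v2' backbone is not implemented in this package; "
            "use backbone='tiny_cnn'"
        )
    return _TinyCNN(cfg, seed)


@dataclass
class TrainedRegressor:
    """A trained model with the parameter ranges it was bound to.

    The ranges are required to denormalize predictions back to pixel
    units; ``history`` records per-epoch losses; ``stage`` is
    ``"pretrained"`` after supervised mask training and ``"finetuned"``
    after unsupervised image training.
    """

    model: _TinyCNN
    ranges: ParameterRanges
    history: list[dict]
    stage: str
    seed: int = 0


def take_batches(stream: Iterator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Materialize ``n`` batches from a pair stream into one array pair."""
    xs, ts = [], []
    for _ in range(n):
        x, t = next(stream)
        xs.append(x)
        ts.append(t)
    return np.concatenate(xs), np.concatenate(ts)


def _clip_with_gate(pred: np.ndarray, lo: float, hi: float):
    gate = (pred > lo) & (pred < hi)
    return np.clip(pred, lo, hi), gate


def _supervised_loss_grad(targets, preds, cfg: HybridLossConfig):
    # floor predictions at the log-domain boundary with a straight-through
    # gradient: the steep MSLE gradient at the floor pulls excursions back
    # into (0, 1) instead of freezing them there
    p_eff = np.maximum(preds, _LOG_FLOOR)
    return hybrid_loss_and_grad(targets, p_eff, cfg)


def _val_supervised_loss(model: _TinyCNN, val_x, val_t, cfg: HybridLossConfig,
                         chunk: int = 64) -> float:
    losses, weights = [], []
    for i in range(0, len(val_x), chunk):
        pred = model.forward(val_x[i:i + chunk])
        loss, _ = _supervised_loss_grad(val_t[i:i + chunk], pred, cfg)
        losses.append(loss)
        weights.append(len(val_x[i:i + chunk]))
    return float(np.average(losses, weights=weights))


def pretrain(model: _TinyCNN, stream: Iterator, val_pairs: tuple[np.ndarray, np.ndarray],
             ranges: ParameterRanges, cfg: TrainConfig | None = None) -> TrainedRegressor:
    """Supervised pretraining on the on-the-fly synthetic mask stream.

    Minimizes the hybrid loss between predicted and true normalized
    parameters with Adam; stops early when the validation loss has not
    improved for ``cfg.patience`` epochs and returns the
    best-validation weights.  Raises on non-finite loss.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = HybridLossConfig(omega=cfg.omega)
    opt = _nn.Adam(model, lr=cfg.learning_rate)
    val_x, val_t = val_pairs
    history: list[dict] = []
    best_val = np.inf
    best_state = model.get_state()
    stall = 0
    step = 0
    total_steps = cfg.max_epochs * cfg.steps_per_epoch
    for epoch in range(cfg.max_epochs):
        train_losses = []
        for _ in range(cfg.steps_per_epoch):
            x, t = next(stream)
            pred = model.forward(x)
            loss, grad = _supervised_loss_grad(t, pred, loss_cfg)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at step {step} (epoch {epoch}); "
                    "check parameter ranges and learning rate")
            model.backward(grad)
            opt.lr = _lr_at(cfg, step, total_steps)
            opt.step()
            train_losses.append(loss)
            step += 1
        val_loss = _val_supervised_loss(model, val_x, val_t, loss_cfg)
        history.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.set_state(best_state)
    return TrainedRegressor(model=model, ranges=ranges, history=history,
                            stage="pretrained", seed=cfg.seed)


def _prepare_image(img: np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    """Grayscale, resize to the model grid and scale to [-1, 1]."""
    a = np.asarray(img, dtype=float)
    if a.ndim == 3:
        a = a.mean(axis=-1)
    if a.max() <= 1.0 and np.all(np.isin(np.unique(a), (0, 1))):
        a = a * 255.0  # binary masks ride the same [0, 255] convention
    pcfg = PreprocessConfig(target_size=input_size, clahe_enabled=False,
                            bilateral_enabled=False)
    return resize_and_scale(a, pcfg)


def _pairs_to_arrays(pairs: Sequence[RegistrationPair],
                     input_size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    F = np.stack([_prepare_image(p.fixed, input_size) for p in pairs])
    M = np.stack([_prepare_image(p.moving, input_size) for p in pairs])
    return F, M


def _warp_batch_with_grads(M: np.ndarray, qs: np.ndarray, D: np.ndarray,
                           shape: tuple[int, int]):
    """Warp each moving image by its own transform; keep bilinear grads."""
    h, w = shape
    warped = np.empty_like(M)
    dus = np.empty_like(M)
    dvs = np.empty_like(M)
    for i in range(len(M)):
        u = (D @ qs[i, :6]).reshape(h, w)
        v = (D @ qs[i, 6:]).reshape(h, w)
        warped[i], dus[i], dvs[i] = bilinear_sample(
            M[i], u, v, fill_value=-1.0, with_grad=True)
    return warped, dus, dvs


def _mean_ncc_loss(model: _TinyCNN, F, M, D, ranges, cfg: TrainConfig) -> float:
    h, w = model.cfg.input_size
    losses = []
    for i in range(0, len(F), 32):
        pred = model.forward(np.stack([F[i:i + 32], M[i:i + 32]], axis=1))
        clipped, _ = _clip_with_gate(pred, cfg.clip_lo, cfg.clip_hi)
        qs = ranges.mins + clipped * (ranges.maxs - ranges.mins)
        warped, _, _ = _warp_batch_with_grads(M[i:i + 32], qs, D, (h, w))
        for f, wrp in zip(F[i:i + 32], warped):
            try:
                losses.append(1.0 - ncc(f, wrp))
            except ValueError:  # fully out-of-frame warp: maximal penalty
                losses.append(2.0)
    return float(np.mean(losses))


def finetune(pretrained: TrainedRegressor, pairs: Sequence[RegistrationPair],
             cfg: TrainConfig | None = None) -> TrainedRegressor:
    """Unsupervised fine-tuning: minimize ``1 - NCC(F, warp(M, Q'))``.

    ``pairs`` need no ground truth.  The pretrained model is deep-copied
    (the pretraining checkpoint is never mutated); training uses Adam at
    ``learning_rate * finetune_lr_factor`` with early stopping on the
    validation NCC loss.  The train/validation split follows
    ``cfg.split`` (the test fraction is left untouched for evaluation).
    """
    if pretrained.stage not in ("pretrained", "finetuned"):
        raise ValueError(f"unexpected model stage {pretrained.stage!r}")
    if pretrained.ranges is None:
        raise ValueError("the pretrained model has no bound parameter ranges")
    cfg = cfg or TrainConfig()
    model = copy.deepcopy(pretrained.model)
    ranges = pretrained.ranges
    h, w = model.cfg.input_size

    F, M = _pairs_to_arrays(pairs, (h, w))
    n = len(F)
    n_train = max(1, int(round(cfg.split[0] * n)))
    n_val = max(1, int(round(cfg.split[1] * n)))
    F_tr, M_tr = F[:n_train], M[:n_train]
    F_va, M_va = F[n_train:n_train + n_val], M[n_train:n_train + n_val]

    y, x = np.mgrid[0:h, 0:w].astype(float)
    D = design_vector(x, y, 2).reshape(-1, 6)
    width = ranges.maxs - ranges.mins

    opt = _nn.Adam(model, lr=cfg.learning_rate * cfg.finetune_lr_factor)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_val = np.inf
    best_state = model.get_state()
    stall = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_train)
        train_losses = []
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Fb, Mb = F_tr[idx], M_tr[idx]
            pred = model.forward(np.stack([Fb, Mb], axis=1))
            clipped, gate = _clip_with_gate(pred, cfg.clip_lo, cfg.clip_hi)
            qs = ranges.mins + clipped * width
            warped, dus, dvs = _warp_batch_with_grads(Mb, qs, D, (h, w))
            B = len(idx)
            dpred = np.zeros_like(pred)
            batch_losses = []
            for i in range(B):
                try:
                    value, gw = ncc_and_grad(Fb[i], warped[i])
                except ValueError:
                    batch_losses.append(2.0)
                    continue
                batch_losses.append(1.0 - value)
                dldw = -gw / B  # d(mean 1-NCC)/d(warped_i)
                dq_u = D.T @ (dldw * dus[i]).ravel()
                dq_v = D.T @ (dldw * dvs[i]).ravel()
                dpred[i] = np.concatenate([dq_u, dq_v]) * width
            dpred *= gate
            loss = float(np.mean(batch_losses))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite fine-tuning loss in epoch {epoch}")
            model.backward(dpred)
            opt.step()
            train_losses.append(loss)
        val_loss = _mean_ncc_loss(model, F_va, M_va, D, ranges, cfg)
        history.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.set_state(best_state)
    return TrainedRegressor(model=model, ranges=ranges,
                            history=pretrained.history + history,
                            stage="finetuned", seed=cfg.seed)


def predict_batch(trained: TrainedRegressor, inputs: np.ndarray,
                  clip: tuple[float, float] = (-0.25, 1.25)) -> np.ndarray:
    """Predict normalized parameters for a batch of stacked pairs.

    ``inputs`` has shape ``(n, 2, H, W)`` in [-1, 1].  Predictions are
    clipped to ``clip`` to bound extrapolation outside the training
    range before any denormalization.
    """
    preds = []
    for i in range(0, len(inputs), 64):
        preds.append(trained.model.forward(inputs[i:i + 64]))
    out = np.concatenate(preds)
    return np.clip(out, *clip)


def predict(trained: TrainedRegressor, pair: RegistrationPair) -> QuadraticTransform:
    """Predict the pixel-unit quadratic transform for one pair.

    Deterministic (pure inference); the transform lives on the model's
    input grid — use :func:`polyreg.polywarp.rescale_transform` to move
    it to another resolution.
    """
    size = trained.model.cfg.input_size
    f = _prepare_image(pair.fixed, size)
    m = _prepare_image(pair.moving, size)
    z = predict_batch(trained, np.stack([f, m])[None, ...])[0]
    return denormalize_params(z, trained.ranges)


def register(trained: TrainedRegressor, fixed: np.ndarray, moving: np.ndarray,
             preprocess_cfg: PreprocessConfig | None = None):
    """Register ``moving`` onto ``fixed`` at the original resolution.

    Both images pass through the hybrid preprocessing, are resized to
    the model grid and scaled to [-1, 1]; the predicted transform is
    analytically rescaled back to the original resolution and applied
    to the *original* moving image.  Returns ``(warped, transform,
    metrics)`` where metrics holds grayscale SSIM/NCC before (fixed vs
    moving) and after (fixed vs warped) alignment.
    """
    from .losses_metrics import ssim  # local import avoids cycle at module load

    pcfg = preprocess_cfg or PreprocessConfig()
    pf = hybrid_preprocess(np.asarray(fixed), pcfg)
    pm = hybrid_preprocess(np.asarray(moving), pcfg)
    q_model = predict(trained, RegistrationPair(fixed=pf, moving=pm))

    h_in, w_in = trained.model.cfg.input_size
    h0, w0 = np.asarray(moving).shape[:2]
    q_full = rescale_transform(q_model, w0 / w_in, h0 / h_in)
    warped = warp_image(np.asarray(moving), q_full)

    def gray(a):
        a = np.asarray(a, dtype=float)
        return a.mean(axis=-1) if a.ndim == 3 else a

    gf, gm, gw = gray(fixed), gray(moving), gray(warped)
    metrics = {
        "ssim_before": ssim(gf, gm), "ssim_after": ssim(gf, gw),
        "ncc_before": ncc(gf, gm), "ncc_after": ncc(gf, gw),
    }
    return warped, q_full, metrics


def save_checkpoint(trained: TrainedRegressor, path) -> None:
    """Write a self-describing checkpoint (weights + config + ranges + history)."""
    meta = {
        "model_config": asdict(trained.model.cfg),
        "ranges": trained.ranges.to_dict(),
        "history": trained.history,
        "stage": trained.stage,
        "seed": trained.seed,
    }
    state = {f"w_{k}": v for k, v in trained.model.get_state().items()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> TrainedRegressor:
    """Load a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        mc = meta["model_config"]
        mc["input_size"] = tuple(mc["input_size"])
        mc["channels"] = tuple(mc["channels"])
        cfg = ModelConfig(**mc)
        model = build_model(cfg, seed=meta["seed"])
        state = {k[2:]: data[k] for k in data.files if k.startswith("w_")}
        model.set_state(state)
    return TrainedRegressor(
        model=model, ranges=ParameterRanges.from_dict(meta["ranges"]),
        history=meta["history"], stage=meta["stage"], seed=meta["seed"])
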