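"""Hybrid fundus preprocessing: CLAHE, bilateral filtering, scaling, augmentation.

The pipeline applies contrast-limited adaptive histogram equalization
(CLAHE) first — bringing out vessels and the optic disc under the
uneven illumination typical of fundus photography — and then an
edge-preserving bilateral filter to smooth away the noise and spurious
texture CLAHE tends to amplify, leaving the model a concentrated input.
Both stages and their order are configurable.

Model-ready arrays are resized to the training resolution and scaled
linearly from [0, 255] to [-1, 1]: black background then sits at -1
rather than 0, so convolutional activations are not suppressed in the
regions whose boundary carries the geometric signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, exposure, restoration, transform

__all__ = [
    "PreprocessConfig",
    "AugmentConfig",
    "clahe",
    "bilateral",
    "hybrid_preprocess",
    "resize_and_scale",
    "unscale",
    "augment_source",
    "augment_pair",
]

_CLAHE_BINS = 256  # histogram bins assumed by the clip-limit convention


@dataclass
class PreprocessConfig:
    """Settings for the hybrid preprocessing pipeline.

    ``clahe_clip_limit`` follows the common multiple-of-mean-bin-height
    convention (2.0 clips histogram bins at twice their mean count);
    it is converted internally to the normalized limit scikit-image
    expects.  ``intensity_range`` is the domain of the input images.
    """

    clahe_enabled: bool = True
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    bilateral_enabled: bool = True
    bilateral_diameter: int = 9
    bilateral_sigma_color: float = 75.0
    bilateral_sigma_space: float = 75.0
    order: str = "clahe_first"  # or "bilateral_first"
    target_size: tuple[int, int] = (256, 256)
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        if self.bilateral_sigma_color <= 0 or self.bilateral_sigma_space <= 0:
            raise ValueError("bilateral sigmas must be > 0")
        if min(self.target_size) <= 0:
            raise ValueError("target_size must be positive")
        lo, hi = self.intensity_range
        if lo >= hi:
            raise ValueError("intensity_range must satisfy low < high")
        if self.order not in ("clahe_first", "bilateral_first"):
            raise ValueError(f"unknown stage order {self.order!r}")


@dataclass
class AugmentConfig:
    """Training-time augmentation settings (flips, rotation, photometric)."""

    enabled: bool = True
    flip_prob: float = 0.5
    max_rotation_deg: float = 15.0
    brightness_delta: float = 0.2   # +-20% of full scale
    contrast_range: tuple[float, float] = (0.8, 1.2)


def _as_float01(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    lo, hi = cfg.intensity_range
    return (np.asarray(image, dtype=float) - lo) / (hi - lo)


def _from_float01(f: np.ndarray, image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    lo, hi = cfg.intensity_range
    out = np.clip(f, 0, 1) * (hi - lo) + lo
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.rint(out).astype(image.dtype)
    return out


def clahe(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    RGB images are equalized on the L channel of CIELAB only, avoiding
    hue shifts.  Constant images pass through unchanged (a degenerate
    histogram has no contrast to redistribute).  Output stays within
    the configured intensity range and keeps the input dtype.
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(image)
    h, w = img.shape[:2]
    ty, tx = cfg.clahe_tile_grid
    if h < ty or w < tx:
        raise ValueError(f"image {h}x{w} smaller than CLAHE tile grid {cfg.clahe_tile_grid}")
    if img.max() == img.min():
        return img.copy()
    kernel = (max(1, h // ty), max(1, w // tx))
    clip = cfg.clahe_clip_limit / _CLAHE_BINS
    f = _as_float01(img, cfg)
    if img.ndim == 3:
        lab = color.rgb2lab(f)
        L = lab[..., 0] / 100.0
        lab[..., 0] = exposure.equalize_adapthist(
            np.clip(L, 0, 1), kernel_size=kernel, clip_limit=clip, nbins=_CLAHE_BINS
        ) * 100.0
        out = color.lab2rgb(lab)
    else:
        out = exposure.equalize_adapthist(
            np.clip(f, 0, 1), kernel_size=kernel, clip_limit=clip, nbins=_CLAHE_BINS
        )
    return _from_float01(out, img, cfg)


def bilateral(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Edge-preserving bilateral smoothing.

    Each pixel becomes a spatial-Gaussian x range-Gaussian weighted mean
    over the ``bilateral_diameter`` window; ``sigma_color`` is expressed
    on the configured intensity scale.  Output range stays within the
    input range.
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(image)
    f = np.clip(_as_float01(img, cfg), 0, 1)
    lo, hi = cfg.intensity_range
    win = cfg.bilateral_diameter | 1  # denoise_bilateral requires an odd window
    kwargs = dict(
        win_size=win,
        sigma_color=cfg.bilateral_sigma_color / (hi - lo),
        sigma_spatial=cfg.bilateral_sigma_space,
    )
    if img.ndim == 3:
        out = restoration.denoise_bilateral(f, channel_axis=-1, **kwargs)
    else:
        out = restoration.denoise_bilateral(f, **kwargs)
    return _from_float01(out, img, cfg)


def hybrid_preprocess(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """The hybrid pipeline: CLAHE then bilateral (order configurable).

    With both stages disabled the input passes through unchanged.
    Deterministic: no randomness in either stage.
    """
    cfg = cfg or PreprocessConfig()
    stages = []
    if cfg.order == "clahe_first":
        if cfg.clahe_enabled:
            stages.append(clahe)
        if cfg.bilateral_enabled:
            stages.append(bilateral)
    else:
        if cfg.bilateral_enabled:
            stages.append(bilateral)
        if cfg.clahe_enabled:
            stages.append(clahe)
    out = np.asarray(image)
    if not stages:
        return out.copy()
    for stage in stages:
        out = stage(out, cfg)
    return out


def resize_and_scale(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Resize to ``target_size`` (bilinear) and scale [0, 255] -> [-1, 1].

    Endpoints map exactly: 0 -> -1, 127.5 -> 0, 255 -> +1.  Images
    already at the target size are not resampled, so the scaling is
    then exact per pixel.
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(image, dtype=float)
    if img.shape[:2] != tuple(cfg.target_size):
        img = transform.resize(img, cfg.target_size, order=1, mode="edge",
                               anti_aliasing=False, preserve_range=True)
    lo, hi = cfg.intensity_range
    return ((img - lo) / (hi - lo) * 2.0 - 1.0).astype(np.float32)


def unscale(scaled: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Inverse of the intensity scaling: [-1, 1] back to the input range."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.intensity_range
    return (np.asarray(scaled, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo


def _geometric(source: np.ndarray, rng: np.random.Generator,
               cfg: AugmentConfig) -> np.ndarray:
    out = np.asarray(source)
    binary = out.ndim == 2 and np.all(np.isin(np.unique(out), (0, 1)))
    if rng.random() < cfg.flip_prob:
        out = out[:, ::-1]
    if rng.random() < cfg.flip_prob:
        out = out[::-1, :]
    angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
    if angle != 0.0:
        rotated = transform.rotate(out.astype(float), angle, order=0 if binary else 1,
                                   preserve_range=True)
        out = rotated.astype(out.dtype) if binary else \
            np.clip(rotated, 0, 255).astype(out.dtype)
    return np.ascontiguousarray(out)


def augment_source(source: np.ndarray, rng: np.random.Generator,
                   cfg: AugmentConfig | None = None) -> np.ndarray:
    """Geometric augmentation of a pretraining source (mask or image).

    Applied *before* the synthetic warp, so the generated pair's ground
    truth remains exact.  Disabled config returns the input unchanged.
    """
    cfg = cfg or AugmentConfig()
    if not cfg.enabled:
        return np.asarray(source)
    return _geometric(source, rng, cfg)


def _photometric(img: np.ndarray, rng: np.random.Generator,
                 cfg: AugmentConfig) -> np.ndarray:
    out = np.asarray(img, dtype=float)
    scale = out.max() if out.max() > 1 else 1.0
    gain = rng.uniform(*cfg.contrast_range)
    delta = rng.uniform(-cfg.brightness_delta, cfg.brightness_delta) * 255.0
    mean = out.mean()
    out = (out - mean) * gain + mean + delta * (scale / 255.0)
    return np.clip(out, 0, 255 if scale > 1 else 1.0)


def augment_pair(fixed: np.ndarray, moving: np.ndarray, rng: np.random.Generator,
                 cfg: AugmentConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Fine-tuning augmentation of an image pair.

    Geometric flips are applied identically to both images (the pair's
    relative geometry is the training signal and must not change);
    photometric brightness/contrast jitter is drawn per image, which the
    intensity-affine-invariant NCC objective tolerates by design.
    """
    cfg = cfg or AugmentConfig()
    if not cfg.enabled:
        return np.asarray(fixed), np.asarray(moving)
    f, m = np.asarray(fixed), np.asarray(moving)
    if rng.random() < cfg.flip_prob:
        f, m = f[:, ::-1], m[:, ::-1]
    if rng.random() < cfg.flip_prob:
        f, m = f[::-1, :], m[::-1, :]
    f = _photometric(f, rng, cfg)
    m = _photometric(m, rng, cfg)
    return np.ascontiguousarray(f), np.ascontiguousarray(m)
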