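"""Synthetic field-of-view masks, fundus-like images and training pairs.

Fundus cameras image the retina through a circular aperture, so a colour
fundus photograph is a bright near-circular field of view (FOV) on a
black background, containing a bright optic-disc blob and a dark
branching vessel tree.  This module emulates exactly those features at
desk scale — enough structure for a transformation regressor to learn
from, with no claim of photorealism — and generates registration pairs
whose ground-truth quadratic transform is exact by construction: the
fixed image is produced by warping the moving image through the same
warp engine used everywhere else in the package, so the stored
transform is exactly the one that registers the pair.

Training data is generated *on the fly*: :func:`pair_stream` never
exhausts and draws fresh transform parameters for every pair, so the
regressor never sees the same warp twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import measure, morphology

from .polywarp import (
    PARAM_NAMES,
    QuadraticTransform,
    normalize_params,
    warp_image,
    warp_mask,
)

__all__ = [
    "ParameterRanges",
    "SyntheticFundus",
    "RegistrationPair",
    "generate_fov_mask",
    "generate_synthetic_fundus",
    "sample_transform",
    "make_training_pair",
    "pair_stream",
    "extract_mask_from_image",
    "mask_source",
    "fundus_source",
]

_REFERENCE_SIZE = 256
_MIN_DIM = 32

# Per-parameter half-ranges / bounds at the 256x256 reference resolution.
# Quadratic terms are kept small relative to linear terms so that sampled
# warps retain most of the FOV in frame (the degenerate-warp guard below
# enforces >= 10% retention; typical draws retain far more).
_REF_BOUNDS = {
    "q00": (-2e-4, 2e-4), "q01": (-2e-4, 2e-4), "q02": (-2e-4, 2e-4),
    "q03": (0.9, 1.1), "q04": (-0.1, 0.1), "q05": (-25.0, 25.0),
    "q10": (-2e-4, 2e-4), "q11": (-2e-4, 2e-4), "q12": (-2e-4, 2e-4),
    "q13": (-0.1, 0.1), "q14": (0.9, 1.1), "q15": (-25.0, 25.0),
}
_QUADRATIC = ("q00", "q01", "q02", "q10", "q11", "q12")
_TRANSLATION = ("q05", "q15")


@dataclass
class ParameterRanges:
    """Per-parameter ``(min, max)`` bounds for the 12 quadratic parameters.

    Used both for sampling synthetic transforms and for the [0, 1]
    normalization of regression targets.  ``mins``/``maxs`` follow the
    canonical parameter order ``q00..q05, q10..q15``.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != (12,) or self.maxs.shape != (12,):
            raise ValueError("ParameterRanges needs 12 mins and 12 maxs")
        if np.any(self.maxs < self.mins):
            raise ValueError("each parameter range needs max >= min")

    @classmethod
    def default(cls, size: int = _REFERENCE_SIZE) -> "ParameterRanges":
        """Default ranges for a ``size`` x ``size`` grid.

        The 256 px reference bounds are rescaled analytically: under a
        coordinate scale ``s = size/256``, translation terms scale by
        ``s``, quadratic terms by ``1/s`` and linear terms are invariant
        — so a warp sampled at any resolution produces the same relative
        deformation of the field of view.
        """
        s = size / _REFERENCE_SIZE
        mins, maxs = [], []
        for name in PARAM_NAMES:
            lo, hi = _REF_BOUNDS[name]
            if name in _QUADRATIC:
                lo, hi = lo / s, hi / s
            elif name in _TRANSLATION:
                lo, hi = lo * s, hi * s
            mins.append(lo)
            maxs.append(hi)
        return cls(np.array(mins), np.array(maxs))

    @classmethod
    def pinned_identity(cls) -> "ParameterRanges":
        """Degenerate ranges that always sample the identity transform."""
        q = QuadraticTransform.identity().params
        return cls(q.copy(), q.copy())

    def to_dict(self) -> dict:
        return {name: [float(lo), float(hi)]
                for name, lo, hi in zip(PARAM_NAMES, self.mins, self.maxs)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterRanges":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names in ranges: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing parameter ranges: {sorted(missing)}")
        mins = np.array([d[n][0] for n in PARAM_NAMES], dtype=float)
        maxs = np.array([d[n][1] for n in PARAM_NAMES], dtype=float)
        return cls(mins, maxs)


@dataclass
class SyntheticFundus:
    """A synthetic fundus-like photograph with its FOV mask and seed."""

    image: np.ndarray  # (H, W, 3) uint8, 0 outside mask
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    seed: int


@dataclass
class RegistrationPair:
    """A fixed/moving pair, optionally with exact ground truth.

    When ``true_transform`` is present, ``fixed == warp(moving,
    true_transform)``: warping the moving image by the ground-truth
    transform reproduces the fixed image exactly.  This is the one
    direction consistent with the unsupervised objective (maximize the
    similarity of the warped moving image to the fixed image) under
    backward warping.
    """

    fixed: np.ndarray
    moving: np.ndarray
    true_transform: Optional[QuadraticTransform] = None
    normalized_target: Optional[np.ndarray] = None


def _check_dims(height: int, width: int) -> None:
    if height < _MIN_DIM or width < _MIN_DIM:
        raise ValueError(f"dimensions must be >= {_MIN_DIM}, got {height}x{width}")


def _fov_mask(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Near-circular FOV disc with jittered centre and horizontal edge clipping.

    The rectangular camera frame crops the aperture circle at its left
    and right edges; the crop margins are drawn independently, so the
    mask carries four corner landmarks in addition to its circular arcs.
    Without them the shape would be nearly rotation-invariant and a
    sizeable subspace of warp parameters (tangential boundary sliding)
    would be unobservable from mask pairs.
    """
    m = min(height, width)
    radius = 0.45 * m * rng.uniform(0.92, 1.0)
    cy = height / 2 + rng.uniform(-0.05, 0.05) * m
    cx = width / 2 + rng.uniform(-0.05, 0.05) * m
    y, x = np.mgrid[0:height, 0:width]
    mask = ((x - cx) ** 2 + (y - cy) ** 2) <= radius**2
    margin_l = rng.uniform(0.03, 0.10) * width
    margin_r = rng.uniform(0.03, 0.10) * width
    mask &= (x >= cx - radius + margin_l) & (x <= cx + radius - margin_r)
    return mask.astype(np.uint8)


def generate_fov_mask(height: int, width: int, rng_seed: int) -> np.ndarray:
    """Generate a binary field-of-view mask (1 inside the camera aperture).

    Deterministic given ``rng_seed``; radius ~0.45*min(H, W) with <=5%
    centre jitter and, half the time, horizontal edge clipping mimicking
    the rectangular crop of fundus frames.
    """
    _check_dims(height, width)
    return _fov_mask(height, width, np.random.default_rng(rng_seed))


def _vessel_tree(height: int, width: int, origin: tuple[float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Binary vessel canvas grown from the optic disc by recursive
    midpoint-displacement branching."""
    canvases = {w: np.zeros((height, width), dtype=bool) for w in (1, 2, 3)}
    m = min(height, width)

    def displace(p0, p1, depth):
        # recursive midpoint displacement -> gently wiggly polyline
        if depth == 0:
            return [p0, p1]
        mid = (p0 + p1) / 2
        normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
        norm = np.linalg.norm(normal)
        if norm > 0:
            mid = mid + normal / norm * rng.normal(0, 0.06) * np.linalg.norm(p1 - p0)
        return displace(p0, mid, depth - 1)[:-1] + displace(mid, p1, depth - 1)

    def draw_polyline(pts, thickness):
        canvas = canvases[min(3, max(1, thickness))]
        for a, b in zip(pts[:-1], pts[1:]):
            rr, cc = skdraw.line(int(round(a[0])), int(round(a[1])),
                                 int(round(b[0])), int(round(b[1])))
            ok = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
            canvas[rr[ok], cc[ok]] = True

    def grow(p0, angle, length, thickness, depth):
        if depth == 0 or length < 0.02 * m:
            return
        p1 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
        draw_polyline(displace(p0, p1, 3), thickness)
        n_children = rng.integers(1, 3)
        for _ in range(n_children):
            child_angle = angle + rng.uniform(-0.9, 0.9)
            grow(p1, child_angle, length * rng.uniform(0.55, 0.8),
                 max(1, thickness - 1), depth - 1)

    n_main = rng.integers(5, 8)
    for k in range(n_main):
        angle = 2 * np.pi * (k + rng.uniform(-0.2, 0.2)) / n_main
        grow(np.array(origin, dtype=float), angle,
             m * rng.uniform(0.18, 0.3), 3, depth=4)

    out = np.zeros((height, width), dtype=bool)
    for w, canvas in canvases.items():
        out |= morphology.dilation(canvas, morphology.disk(max(0, w // 2)))
    return out


def generate_synthetic_fundus(height: int, width: int, rng_seed: int) -> SyntheticFundus:
    """Generate a fundus-like RGB image: reddish-brown background inside a
    circular FOV, a bright optic-disc blob, a dark branching vessel tree,
    a mild illumination gradient and additive Gaussian noise.

    Pixels outside the FOV mask are exactly 0.  Deterministic given
    ``rng_seed``.
    """
    _check_dims(height, width)
    rng = np.random.default_rng(rng_seed)
    mask = _fov_mask(height, width, rng)
    m = min(height, width)
    y, x = np.mgrid[0:height, 0:width]

    base = np.empty((height, width, 3), dtype=float)
    base[..., 0] = rng.uniform(140, 170)  # R
    base[..., 1] = rng.uniform(60, 85)    # G
    base[..., 2] = rng.uniform(30, 50)    # B

    # optic disc: bright blob offset from the FOV centre
    disc_r = 0.08 * m
    ang = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(0.3, 0.55) * 0.45 * m
    cy, cx = height / 2 + dist * np.sin(ang), width / 2 + dist * np.cos(ang)
    blob = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * disc_r**2)))
    disc_color = np.array([235.0, 190.0, 120.0])
    img = base + blob[..., None] * (disc_color - base)

    vessels = _vessel_tree(height, width, (cy, cx), rng)
    img = np.where(vessels[..., None], img * 0.45, img)

    # mild multiplicative illumination ramp in a random direction
    g_ang = rng.uniform(0, 2 * np.pi)
    ramp = ((x - width / 2) * np.cos(g_ang) + (y - height / 2) * np.sin(g_ang)) / m
    img *= (1.0 + 0.15 * ramp)[..., None]

    img += rng.normal(0, 3.0, size=img.shape)
    img = np.clip(img, 0, 255)
    img *= mask[..., None]
    return SyntheticFundus(image=img.astype(np.uint8), mask=mask, seed=rng_seed)


def sample_transform(ranges: ParameterRanges, rng: np.random.Generator) -> QuadraticTransform:
    """Draw each parameter independently and uniformly from its range."""
    params = rng.uniform(ranges.mins, ranges.maxs)
    # uniform(a, a) can return a + eps in edge cases; pin degenerate ranges
    degenerate = ranges.maxs == ranges.mins
    params = np.where(degenerate, ranges.mins, params)
    return QuadraticTransform.from_params(params)


def _target_for(t: QuadraticTransform, ranges: ParameterRanges) -> np.ndarray:
    """Normalized target, mapping zero-width (pinned) ranges to 0.5."""
    width = ranges.maxs - ranges.mins
    if np.all(width > 0):
        return normalize_params(t, ranges)
    out = np.full(12, 0.5)
    live = width > 0
    out[live] = (t.params[live] - ranges.mins[live]) / width[live]
    return out


def _foreground_mask(source: np.ndarray) -> np.ndarray:
    if source.ndim == 3:
        return (source.max(axis=-1) > 0).astype(np.uint8)
    return (source > 0).astype(np.uint8)


def _is_binary(a: np.ndarray) -> bool:
    return a.ndim == 2 and np.all(np.isin(np.unique(a), (0, 1)))


def make_training_pair(source: np.ndarray, ranges: ParameterRanges,
                       rng: np.random.Generator,
                       max_attempts: int = 20) -> RegistrationPair:
    """Build a registration pair with exact ground truth.

    ``moving`` is the source itself; ``fixed`` is the source warped by
    a freshly sampled quadratic transform — through the same warp
    engine users apply, so warping ``moving`` by ``true_transform``
    reproduces ``fixed`` bit-exactly (and a regressor trained on these
    targets predicts exactly the transform that aligns the moving image
    to the fixed one).  Draws that expel more than 90% of the
    foreground from the frame are resampled (at most ``max_attempts``
    times).
    """
    source = np.asarray(source)
    if source.size == 0 or not np.any(source):
        raise ValueError("source must be non-empty with non-zero foreground")
    fg = _foreground_mask(source)
    fg_total = int(fg.sum())
    binary = _is_binary(source)
    for _ in range(max_attempts):
        t = sample_transform(ranges, rng)
        warped_fg = warp_mask(fg, t)
        if warped_fg.sum() < 0.1 * fg_total:
            continue
        warped = warp_mask(source, t) if binary else warp_image(source, t)
        return RegistrationPair(
            fixed=warped, moving=source, true_transform=t,
            normalized_target=_target_for(t, ranges),
        )
    raise RuntimeError(
        f"no admissible transform after {max_attempts} draws; "
        "the configured parameter ranges expel the field of view from frame"
    )


def _to_unit_range(a: np.ndarray) -> np.ndarray:
    """Scale an input to the network's [-1, 1] domain.

    Binary {0,1} masks map to {-1, +1}; intensity images map linearly
    from [0, 255].  Black background lands at -1 so convolutional
    activations are not suppressed there.
    """
    a = np.asarray(a, dtype=np.float32)
    if a.ndim == 3:
        a = a.mean(axis=-1)
    if a.max() <= 1.0:
        return a * 2.0 - 1.0
    return a / 127.5 - 1.0


def pair_stream(source_provider: Callable[[np.random.Generator], np.ndarray],
                ranges: ParameterRanges,
                rng: np.random.Generator,
                batch_size: int,
                source_augment: Optional[Callable] = None,
                ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Unbounded iterator of on-the-fly training batches.

    Each element is ``(inputs, targets)`` with inputs of shape
    ``(batch_size, 2, H, W)`` (fixed and moving stacked as channels,
    scaled to [-1, 1]) and targets of shape ``(batch_size, 12)``
    ([0, 1]-normalized parameters).  Fresh transforms are drawn for
    every pair, so the stream never repeats; it is fully reproducible
    under a seeded ``rng``.

    ``source_augment(source, rng)``, when given, is applied to the
    source *before* the synthetic warp, so ground truth stays exact.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    while True:
        inputs, targets = [], []
        for _ in range(batch_size):
            source = source_provider(rng)
            if source_augment is not None:
                source = source_augment(source, rng)
            pair = make_training_pair(source, ranges, rng)
            inputs.append(np.stack([_to_unit_range(pair.fixed),
                                    _to_unit_range(pair.moving)]))
            targets.append(pair.normalized_target)
        yield (np.stack(inputs).astype(np.float32),
               np.stack(targets).astype(np.float32))


def mask_source(height: int, width: int) -> Callable[[np.random.Generator], np.ndarray]:
    """Source provider drawing a fresh random FOV mask per pair."""
    _check_dims(height, width)
    return lambda rng: _fov_mask(height, width, rng)


def fundus_source(height: int, width: int) -> Callable[[np.random.Generator], np.ndarray]:
    """Source provider drawing a fresh synthetic fundus image per pair."""
    _check_dims(height, width)

    def provide(rng: np.random.Generator) -> np.ndarray:
        seed = int(rng.integers(0, 2**31 - 1))
        return generate_synthetic_fundus(height, width, seed).image

    return provide


def extract_mask_from_image(image: np.ndarray, threshold: float = 10.0) -> np.ndarray:
    """Threshold an image into its FOV mask (non-black areas -> 1).

    The max-channel intensity is thresholded, then only the largest
    connected component is kept and its holes are filled — vessels and
    dark lesions inside the FOV must not punch holes in the mask.
    """
    img = np.asarray(image, dtype=float)
    fg = img.max(axis=-1) if img.ndim == 3 else img
    mask = fg > threshold
    if not np.any(mask):
        raise ValueError("image is entirely black: no field of view to extract")
    labels = measure.label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    return ndi.binary_fill_holes(mask).astype(np.uint8)
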