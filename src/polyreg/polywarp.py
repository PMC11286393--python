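"""Polynomial coordinate mapping and differentiable image warping.

This module is the computational core of the polynomial transformation
layer (PTL): a degree-``p`` polynomial maps every output pixel ``(x, y)``
(``x`` = column, ``y`` = row, 0-based, origin top-left) to a source
location ``(u, v)``, and the output image is filled by sampling the
source there (*backward* warping, the standard contract for
differentiable spatial transformation layers — it produces hole-free
dense output).

For the quadratic case (degree 2) the mapping is

    u = q00*x^2 + q01*y^2 + q02*x*y + q03*x + q04*y + q05
    v = q10*x^2 + q11*y^2 + q12*x*y + q13*x + q14*y + q15

i.e. a 2x6 matrix ``Q`` applied to the monomial vector
``[x^2, y^2, xy, x, y, 1]``.  Bilinear sampling makes the warp
differentiable with respect to ``Q``, which is what lets an image
similarity loss drive a parameter regressor through this layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PolynomialTransform",
    "QuadraticTransform",
    "WarpConfig",
    "n_terms",
    "monomial_exponents",
    "design_vector",
    "identity_transform",
    "map_coords",
    "bilinear_sample",
    "nearest_sample",
    "warp_image",
    "warp_mask",
    "normalize_params",
    "denormalize_params",
    "invert_coords",
    "rescale_transform",
]

#: Parameter names of the quadratic transform, in canonical order
#: (row u first, then row v; within a row: x^2, y^2, xy, x, y, 1).
PARAM_NAMES: tuple[str, ...] = (
    "q00", "q01", "q02", "q03", "q04", "q05",
    "q10", "q11", "q12", "q13", "q14", "q15",
)

_SUPPORTED_DEGREES = (1, 2, 3, 4, 5)


def n_terms(degree: int) -> int:
    """Number of monomials of total degree <= ``degree`` in two variables."""
    _check_degree(degree)
    return (degree + 1) * (degree + 2) // 2


def _check_degree(degree: int) -> None:
    if degree not in _SUPPORTED_DEGREES:
        raise ValueError(
            f"unsupported polynomial degree {degree!r}; supported: {_SUPPORTED_DEGREES}"
        )


def monomial_exponents(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs ``(i, j)`` for ``x^i * y^j`` in the canonical basis order.

    For each total degree ``d`` from ``degree`` down to 2 the order is
    ``x^d, y^d, x^(d-1)*y, ..., x*y^(d-1)``; the basis always ends with
    ``x, y, 1``.  Degree 2 therefore reads ``[x^2, y^2, xy, x, y, 1]``
    and degree 1 reads ``[x, y, 1]``.
    """
    _check_degree(degree)
    exps: list[tuple[int, int]] = []
    for d in range(degree, 1, -1):
        exps.append((d, 0))
        exps.append((0, d))
        for i in range(d - 1, 0, -1):
            exps.append((i, d - i))
    exps.extend([(1, 0), (0, 1), (0, 0)])
    return exps


def design_vector(x, y, degree: int) -> np.ndarray:
    """Evaluate the monomial basis at ``(x, y)``.

    Accepts scalars or broadcastable arrays; the basis axis is appended
    last, so the result has shape ``(*broadcast_shape, n_terms(degree))``.
    The last element is always 1.
    """
    exps = monomial_exponents(degree)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = [x**i * y**j if (i or j) else np.ones(np.broadcast(x, y).shape)
            for i, j in exps]
    return np.stack(np.broadcast_arrays(*cols), axis=-1)


class PolynomialTransform:
    """A degree-``p`` polynomial coordinate mapping (output -> source).

    Parameters
    ----------
    degree:
        Polynomial degree ``p`` in 1..5.
    coeffs_u, coeffs_v:
        Coefficients of the ``u`` and ``v`` polynomials in the canonical
        monomial order of :func:`monomial_exponents`; length must equal
        :func:`n_terms` ``(degree)``.  Units: pixels.
    """

    def __init__(self, degree: int, coeffs_u: Sequence[float], coeffs_v: Sequence[float]):
        _check_degree(degree)
        cu = np.asarray(coeffs_u, dtype=float)
        cv = np.asarray(coeffs_v, dtype=float)
        nt = n_terms(degree)
        if cu.shape != (nt,) or cv.shape != (nt,):
            raise ValueError(
                f"degree-{degree} transform needs {nt} coefficients per axis, "
                f"got {cu.shape} and {cv.shape}"
            )
        if not (np.all(np.isfinite(cu)) and np.all(np.isfinite(cv))):
            raise ValueError("transform coefficients must be finite")
        self.degree = int(degree)
        self.coeffs_u = cu
        self.coeffs_v = cv

    @property
    def coeffs(self) -> np.ndarray:
        """Coefficients stacked as a ``(2, n_terms)`` matrix (u row, v row)."""
        return np.stack([self.coeffs_u, self.coeffs_v])

    def __call__(self, x, y):
        return map_coords(self, x, y)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PolynomialTransform)
            and self.degree == other.degree
            and np.array_equal(self.coeffs_u, other.coeffs_u)
            and np.array_equal(self.coeffs_v, other.coeffs_v)
        )

    def __repr__(self) -> str:
        return (f"{type(self).__name__}(degree={self.degree}, "
                f"coeffs_u={self.coeffs_u.tolist()}, coeffs_v={self.coeffs_v.tolist()})")

    def to_dict(self) -> dict:
        """JSON-ready representation (pixel units, backward mapping)."""
        return {
            "degree": self.degree,
            "Q": [self.coeffs_u.tolist(), self.coeffs_v.tolist()],
            "coordinate_units": "pixel",
            "mapping": "backward",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialTransform":
        degree = int(d["degree"])
        cu, cv = d["Q"]
        if degree == 2:
            return QuadraticTransform(np.array([cu, cv], dtype=float))
        return cls(degree, cu, cv)


class QuadraticTransform(PolynomialTransform):
    """Quadratic (degree-2) transform: a 2x6 matrix ``Q`` on ``[x^2, y^2, xy, x, y, 1]``."""

    def __init__(self, Q):
        Q = np.asarray(Q, dtype=float)
        if Q.shape != (2, 6):
            raise ValueError(f"Q must be a 2x6 matrix, got shape {Q.shape}")
        super().__init__(2, Q[0], Q[1])

    @property
    def Q(self) -> np.ndarray:
        return self.coeffs

    @property
    def params(self) -> np.ndarray:
        """The 12 parameters q00..q05, q10..q15 as a flat vector."""
        return self.coeffs.ravel()

    @classmethod
    def identity(cls) -> "QuadraticTransform":
        Q = np.zeros((2, 6))
        Q[0, 3] = 1.0  # q03: u = x
        Q[1, 4] = 1.0  # q14: v = y
        return cls(Q)

    @classmethod
    def from_params(cls, params: Sequence[float]) -> "QuadraticTransform":
        p = np.asarray(params, dtype=float)
        if p.shape != (12,):
            raise ValueError(f"expected 12 parameters, got shape {p.shape}")
        return cls(p.reshape(2, 6))


@dataclass
class WarpConfig:
    """How :func:`warp_image` samples the source image.

    ``fill_value`` is used for samples falling outside the source bounds;
    0 (black) matches the fundus field-of-view background.
    """

    interpolation: str = "bilinear"  # {"bilinear", "nearest"}
    fill_value: float = 0.0

    def __post_init__(self):
        if self.interpolation not in ("bilinear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


def identity_transform(degree: int) -> PolynomialTransform:
    """The identity mapping ``u = x, v = y`` at the given degree."""
    _check_degree(degree)
    if degree == 2:
        return QuadraticTransform.identity()
    nt = n_terms(degree)
    cu = np.zeros(nt)
    cv = np.zeros(nt)
    cu[-3] = 1.0  # x
    cv[-2] = 1.0  # y
    return PolynomialTransform(degree, cu, cv)


def map_coords(t: PolynomialTransform, x, y):
    """Map output coordinates ``(x, y)`` to source coordinates ``(u, v)``.

    Pure polynomial evaluation; works elementwise on arrays.
    """
    d = design_vector(x, y, t.degree)
    u = d @ t.coeffs_u
    v = d @ t.coeffs_v
    return u, v


def _gather(image: np.ndarray, yi: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """Index ``image[yi, xi]`` with clipped integer indices (2D or HxWxC)."""
    h, w = image.shape[:2]
    yi = np.clip(yi, 0, h - 1)
    xi = np.clip(xi, 0, w - 1)
    return image[yi, xi]


def bilinear_sample(image: np.ndarray, u, v, fill_value: float = 0.0,
                    with_grad: bool = False):
    """Sample ``image`` at real-valued locations ``(u, v)`` bilinearly.

    ``u`` indexes columns, ``v`` rows.  Samples outside ``[0, W-1] x
    [0, H-1]`` take ``fill_value``.  When ``with_grad`` is true, also
    returns ``(d_sample/d_u, d_sample/d_v)`` — the piecewise-linear
    derivatives of the interpolant, zero at out-of-bounds samples —
    which is what makes the warp differentiable w.r.t. the transform
    parameters.
    """
    img = np.asarray(image, dtype=float)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    h, w = img.shape[:2]

    x0 = np.floor(u).astype(np.int64)
    y0 = np.floor(v).astype(np.int64)
    fx = u - x0
    fy = v - y0
    valid = (u >= 0) & (u <= w - 1) & (v >= 0) & (v <= h - 1)

    i00 = _gather(img, y0, x0)
    i01 = _gather(img, y0, x0 + 1)
    i10 = _gather(img, y0 + 1, x0)
    i11 = _gather(img, y0 + 1, x0 + 1)

    if img.ndim == 3:  # broadcast weights over the channel axis
        fx = fx[..., None]
        fy = fy[..., None]
        valid_b = valid[..., None]
    else:
        valid_b = valid

    top = i00 * (1 - fx) + i01 * fx
    bot = i10 * (1 - fx) + i11 * fx
    out = top * (1 - fy) + bot * fy
    out = np.where(valid_b, out, fill_value)
    if not with_grad:
        return out
    du = ((i01 - i00) * (1 - fy) + (i11 - i10) * fy)
    dv = (bot - top)
    du = np.where(valid_b, du, 0.0)
    dv = np.where(valid_b, dv, 0.0)
    return out, du, dv


def _round_half_away(a: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (documented tie rule)."""
    return np.trunc(a + np.copysign(0.5, a)).astype(np.int64)


def nearest_sample(image: np.ndarray, u, v, fill_value: float = 0.0) -> np.ndarray:
    """Nearest-neighbour sampling with round-half-away-from-zero ties."""
    img = np.asarray(image)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    h, w = img.shape[:2]
    xi = _round_half_away(u)
    yi = _round_half_away(v)
    valid = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    out = _gather(img, yi, xi)
    if img.ndim == 3:
        valid = valid[..., None]
    return np.where(valid, out, np.asarray(fill_value, dtype=img.dtype))


def _output_grid(shape) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape[:2]
    y, x = np.mgrid[0:h, 0:w]
    return x.astype(float), y.astype(float)


def warp_image(image: np.ndarray, t: PolynomialTransform,
               cfg: WarpConfig | None = None) -> np.ndarray:
    """Warp ``image`` by ``t`` (backward mapping).

    Every output pixel ``(x, y)`` is filled by sampling the source at
    ``(u, v) = map_coords(t, x, y)``.  Output shape equals input shape.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("cannot warp an empty image")
    cfg = cfg or WarpConfig()
    x, y = _output_grid(img.shape)
    u, v = map_coords(t, x, y)
    if cfg.interpolation == "nearest":
        return nearest_sample(img, u, v, cfg.fill_value)
    out = bilinear_sample(img, u, v, cfg.fill_value)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), np.iinfo(img.dtype).min, np.iinfo(img.dtype).max)
    return out.astype(img.dtype, copy=False)


def warp_mask(mask: np.ndarray, t: PolynomialTransform) -> np.ndarray:
    """Warp a binary field-of-view mask (nearest neighbour, fill 0).

    The output stays binary; non-binary input is rejected.
    """
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("warp_mask expects a binary {0,1} mask")
    return warp_image(m, t, WarpConfig(interpolation="nearest", fill_value=0))


def normalize_params(t: "QuadraticTransform | np.ndarray", ranges) -> np.ndarray:
    """Map the 12 quadratic parameters to [0, 1] via ``(q - min)/(max - min)``.

    ``ranges`` must expose ``mins`` and ``maxs`` arrays in canonical
    parameter order (see ``ParameterRanges``).  Degenerate ranges
    (max == min) are rejected — they cannot be normalized.
    """
    q = t.params if isinstance(t, QuadraticTransform) else np.asarray(t, dtype=float)
    mins = np.asarray(ranges.mins, dtype=float)
    maxs = np.asarray(ranges.maxs, dtype=float)
    width = maxs - mins
    if np.any(width <= 0):
        bad = [PARAM_NAMES[i] for i in np.nonzero(width <= 0)[0]]
        raise ValueError(f"degenerate parameter range(s) (max <= min): {bad}")
    return (q - mins) / width


def denormalize_params(normalized: np.ndarray, ranges) -> QuadraticTransform:
    """Inverse of :func:`normalize_params`: unit-scaled vector -> transform."""
    z = np.asarray(normalized, dtype=float)
    mins = np.asarray(ranges.mins, dtype=float)
    maxs = np.asarray(ranges.maxs, dtype=float)
    return QuadraticTransform.from_params(mins + z * (maxs - mins))


def invert_coords(t: QuadraticTransform, u, v, n_iter: int = 25):
    """Numerically invert ``t``: find ``(x, y)`` with ``map_coords(t, x, y) = (u, v)``.

    Fixed-point iteration on the degree-1 part: the affine component is
    solved exactly each step and the quadratic residual re-evaluated at
    the current estimate.  Converges for the mild curvatures this
    package samples (quadratic terms small relative to linear terms).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    Q = t.Q
    A = np.array([[Q[0, 3], Q[0, 4]], [Q[1, 3], Q[1, 4]]])
    b = Q[:, 5]
    Ainv = np.linalg.inv(A)
    x, y = u.copy(), v.copy()
    for _ in range(n_iter):
        qx = Q[0, 0] * x**2 + Q[0, 1] * y**2 + Q[0, 2] * x * y
        qy = Q[1, 0] * x**2 + Q[1, 1] * y**2 + Q[1, 2] * x * y
        rx = u - b[0] - qx
        ry = v - b[1] - qy
        x = Ainv[0, 0] * rx + Ainv[0, 1] * ry
        y = Ainv[1, 0] * rx + Ainv[1, 1] * ry
    return x, y


def rescale_transform(t: QuadraticTransform, scale_x: float,
                      scale_y: float | None = None) -> QuadraticTransform:
    """Re-express ``t`` on a grid scaled by ``(scale_x, scale_y)``.

    New coordinates relate to old ones by ``x' = scale_x * x``,
    ``y' = scale_y * y``.  Substituting ``x -> x'/sx, y -> y'/sy`` into
    the quadratic mapping and rescaling the outputs (``u`` by ``sx``,
    ``v`` by ``sy``) multiplies each coefficient by the output scale and
    divides it by its monomial's scale (``sx^2`` for x^2, ``sx*sy`` for
    xy, 1 for the constant).  Used to transfer a transform predicted at
    the model's input resolution to the original image resolution.
    """
    sx = float(scale_x)
    sy = sx if scale_y is None else float(scale_y)
    if sx <= 0 or sy <= 0:
        raise ValueError("scales must be positive")
    mono_scale = np.array([sx**2, sy**2, sx * sy, sx, sy, 1.0])
    Q = t.Q.copy()
    Q[0] *= sx / mono_scale
    Q[1] *= sy / mono_scale
    return QuadraticTransform(Q)
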