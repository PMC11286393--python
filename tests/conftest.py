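import numpy as np
import pytest

from polyreg import ParameterRanges, QuadraticTransform


def warp_oracle(image: np.ndarray, Q: np.ndarray, interpolation: str = "bilinear",
                fill: float = 0.0) -> np.ndarray:
    """Independent per-pixel scalar-loop warp (backward mapping).

    Deliberately naive: evaluates the quadratic polynomial and the
    bilinear/nearest interpolation pixel by pixel with plain Python
    arithmetic, sharing no code with the vectorized engine.
    """
    h, w = image.shape[:2]
    out = np.full_like(np.asarray(image, dtype=float), fill)
    for yy in range(h):
        for xx in range(w):
            u = (Q[0][0] * xx * xx + Q[0][1] * yy * yy + Q[0][2] * xx * yy
                 + Q[0][3] * xx + Q[0][4] * yy + Q[0][5])
            v = (Q[1][0] * xx * xx + Q[1][1] * yy * yy + Q[1][2] * xx * yy
                 + Q[1][3] * xx + Q[1][4] * yy + Q[1][5])
            if interpolation == "nearest":
                import math
                ui = int(math.floor(abs(u) + 0.5)) * (1 if u >= 0 else -1)
                vi = int(math.floor(abs(v) + 0.5)) * (1 if v >= 0 else -1)
                if 0 <= ui < w and 0 <= vi < h:
                    out[yy, xx] = image[vi, ui]
                continue
            if not (0 <= u <= w - 1 and 0 <= v <= h - 1):
                continue
            x0, y0 = int(np.floor(u)), int(np.floor(v))
            fx, fy = u - x0, v - y0
            x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
            out[yy, xx] = (image[y0, x0] * (1 - fx) * (1 - fy)
                           + image[y0, x1] * fx * (1 - fy)
                           + image[y1, x0] * (1 - fx) * fy
                           + image[y1, x1] * fx * fy)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ranges():
    """Default parameter ranges on a 64 px grid."""
    return ParameterRanges.default(64)


@pytest.fixture
def random_image(rng):
    return rng.uniform(0, 255, size=(16, 16))


def random_small_transform(rng) -> QuadraticTransform:
    """A random quadratic transform with mild coefficients (16 px scale)."""
    Q = np.zeros((2, 6))
    Q[0, :3] = rng.uniform(-2e-3, 2e-3, 3)
    Q[1, :3] = rng.uniform(-2e-3, 2e-3, 3)
    Q[0, 3:5] = [1, 0] + rng.uniform(-0.08, 0.08, 2)
    Q[1, 3:5] = [0, 1] + rng.uniform(-0.08, 0.08, 2)
    Q[:, 5] = rng.uniform(-3, 3, 2)
    return QuadraticTransform(Q)
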