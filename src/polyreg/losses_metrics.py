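"""Losses and evaluation statistics for polynomial-parameter regression.

Supervised pretraining minimizes a hybrid loss on [0, 1]-normalized
parameter vectors,

    L_hybrid(Q, Q') = omega * MSLE(Q, Q') + (1 - omega) * (1 - CoS(Q, Q')),

combining the mean squared logarithmic error (scale-robust across
parameters of very different magnitudes) with cosine similarity
(directional consistency, tolerant of sign structure).  Unsupervised
fine-tuning minimizes ``1 - NCC`` between the fixed image and the
warped moving image.  Evaluation covers image-level similarity (global
SSIM, NCC) and parameter-level agreement (per-parameter Pearson
correlation and Bland-Altman limits of agreement, plus a pooled
regression over all parameters).

MSLE is only defined for entries > -1; this module refuses raw
pixel-unit parameter vectors (which contain large negative entries) —
compute it on normalized parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .polywarp import PARAM_NAMES, normalize_params

__all__ = [
    "HybridLossConfig",
    "SSIMConstants",
    "AgreementStats",
    "RegressionReport",
    "msle",
    "cosine_similarity",
    "hybrid_loss",
    "hybrid_loss_and_grad",
    "ncc",
    "ncc_loss",
    "ncc_and_grad",
    "ssim",
    "pearson_r",
    "bland_altman",
    "pooled_regression_report",
]


@dataclass
class HybridLossConfig:
    """Weighting of the hybrid loss; ``omega = 0.5`` gives the MSLE and
    cosine terms equal contribution."""

    omega: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")


@dataclass
class SSIMConstants:
    """Stabilizing constants for SSIM: C1 = (0.01 L)^2, C2 = (0.03 L)^2
    with ``L`` the dynamic range of the images (255 for 8-bit data)."""

    L: float = 255.0
    C1: float = field(init=False)
    C2: float = field(init=False)

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("dynamic range L must be > 0")
        self.C1 = (0.01 * self.L) ** 2
        self.C2 = (0.03 * self.L) ** 2


def _check_msle_domain(a: np.ndarray) -> None:
    if np.any(a <= -1.0):
        raise ValueError(
            "MSLE requires all entries > -1 (log domain); "
            "normalize parameters to [0, 1] before computing it"
        )


def msle(target_vec, pred_vec) -> float:
    """Mean squared logarithmic error: mean of (log(1+t) - log(1+p))^2."""
    t = np.asarray(target_vec, dtype=float)
    p = np.asarray(pred_vec, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    _check_msle_domain(t)
    _check_msle_domain(p)
    return float(np.mean((np.log1p(t) - np.log1p(p)) ** 2))


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two vectors (1 parallel, -1 anti-parallel)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def hybrid_loss(target_vec, pred_vec, cfg: HybridLossConfig | None = None) -> float:
    """``omega * MSLE + (1 - omega) * (1 - CoS)``; zero iff pred == target."""
    cfg = cfg or HybridLossConfig()
    return (cfg.omega * msle(target_vec, pred_vec)
            + (1.0 - cfg.omega) * (1.0 - cosine_similarity(target_vec, pred_vec)))


def hybrid_loss_and_grad(targets: np.ndarray, preds: np.ndarray,
                         cfg: HybridLossConfig | None = None,
                         ) -> tuple[float, np.ndarray]:
    """Batched hybrid loss and its analytic gradient w.r.t. ``preds``.

    ``targets`` and ``preds`` have shape ``(batch, n)``.  Returns the
    batch-mean loss and the gradient array of the same shape.  A tiny
    epsilon stabilizes the cosine term's norms; the training loop keeps
    predictions inside the log domain before calling this.
    """
    cfg = cfg or HybridLossConfig()
    t = np.asarray(targets, dtype=float)
    p = np.asarray(preds, dtype=float)
    if t.shape != p.shape or t.ndim != 2:
        raise ValueError(f"expected matching (batch, n) shapes, got {t.shape}, {p.shape}")
    _check_msle_domain(t)
    _check_msle_domain(p)
    B, N = t.shape
    eps = 1e-12

    dlog = np.log1p(t) - np.log1p(p)
    msle_per = np.mean(dlog**2, axis=1)
    dmsle = -2.0 * dlog / (1.0 + p) / N

    nt = np.linalg.norm(t, axis=1, keepdims=True) + eps
    npred = np.linalg.norm(p, axis=1, keepdims=True) + eps
    dot = np.sum(t * p, axis=1, keepdims=True)
    cos = dot / (nt * npred)
    dcos = t / (nt * npred) - cos * p / npred**2

    loss = float(np.mean(cfg.omega * msle_per + (1 - cfg.omega) * (1 - cos[:, 0])))
    grad = (cfg.omega * dmsle - (1 - cfg.omega) * dcos) / B
    return loss, grad


def _region(f: np.ndarray, w: np.ndarray, mask) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=float)
    w = np.asarray(w, dtype=float)
    if f.shape != w.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {w.shape}")
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        return f[sel], w[sel]
    return f.ravel(), w.ravel()


def ncc(f, w, mask=None) -> float:
    """Normalized cross correlation over the evaluated region.

    Each image is centered by its own mean and normalized by its own
    energy, making the score invariant to per-image affine intensity
    maps with positive gain.  ``mask`` optionally restricts the region
    (e.g. to the intersection of two fields of view).
    """
    fv, wv = _region(f, w, mask)
    fc = fv - fv.mean()
    wc = wv - wv.mean()
    denom = np.sqrt(np.sum(fc**2) * np.sum(wc**2))
    if denom == 0.0:
        raise ValueError("NCC is undefined when an image is constant over the region")
    return float(np.sum(fc * wc) / denom)


def ncc_loss(f, w, mask=None) -> float:
    """The unsupervised registration objective, ``1 - NCC``."""
    return 1.0 - ncc(f, w, mask=mask)


def ncc_and_grad(f: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    """NCC and its analytic gradient with respect to ``w``.

    The gradient of the centering is already mean-free, so the compact
    form ``fc/(|fc||wc|) - ncc * wc/|wc|^2`` is exact.  Used by the
    fine-tuning loop to differentiate ``1 - NCC`` through the warp.
    """
    fv = np.asarray(f, dtype=float)
    wv = np.asarray(w, dtype=float)
    fc = fv - fv.mean()
    wc = wv - wv.mean()
    nf = np.sqrt(np.sum(fc**2))
    nw = np.sqrt(np.sum(wc**2))
    if nf == 0.0 or nw == 0.0:
        raise ValueError("NCC is undefined for constant images")
    value = float(np.sum(fc * wc) / (nf * nw))
    grad = fc / (nf * nw) - value * wc / nw**2
    return value, grad


def ssim(a, b, k: SSIMConstants | None = None, windowed: bool = False) -> float:
    """Structural similarity index from global image statistics.

    ``(2 mu_a mu_b + C1)(2 sigma_ab + C2) /
    ((mu_a^2 + mu_b^2 + C1)(sigma_a^2 + sigma_b^2 + C2))``
    with means, variances and covariance taken over the whole image.
    Equals 1 iff the images are identical.  ``windowed=True`` computes
    the conventional sliding-window mean SSIM instead (scikit-image).
    """
    k = k or SSIMConstants()
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if windowed:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(
            x, y, data_range=k.L, channel_axis=-1 if x.ndim == 3 else None))
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = np.mean((x - mx) * (y - my))
    return float(((2 * mx * my + k.C1) * (2 * cov + k.C2))
                 / ((mx**2 + my**2 + k.C1) * (vx + vy + k.C2)))


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value (t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AgreementStats:
    """Bland-Altman agreement plus linear correlation for one quantity."""

    mean_difference: float
    lower_limit: float
    upper_limit: float
    pearson_r: float
    p_value: float
    means: Optional[np.ndarray] = None  # paired means, for plotting
    diffs: Optional[np.ndarray] = None  # paired differences, for plotting

    def to_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference,
            "lower_limit": self.lower_limit,
            "upper_limit": self.upper_limit,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementStats":
        return cls(**d)


def bland_altman(x, y) -> AgreementStats:
    """Bland-Altman agreement between paired measurements ``x`` and ``y``.

    ``mean_difference = mean(x - y)``; the limits of agreement are
    ``mean +- 1.96 * SD(x - y)`` with the sample SD (n-1 denominator,
    0 when all differences are equal).  The Pearson fields relate ``x``
    to ``y`` directly and are NaN when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1)) if np.ptp(d) > 0 else 0.0
    try:
        r, p = pearson_r(x, y)
    except ValueError:
        r, p = float("nan"), float("nan")
    return AgreementStats(
        mean_difference=md,
        lower_limit=md - 1.96 * sd,
        upper_limit=md + 1.96 * sd,
        pearson_r=r,
        p_value=p,
        means=(x + y) / 2.0,
        diffs=d,
    )


@dataclass
class RegressionReport:
    """Parameter-level and image-level evaluation of a trained regressor."""

    per_parameter: dict[str, AgreementStats]
    pooled_r: float
    pooled_p: float
    ssim_before: Optional[float] = None
    ssim_after: Optional[float] = None
    ncc_before: Optional[float] = None
    ncc_after: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "per_parameter": {k: v.to_dict() for k, v in self.per_parameter.items()},
            "pooled_r": self.pooled_r,
            "pooled_p": self.pooled_p,
            "ssim_before": self.ssim_before,
            "ssim_after": self.ssim_after,
            "ncc_before": self.ncc_before,
            "ncc_after": self.ncc_after,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionReport":
        per = {k: AgreementStats.from_dict(v) for k, v in d["per_parameter"].items()}
        return cls(per_parameter=per, pooled_r=d["pooled_r"], pooled_p=d["pooled_p"],
                   ssim_before=d.get("ssim_before"), ssim_after=d.get("ssim_after"),
                   ncc_before=d.get("ncc_before"), ncc_after=d.get("ncc_after"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "RegressionReport":
        return cls.from_dict(json.loads(s))

    def to_frame(self) -> pd.DataFrame:
        """Per-parameter stats as a DataFrame (one row per parameter)."""
        rows = {k: v.to_dict() for k, v in self.per_parameter.items()}
        return pd.DataFrame.from_dict(rows, orient="index")


def _gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return img.mean(axis=-1) if img.ndim == 3 else img


def pooled_regression_report(
    pred_params: np.ndarray,
    target_params: np.ndarray,
    ranges,
    image_pairs_before_after: Optional[Sequence[tuple]] = None,
) -> RegressionReport:
    """Full evaluation: per-parameter agreement, pooled correlation, and
    (optionally) image-level SSIM/NCC before and after alignment.

    ``pred_params`` and ``target_params`` are ``(n, 12)`` arrays in
    pixel units; both are normalized to [0, 1] per parameter via
    ``ranges`` before any statistic is computed, so parameters of very
    different magnitudes contribute comparably.  The pooled correlation
    concatenates all 12 normalized parameter columns into one
    regression.  ``image_pairs_before_after`` is a sequence of
    ``(fixed, moving, warped)`` triples; the before metrics compare
    fixed to moving, the after metrics fixed to warped.
    """
    P = np.asarray(pred_params, dtype=float)
    T = np.asarray(target_params, dtype=float)
    if P.shape != T.shape or P.ndim != 2 or P.shape[1] != 12:
        raise ValueError(f"expected matching (n, 12) arrays, got {P.shape} and {T.shape}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 pairs for a regression report")
    Pn = np.stack([normalize_params(p, ranges) for p in P])
    Tn = np.stack([normalize_params(t, ranges) for t in T])

    per = {name: bland_altman(Pn[:, i], Tn[:, i])
           for i, name in enumerate(PARAM_NAMES)}
    pooled_r, pooled_p = pearson_r(Pn.ravel(), Tn.ravel())

    ssim_b = ssim_a = ncc_b = ncc_a = None
    if image_pairs_before_after:
        sb, sa, nb, na = [], [], [], []
        for fixed, moving, warped in image_pairs_before_after:
            fg, mg, wg = _gray(fixed), _gray(moving), _gray(warped)
            sb.append(ssim(fg, mg))
            sa.append(ssim(fg, wg))
            nb.append(ncc(fg, mg))
            na.append(ncc(fg, wg))
        ssim_b, ssim_a = float(np.mean(sb)), float(np.mean(sa))
        ncc_b, ncc_a = float(np.mean(nb)), float(np.mean(na))

    return RegressionReport(per_parameter=per, pooled_r=pooled_r, pooled_p=pooled_p,
                            ssim_before=ssim_b, ssim_after=ssim_a,
                            ncc_before=ncc_b, ncc_after=ncc_a)
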