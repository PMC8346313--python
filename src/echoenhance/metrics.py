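"""Image-quality scores: pixel MSE, PSNR and SSIM.

All three are defined on the integer intensity scale ``0 .. 2**n - 1`` of
the images' bit depth ``n``.  SSIM is computed from single global moments
(means, population variances, covariance) by default; a sliding-window
variant (8x8, mean-aggregated) is available for comparison with common
practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import EchoImage

__all__ = ["QualityReport", "image_mse", "psnr", "ssim", "evaluate_pair"]


def _check_pair(x: EchoImage, y: EchoImage) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.bit_depth != y.bit_depth:
        raise ValueError(f"bit depth mismatch: {x.bit_depth} vs {y.bit_depth}")


def image_mse(x: EchoImage, y: EchoImage) -> float:
    """Mean squared difference on the ``0 .. 2**n - 1`` scale."""
    _check_pair(x, y)
    return float(np.mean((x.to_integer_scale() - y.to_integer_scale()) ** 2))


def psnr(x: EchoImage, y: EchoImage) -> float:
    """``10 * log10((2**n - 1)^2 / MSE)`` in dB; ``+inf`` when MSE is 0."""
    mse = image_mse(x, y)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(x.levels**2 / mse)


def _ssim_from_moments(
    mx: float, my: float, vx: float, vy: float, cov: float, e1: float, e2: float
) -> float:
    return ((2 * mx * my + e1) * (2 * cov + e2)) / (
        (mx**2 + my**2 + e1) * (vx + vy + e2)
    )


def ssim(
    x: EchoImage,
    y: EchoImage,
    e1: float | None = None,
    e2: float | None = None,
    mode: str = "global",
    window: int = 8,
) -> float:
    """Structural similarity on the integer scale.

    ``mode='global'`` (default) uses whole-image means, population variances
    and covariance; ``mode='window'`` averages the same statistic over all
    dense ``window x window`` patches.  Stabilizers default to
    ``(0.01 * L)**2`` and ``(0.03 * L)**2`` with ``L = 2**n - 1``.
    """
    _check_pair(x, y)
    L = x.levels
    if e1 is None:
        e1 = (0.01 * L) ** 2
    if e2 is None:
        e2 = (0.03 * L) ** 2
    xs = x.to_integer_scale()
    ys = y.to_integer_scale()
    if mode == "global":
        return float(
            _ssim_from_moments(
                xs.mean(),
                ys.mean(),
                xs.var(),
                ys.var(),
                float(np.mean((xs - xs.mean()) * (ys - ys.mean()))),
                e1,
                e2,
            )
        )
    if mode == "window":
        if min(x.shape) < window:
            raise ValueError(f"image smaller than the {window}x{window} window")
        xw = sliding_window_view(xs, (window, window))
        yw = sliding_window_view(ys, (window, window))
        mx = xw.mean(axis=(-2, -1))
        my = yw.mean(axis=(-2, -1))
        vx = xw.var(axis=(-2, -1))
        vy = yw.var(axis=(-2, -1))
        cov = (xw * yw).mean(axis=(-2, -1)) - mx * my
        values = (2 * mx * my + e1) * (2 * cov + e2) / ((mx**2 + my**2 + e1) * (vx + vy + e2))
        return float(values.mean())
    raise ValueError(f"unknown ssim mode {mode!r}; expected 'global' or 'window'")


@dataclass(frozen=True)
class QualityReport:
    """One reference/test comparison: MSE, PSNR (dB) and SSIM."""

    mse: float
    psnr_db: float
    ssim: float
    e1: float
    e2: float


def evaluate_pair(
    reference: EchoImage, test: EchoImage, ssim_mode: str = "global"
) -> QualityReport:
    """Compute all three scores for one image pair."""
    L = reference.levels
    e1 = (0.01 * L) ** 2
    e2 = (0.03 * L) ** 2
    return QualityReport(
        mse=image_mse(reference, test),
        psnr_db=psnr(reference, test),
        ssim=ssim(reference, test, mode=ssim_mode),
        e1=e1,
        e2=e2,
    )
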