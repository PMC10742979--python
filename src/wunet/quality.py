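"""PSNR and SSIM against a designated reference stack.

PSNR is 10*log10(data_range^2 / MSE) with the MSE taken over the whole
scope (one optical section, or a full stack as a single volume).  SSIM uses
a Gaussian window (11 pixels, sigma 1.5, k1=0.01, k2=0.03); volumetric
scope applies a true 3-D window when the stack is deep enough and falls
back to averaging per-section SSIM otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .stack_io import TissueStack

__all__ = ["QualityReport", "psnr", "ssim", "stack_quality"]


@dataclass
class QualityReport:
    psnr_db: float
    ssim: float
    scope: str                    # "section" or "stack"
    data_range: float
    reference_provenance: str = ""
    identical: bool = False       # MSE was zero; psnr_db flagged infinite


def _data_range(reference: np.ndarray, data_range: float | None) -> float:
    if data_range is not None:
        if data_range <= 0:
            raise ValueError("data_range must be positive")
        return float(data_range)
    rng = float(reference.max() - reference.min())
    if rng <= 0:
        raise ValueError("reference has zero intensity spread; pass "
                         "data_range explicitly")
    return rng


def psnr(reference: np.ndarray, test: np.ndarray,
         data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical inputs.

    ``data_range`` defaults to max - min of the reference.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {test.shape}")
    dr = _data_range(reference, data_range)
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(dr * dr / mse)


def ssim(reference: np.ndarray, test: np.ndarray,
         data_range: float | None = None, window: int = 11,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
         volumetric: bool = True) -> float:
    """Mean structural similarity with a Gaussian window.

    For 3-D input, a 3-D window is used when every axis fits the window
    and ``volumetric`` is true; otherwise per-section SSIM values (first
    axis treated as depth) are averaged.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {test.shape}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    dr = _data_range(reference, data_range)
    kwargs = dict(win_size=window, gaussian_weights=True, sigma=sigma,
                  K1=k1, K2=k2, data_range=dr, use_sample_covariance=False)
    if reference.ndim == 2:
        if min(reference.shape) < window:
            raise ValueError("window larger than image")
        return float(structural_similarity(reference, test, **kwargs))
    if reference.ndim == 3:
        if volumetric and min(reference.shape) >= window:
            return float(structural_similarity(reference, test, **kwargs))
        if min(reference.shape[1:]) < window:
            raise ValueError("window larger than sections")
        vals = [structural_similarity(r, t, **kwargs)
                for r, t in zip(reference, test)]
        return float(np.mean(vals))
    raise ValueError("expected a 2-D section or 3-D volume")


def stack_quality(reference: TissueStack, test: TissueStack,
                  data_range: float | None = None,
                  window: int = 11) -> QualityReport:
    """Volumetric PSNR/SSIM of a test stack against its reference.

    Volumetric PSNR uses a single MSE over the whole stack (the stricter
    contract), not the mean of per-section PSNRs.
    """
    ref = reference.sections()
    tst = test.sections()
    if ref.shape != tst.shape:
        raise ValueError("stacks must be congruent")
    dr = _data_range(ref, data_range)
    p = psnr(ref, tst, dr)
    s = ssim(ref, tst, dr, window=window)
    return QualityReport(psnr_db=p, ssim=s, scope="stack", data_range=dr,
                         reference_provenance=reference.provenance,
                         identical=not np.isfinite(p))
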