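"""Metabolic-function metrics from two-channel autofluorescence sections.

Two families of metrics are extracted per optical section:

* the **optical redox ratio** RR = FAD / (FAD + NAD(P)H) per pixel, summarised
  by its in-mask mean and interquartile range (intra-field heterogeneity);
* the **mitochondrial clustering exponent** beta: the cytoplasmic NAD(P)H
  intensity-fluctuation image is Fourier transformed, its power spectral
  density radially averaged, and an inverse power law R(k) = A * k^-beta is
  fit by ordinary least squares in log-log coordinates.

Per stack, the mean and sample variance (n-1 denominator) across depth of
mean RR, RR IQR and beta form the six stack-level summaries used to compare
denoising models against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack_io import TissueStack

__all__ = [
    "RedoxMap", "PsdFit", "MetricProfile", "redox_map", "section_rr_stats",
    "fluctuation_image", "psd2d", "radial_psd", "fit_beta", "stack_metrics",
    "SUMMARY_NAMES",
]

#: the six stack-level summaries, in reporting order
SUMMARY_NAMES = ("mean_rr", "var_mean_rr", "mean_rr_iqr", "var_rr_iqr",
                 "mean_beta", "var_beta")

#: default spatial-frequency band for the power-law fit (cycles/pixel);
#: the lower edge is 3/N for an N-pixel section (set at fit time)
DEFAULT_FIT_KMAX = 0.45

MIN_VALID_PIXELS = 100
MIN_FIT_BINS = 8


@dataclass
class RedoxMap:
    """Per-pixel redox ratio with its validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass
class PsdFit:
    """Radially averaged PSD and its log-log power-law fit."""

    k: np.ndarray
    psd: np.ndarray
    A: float
    beta: float
    fit_range: tuple[float, float]
    r_squared_fit: float


@dataclass
class MetricProfile:
    """Per-depth metric arrays and the six stack-level summaries."""

    mean_rr: np.ndarray
    rr_iqr: np.ndarray
    beta: np.ndarray
    summaries: dict[str, float]
    n_failed_depths: int = 0

    @property
    def n_depths(self) -> int:
        return len(self.mean_rr)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth": np.arange(self.n_depths),
                             "mean_rr": self.mean_rr,
                             "rr_iqr": self.rr_iqr,
                             "beta": self.beta})


# ---------------------------------------------------------------------------
# redox ratio
# ---------------------------------------------------------------------------

def redox_map(nadph: np.ndarray, fad: np.ndarray,
              mask: np.ndarray | None = None,
              eps: float = 1e-12) -> RedoxMap:
    """Pixelwise RR = FAD / (FAD + NAD(P)H) on valid pixels.

    A pixel is valid when the channel sum exceeds ``eps`` and, if a mask is
    given, it lies inside the mask.  RR is invariant to common positive
    rescaling of both channels and bounded in [0, 1] for non-negative
    inputs.
    """
    nadph = np.asarray(nadph, dtype=float)
    fad = np.asarray(fad, dtype=float)
    if nadph.shape != fad.shape:
        raise ValueError(f"shape mismatch: {nadph.shape} vs {fad.shape}")
    if (nadph < 0).any() or (fad < 0).any():
        raise ValueError("channel intensities must be non-negative")
    total = nadph + fad
    valid = total > eps
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != nadph.shape:
            raise ValueError("mask shape mismatch")
        valid = valid & mask
    values = np.divide(fad, total, out=np.zeros_like(total), where=valid)
    return RedoxMap(values=values, valid_mask=valid)


def section_rr_stats(rmap: RedoxMap) -> tuple[float, float]:
    """In-mask mean RR and interquartile range (linear-interpolated
    percentiles).  Returns (nan, nan) with a warning below
    ``MIN_VALID_PIXELS`` valid pixels."""
    vals = rmap.valid_values
    if vals.size < MIN_VALID_PIXELS:
        warnings.warn(f"only {vals.size} valid pixels; RR statistics "
                      "undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    q25, q75 = np.percentile(vals, [25, 75])
    return float(vals.mean()), float(q75 - q25)


# ---------------------------------------------------------------------------
# mitochondrial clustering
# ---------------------------------------------------------------------------

def fluctuation_image(nadph: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Intensity-fluctuation image: divide by the in-mask mean.

    Out-of-mask pixels are replaced by 1 (the in-mask mean after
    normalisation) to suppress mask-boundary spectral leakage.  The result
    is invariant to global intensity scaling.
    """
    nadph = np.asarray(nadph, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != nadph.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    m = nadph[mask].mean()
    if m <= 0:
        raise ValueError("in-mask mean must be positive")
    out = nadph / m
    out[~mask] = 1.0
    return out


def psd2d(image: np.ndarray) -> np.ndarray:
    """Two-dimensional power spectral density |FFT|^2 / n_pixels.

    With this normalisation the full PSD sums to n_pixels times the
    variance for zero-mean input (Parseval).
    """
    image = np.asarray(image, dtype=float)
    F = np.fft.fft2(image)
    return np.abs(F) ** 2 / image.size


def radial_psd(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectral density of a square section.

    The PSD is |FFT|^2 / n_pixels (so the full PSD sums to n_pixels times
    the variance for zero-mean input), averaged in annular bins one
    frequency sample wide.  The DC bin is excluded; bin centres are
    i / N cycles/pixel for i = 1 .. N//2.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square; pad or crop upstream")
    n = image.shape[0]
    if n < 32:
        raise ValueError("side must be >= 32")
    psd2 = psd2d(image)
    fx = np.fft.fftfreq(n)
    kr = np.hypot(fx[:, None], fx[None, :])
    idx = np.rint(kr * n).astype(int)
    nbins = n // 2
    counts = np.bincount(idx.ravel(), minlength=nbins + 1)[1:nbins + 1]
    sums = np.bincount(idx.ravel(), weights=psd2.ravel(),
                       minlength=nbins + 1)[1:nbins + 1]
    k = np.arange(1, nbins + 1) / n
    with np.errstate(invalid="ignore"):
        psd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return k, psd


def fit_beta(k: np.ndarray, psd: np.ndarray,
             fit_range: tuple[float, float] | None = None) -> PsdFit:
    """Ordinary least squares of log10(psd) on log10(k) over ``fit_range``.

    beta is the negative slope and A the linear-scale amplitude.  The
    default band spans [3/N, 0.45] cycles/pixel, excluding the DC-adjacent
    bins and the anisotropic corner frequencies.  Non-positive PSD bins in
    range are excluded; fewer than ``MIN_FIT_BINS`` usable bins is an
    error.
    """
    k = np.asarray(k, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if k.size != psd.size:
        raise ValueError("k and psd must have equal length")
    if np.any(np.diff(k) <= 0):
        raise ValueError("k must be strictly increasing")
    if fit_range is None:
        n = int(round(1.0 / k[0]))
        fit_range = (3.0 / n, DEFAULT_FIT_KMAX)
    lo, hi = fit_range
    sel = (k >= lo) & (k <= hi) & np.isfinite(psd) & (psd > 0)
    if sel.sum() < MIN_FIT_BINS:
        raise ValueError(
            f"only {int(sel.sum())} usable PSD bins in {fit_range}; "
            f"need >= {MIN_FIT_BINS}")
    lk = np.log10(k[sel])
    lp = np.log10(psd[sel])
    slope, intercept = np.polyfit(lk, lp, 1)
    pred = slope * lk + intercept
    ss_res = float(((lp - pred) ** 2).sum())
    ss_tot = float(((lp - lp.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PsdFit(k=k[sel], psd=psd[sel], A=float(10 ** intercept),
                  beta=float(-slope), fit_range=(float(lo), float(hi)),
                  r_squared_fit=r2)


# ---------------------------------------------------------------------------
# stack-level summaries
# ---------------------------------------------------------------------------

def _default_mask(nadph_section: np.ndarray, quantile: float) -> np.ndarray:
    return nadph_section > np.quantile(nadph_section, quantile)


def _summaries(per_depth: dict[str, np.ndarray]) -> dict[str, float]:
    def _mv(x):
        x = x[np.isfinite(x)]
        if x.size == 0:
            return float("nan"), float("nan")
        var = float(x.var(ddof=1)) if x.size > 1 else float("nan")
        return float(x.mean()), var

    m_rr, v_rr = _mv(per_depth["mean_rr"])
    m_iqr, v_iqr = _mv(per_depth["rr_iqr"])
    m_b, v_b = _mv(per_depth["beta"])
    return dict(zip(SUMMARY_NAMES, (m_rr, v_rr, m_iqr, v_iqr, m_b, v_b)))


def stack_metrics(nadph: TissueStack, fad: TissueStack,
                  masks: np.ndarray | None = None,
                  fit_range: tuple[float, float] | None = None,
                  mask_quantile: float = 0.25) -> MetricProfile:
    """Per-depth RR statistics and clustering exponents plus the six
    stack-level summaries.

    Without explicit masks, each depth's cytoplasm mask defaults to the
    pixels above the ``mask_quantile`` quantile of that NAD(P)H section.
    Depths where a metric cannot be computed are recorded as NaN and
    excluded from the summaries; the count is reported.  All summaries are
    order-free statistics, invariant to depth permutation.
    """
    if nadph.n_depths != fad.n_depths:
        raise ValueError("channel stacks must be depth-aligned")
    if nadph.section_shape != fad.section_shape:
        raise ValueError("channel stacks must share section shape")
    nd = nadph.n_depths
    mean_rr = np.full(nd, np.nan)
    rr_iqr = np.full(nd, np.nan)
    beta = np.full(nd, np.nan)
    n_failed = 0
    for d in range(nd):
        # denoised output may undershoot zero slightly; metrics are
        # defined on non-negative intensities
        sec_n = np.clip(nadph.section(d), 0.0, None)
        sec_f = np.clip(fad.section(d), 0.0, None)
        mask = (np.asarray(masks[d], dtype=bool) if masks is not None
                else _default_mask(sec_n, mask_quantile))
        try:
            rmap = redox_map(sec_n, sec_f, mask)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_rr[d], rr_iqr[d] = section_rr_stats(rmap)
            fluct = fluctuation_image(sec_n, mask)
            k, psd = radial_psd(fluct)
            beta[d] = fit_beta(k, psd, fit_range).beta
        except ValueError:
            n_failed += 1
    per_depth = {"mean_rr": mean_rr, "rr_iqr": rr_iqr, "beta": beta}
    return MetricProfile(mean_rr=mean_rr, rr_iqr=rr_iqr, beta=beta,
                         summaries=_summaries(per_depth),
                         n_failed_depths=n_failed)
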