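"""Single-level 2-D discrete wavelet analysis/synthesis.

One analysis step splits a patch into a coarse approximation (LL) and three
detail images (LH horizontal, HL vertical, HH diagonal), each at half the
resolution for the default biorthogonal 1.1 wavelet.  These four sub-bands
are the routing unit of the wavelet-domain denoiser: each one is restored by
its own network before synthesis recombines them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

DEFAULT_WAVELET = "bior1.1"
DEFAULT_MODE = "symmetric"

#: wavelet families supported for sub-band routing
SUPPORTED_FAMILIES = ("bior", "coif", "db")

BAND_ORDER = ("LL", "LH", "HL", "HH")


def _check_wavelet(name: str) -> pywt.Wavelet:
    if not any(name.startswith(fam) for fam in SUPPORTED_FAMILIES):
        raise ValueError(
            f"unsupported wavelet {name!r}; expected one of the families "
            f"{SUPPORTED_FAMILIES}")
    try:
        return pywt.Wavelet(name)
    except ValueError as exc:  # unknown name within a family
        raise ValueError(f"unknown wavelet {name!r}") from exc


@dataclass
class SubbandSet:
    """The four single-level sub-bands of one patch, in (LL, LH, HL, HH) order."""

    approx: np.ndarray
    horiz: np.ndarray
    vert: np.ndarray
    diag: np.ndarray
    wavelet_name: str = DEFAULT_WAVELET
    boundary_mode: str = DEFAULT_MODE

    def __post_init__(self):
        shapes = {b.shape for b in self.bands}
        if len(shapes) != 1:
            raise ValueError(f"sub-bands must be congruent, got shapes {shapes}")

    @property
    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.approx, self.horiz, self.vert, self.diag)

    def as_array(self) -> np.ndarray:
        """Stack the bands as a (4, h, w) array in (LL, LH, HL, HH) order."""
        return np.stack(self.bands)

    @classmethod
    def from_array(cls, arr: np.ndarray, wavelet_name: str = DEFAULT_WAVELET,
                   boundary_mode: str = DEFAULT_MODE) -> "SubbandSet":
        if arr.shape[0] != 4:
            raise ValueError("expected a (4, h, w) array")
        return cls(arr[0], arr[1], arr[2], arr[3], wavelet_name, boundary_mode)


def dwt_single(patch: np.ndarray, wavelet_name: str = DEFAULT_WAVELET,
               boundary_mode: str = DEFAULT_MODE) -> SubbandSet:
    """One analysis level of the separable 2-D discrete wavelet transform.

    For biorthogonal 1.1 (the Haar-equivalent pair) on even side lengths
    each sub-band has exactly half the side length with no boundary
    expansion.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D")
    if patch.shape[0] % 2 or patch.shape[1] % 2:
        raise ValueError(f"patch sides must be even, got {patch.shape}")
    _check_wavelet(wavelet_name)
    ca, (ch, cv, cd) = pywt.dwt2(patch, wavelet_name, mode=boundary_mode)
    return SubbandSet(ca, ch, cv, cd, wavelet_name, boundary_mode)


def idwt_single(bands: SubbandSet) -> np.ndarray:
    """Exact synthesis inverse of :func:`dwt_single`."""
    _check_wavelet(bands.wavelet_name)
    return pywt.idwt2((bands.approx, (bands.horiz, bands.vert, bands.diag)),
                      bands.wavelet_name, mode=bands.boundary_mode)


def subband_side(side: int, wavelet_name: str = DEFAULT_WAVELET,
                 boundary_mode: str = DEFAULT_MODE) -> int:
    """Side length of the sub-bands produced from a ``side``-pixel patch."""
    w = _check_wavelet(wavelet_name)
    if boundary_mode == "periodization":
        return (side + 1) // 2
    return pywt.dwt_coeff_len(side, w.dec_len, mode=boundary_mode)
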