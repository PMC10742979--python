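"""Reading, writing and reshaping of multi-frame two-photon image stacks.

A tissue stack is one imaged field (ROI): a z-series of optical sections,
each acquired as one or more repeated frames.  On disk a stack is a
multi-page grayscale TIFF ordered depth-major then frame, accompanied by a
YAML sidecar header (``<file>.yaml``) declaring depth count, frames per
depth, depth spacing, channel and provenance.

This module also houses the deterministic plumbing around training data:
frame averaging into ground truth, seeded single-frame selection, 2x2
patching/stitching, percentile intensity normalisation, and ROI-level
dataset splitting (the data-leakage guard: sections of one ROI never land
in two split groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
import yaml

CHANNELS = ("NADPH", "FAD")
PROVENANCES = ("raw_frames", "raw_single", "gt_average", "denoised", "clean")

#: provenances whose intensities must be non-negative
_NONNEGATIVE = {"raw_frames", "raw_single", "gt_average", "clean"}


class StackStructureError(ValueError):
    """Page count inconsistent with the declared depth/frame layout."""


class StackFormatError(ValueError):
    """File is not a multi-page grayscale TIFF."""


class DataError(ValueError):
    """Input data violates a numeric precondition (non-finite, negative)."""


@dataclass
class TissueStack:
    """Per-channel z-stack of optical sections with per-depth frame repeats.

    ``voxels`` is indexed (depth, frame, row, col).
    """

    channel: str
    voxels: np.ndarray
    depth_spacing_um: float = 4.0
    provenance: str = "raw_single"
    roi_id: str = ""
    patient_id: str = ""

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 4:
            raise ValueError("voxels must be indexed (depth, frame, row, col)")
        if not np.isfinite(v).all():
            raise DataError("stack intensities must be finite")
        if self.provenance in _NONNEGATIVE and (v < 0).any():
            raise DataError(
                f"{self.provenance} stacks must have non-negative intensities")
        if self.depth_spacing_um <= 0:
            raise ValueError("depth_spacing_um must be positive")
        if self.provenance == "raw_single" and v.shape[1] != 1:
            raise ValueError("raw_single stacks carry one frame per depth")
        self.voxels = v

    @property
    def n_depths(self) -> int:
        return self.voxels.shape[0]

    @property
    def frames_per_depth(self) -> int:
        return self.voxels.shape[1]

    @property
    def section_shape(self) -> tuple[int, int]:
        return self.voxels.shape[2:]

    def section(self, depth: int, frame: int = 0) -> np.ndarray:
        return self.voxels[depth, frame]

    def sections(self) -> np.ndarray:
        """(depth, row, col) view for single-frame stacks."""
        if self.frames_per_depth != 1:
            raise ValueError("stack has multiple frames per depth; average "
                             "or select a frame first")
        return self.voxels[:, 0]


@dataclass(frozen=True)
class DatasetSplit:
    """ROI-granular train/validation/test partition."""

    train_rois: frozenset
    val_rois: frozenset
    test_rois: frozenset
    seed: int

    def __post_init__(self):
        groups = (self.train_rois, self.val_rois, self.test_rois)
        total = sum(len(g) for g in groups)
        union = frozenset().union(*groups)
        if total != len(union):
            raise ValueError("split groups must be pairwise disjoint")


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: TissueStack, path) -> Path:
    """Write a stack as multi-page grayscale TIFF + YAML sidecar header."""
    path = Path(path)
    d, f, h, w = stack.voxels.shape
    # float64 pages keep the read/write pair an exact inverse
    pages = stack.voxels.reshape(d * f, h, w)
    tifffile.imwrite(path, pages)
    header = {
        "depths": int(d),
        "frames_per_depth": int(f),
        "depth_spacing_um": float(stack.depth_spacing_um),
        "channel": stack.channel,
        "provenance": stack.provenance,
        "roi_id": stack.roi_id,
        "patient_id": stack.patient_id,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(header))
    return path


def read_stack(path, channel: str | None = None) -> TissueStack:
    """Read a multi-page grayscale TIFF stack with its sidecar header.

    Pages are ordered depth-major then frame.  ``channel`` overrides the
    sidecar channel if given.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise StackFormatError(
            f"expected grayscale pages, got page shape {pages.shape[1:]}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise StackFormatError(f"missing sidecar header {sidecar}")
    header = yaml.safe_load(sidecar.read_text())
    f = int(header["frames_per_depth"])
    if pages.shape[0] % f:
        raise StackStructureError(
            f"{pages.shape[0]} pages not divisible by {f} frames per depth")
    d = pages.shape[0] // f
    if "depths" in header and int(header["depths"]) != d:
        raise StackStructureError(
            f"sidecar declares {header['depths']} depths but file holds {d}")
    voxels = np.asarray(pages, dtype=float).reshape(d, f, *pages.shape[1:])
    return TissueStack(
        channel=channel or header["channel"],
        voxels=voxels,
        depth_spacing_um=float(header.get("depth_spacing_um", 4.0)),
        provenance=header.get("provenance", "raw_single"),
        roi_id=str(header.get("roi_id", "")),
        patient_id=str(header.get("patient_id", "")),
    )


# ---------------------------------------------------------------------------
# frame handling
# ---------------------------------------------------------------------------

def frame_average(stack: TissueStack, n_frames: int = 6) -> TissueStack:
    """Arithmetic mean of the first ``n_frames`` frames at each depth.

    Averaging n i.i.d. noisy frames reduces additive-noise variance by n,
    i.e. a PSNR gain of 10*log10(n) dB under purely additive corruption.
    """
    if n_frames < 1 or n_frames > stack.frames_per_depth:
        raise ValueError(
            f"n_frames={n_frames} not available (stack has "
            f"{stack.frames_per_depth} frames per depth)")
    mean = stack.voxels[:, :n_frames].mean(axis=1, keepdims=True)
    return replace(stack, voxels=mean, provenance="gt_average")


def select_input_frame(stack: TissueStack, seed: int,
                       per_depth: bool = True) -> TissueStack:
    """Seeded random choice of a single acquisition frame.

    With ``per_depth`` (default) an independent frame index is drawn at
    every depth; otherwise one index is drawn for the whole stack.
    """
    f = stack.frames_per_depth
    if f == 1:
        return replace(stack, provenance="raw_single")
    rng = np.random.default_rng(seed)
    if per_depth:
        idx = rng.integers(0, f, size=stack.n_depths)
    else:
        idx = np.full(stack.n_depths, rng.integers(0, f))
    chosen = stack.voxels[np.arange(stack.n_depths), idx][:, None]
    return replace(stack, voxels=chosen, provenance="raw_single")


# ---------------------------------------------------------------------------
# patching
# ---------------------------------------------------------------------------

def patch_2x2(section: np.ndarray) -> np.ndarray:
    """Quadrant decomposition of an even-sided section.

    Returns a (4, R, C) array in placement order
    (top-left, top-right, bottom-left, bottom-right); lossless.
    """
    section = np.asarray(section)
    if section.ndim != 2:
        raise ValueError("section must be 2-D")
    h, w = section.shape
    if h % 2 or w % 2:
        raise ValueError(f"section sides must be even, got {section.shape}")
    r, c = h // 2, w // 2
    return np.stack([section[:r, :c], section[:r, c:],
                     section[r:, :c], section[r:, c:]])


def stitch_2x2(patches: np.ndarray,
               indices: Sequence[int] = (0, 1, 2, 3)) -> np.ndarray:
    """Exact quadrant reassembly; inverse of :func:`patch_2x2`."""
    patches = np.asarray(patches)
    if patches.shape[0] != 4:
        raise ValueError("expected exactly four patches")
    if len(set(indices)) != 4 or set(indices) != {0, 1, 2, 3}:
        raise ValueError("indices must be a permutation of 0..3")
    shapes = {p.shape for p in patches}
    if len(shapes) != 1:
        raise ValueError("patches must be congruent")
    quad = [None] * 4
    for p, i in zip(patches, indices):
        quad[i] = p
    return np.block([[quad[0], quad[1]], [quad[2], quad[3]]])


# ---------------------------------------------------------------------------
# intensity normalisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationParams:
    """Affine map recorded so denoised output can be returned to the
    input intensity scale."""

    offset: float
    scale: float
    degenerate: bool = False
    p_low: float = 0.1
    p_high: float = 99.9


def percentile_normalize(section: np.ndarray, p_low: float = 0.1,
                         p_high: float = 99.9
                         ) -> tuple[np.ndarray, NormalizationParams]:
    """Map the ``p_low`` percentile to 0 and ``p_high`` to 1.

    Degenerate (zero-spread) inputs map to all-zeros with the scale
    flagged so inversion reproduces the constant.
    """
    if not p_low < p_high:
        raise ValueError("p_low must be below p_high")
    x = np.asarray(section, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("cannot normalize non-finite intensities")
    lo, hi = np.percentile(x, [p_low, p_high])
    scale = hi - lo
    if scale <= 0:
        params = NormalizationParams(float(lo), 0.0, True, p_low, p_high)
        return np.zeros_like(x), params
    params = NormalizationParams(float(lo), float(scale), False, p_low, p_high)
    return (x - lo) / scale, params


def denormalize(section: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Invert :func:`percentile_normalize`."""
    if params.degenerate:
        return np.full_like(np.asarray(section, dtype=float), params.offset)
    return np.asarray(section, dtype=float) * params.scale + params.offset


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_by_roi(rois: Iterable, fractions: tuple[float, float] = (0.75, 0.25),
                 seed: int = 0) -> DatasetSplit:
    """Seeded shuffle then proportional cut at ROI granularity.

    ``fractions`` are the (train, validation) shares; any remainder forms
    the test group.  Splitting at ROI level prevents sections of one field
    from leaking across groups.
    """
    rois = list(rois)
    f_train, f_val = fractions
    if f_train <= 0 or f_val <= 0 or f_train + f_val > 1 + 1e-12:
        raise ValueError("fractions must be positive with sum <= 1")
    n = len(rois)
    n_train = int(round(f_train * n))
    n_val = int(round(f_val * n))
    if n_train + n_val > n:
        n_val = n - n_train
    if n_train < 1 or n_val < 1:
        raise ValueError(f"{n} ROIs are too few for the requested split")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [rois[i] for i in order]
    return DatasetSplit(
        train_rois=frozenset(shuffled[:n_train]),
        val_rois=frozenset(shuffled[n_train:n_train + n_val]),
        test_rois=frozenset(shuffled[n_train + n_val:]),
        seed=seed,
    )
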