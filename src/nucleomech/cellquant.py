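"""Scalar per-cell quantifications.

Nuclear/cytoplasmic signal ratio, fluorescent-dot density per nuclear area,
focal-adhesion count, actin structure-tensor coherency, and the spreading
ratio between two time points.  Masks are inputs throughout; 8-connectivity
is the repo-wide component convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .errors import DegenerateFitError, UndefinedRatioError, ValidationError

EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class CellRecord:
    cell_id: int
    nc_ratio: float = np.nan
    dot_density: float = np.nan
    fa_count: int = -1
    coherency: float = np.nan
    spreading_ratio: float = np.nan
    qc: dict | None = None


def _as_bool(mask) -> np.ndarray:
    from .stacks import LabelMask

    if isinstance(mask, LabelMask):
        return mask.labels > 0
    return np.asarray(mask) > 0


def estimate_background(image: np.ndarray, cell_mask) -> float:
    """Median intensity outside the cell mask (0 if the mask fills the frame)."""
    outside = ~_as_bool(cell_mask)
    if not outside.any():
        return 0.0
    return float(np.median(np.asarray(image, dtype=float)[outside]))


def nc_ratio(
    signal: np.ndarray,
    nucleus_mask,
    cell_mask,
    background: float | None = None,
) -> float:
    """Mean background-subtracted intensity in nucleus over cytoplasm.

    Cytoplasm = cell minus nucleus.  Background defaults to the median
    intensity outside the cell mask.
    """
    signal = np.asarray(signal, dtype=float)
    nuc = _as_bool(nucleus_mask)
    cell = _as_bool(cell_mask)
    cyto = cell & ~nuc
    if not nuc.any():
        raise ValidationError("empty nucleus mask")
    if not cyto.any():
        raise ValidationError("cytoplasm region (cell minus nucleus) is empty")
    bg = estimate_background(signal, cell) if background is None else float(background)
    nuc_mean = float(signal[nuc].mean()) - bg
    cyto_mean = float(signal[cyto].mean()) - bg
    if cyto_mean <= 0:
        raise UndefinedRatioError("cytoplasm mean <= 0 after background subtraction")
    return nuc_mean / cyto_mean


def dot_density(
    signal: np.ndarray,
    nucleus_mask,
    pixel_size_um: float = 1.0,
    min_distance_px: int = 3,
    threshold: float | str = "otsu",
) -> tuple[int, float, float]:
    """Count bright nuclear dots and the summed dot intensity per nuclear area.

    Dots are local maxima above threshold separated by watershed; density is
    the total integrated dot intensity divided by the nuclear area in um^2.
    Returns ``(n_dots, total_dot_intensity, density)``.
    """
    signal = np.asarray(signal, dtype=float)
    nuc = _as_bool(nucleus_mask)
    area_um2 = float(np.count_nonzero(nuc)) * pixel_size_um**2
    if area_um2 <= 0:
        raise ValidationError("zero-area nucleus")
    inside = signal[nuc]
    if threshold == "otsu":
        thr = float(threshold_otsu(inside)) if np.ptp(inside) > 0 else np.inf
    else:
        thr = float(threshold)
    above = (signal > thr) & nuc
    if not above.any():
        return 0, 0.0, 0.0
    peaks = peak_local_max(
        signal, min_distance=min_distance_px, labels=above.astype(int), exclude_border=False
    )
    if len(peaks) == 0:
        return 0, 0.0, 0.0
    markers = np.zeros_like(signal, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    dots = watershed(-signal, markers=markers, mask=above)
    n_dots = int(dots.max())
    total = float(signal[dots > 0].sum())
    return n_dots, total, total / area_um2


def count_focal_adhesions(
    vinculin: np.ndarray,
    cell_mask,
    min_area_um2: float = 0.25,
    pixel_size_um: float = 1.0,
    threshold: float | str = "otsu",
) -> int:
    """Count above-threshold connected components of area >= min_area_um2.

    The area rule is inclusive; threshold defaults to Otsu computed within
    the cell mask.
    """
    vinculin = np.asarray(vinculin, dtype=float)
    cell = _as_bool(cell_mask)
    if not cell.any():
        raise ValidationError("empty cell mask")
    inside = vinculin[cell]
    if threshold == "otsu":
        if np.ptp(inside) == 0:
            return 0
        thr = float(threshold_otsu(inside))
    else:
        thr = float(threshold)
    bw = (vinculin > thr) & cell
    labels, n = ndimage.label(bw, structure=EIGHT)
    if n == 0:
        return 0
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    min_area_px = min_area_um2 / pixel_size_um**2
    return int(np.count_nonzero(areas >= min_area_px))


def actin_coherency(
    actin: np.ndarray,
    cell_mask,
    tensor_sigma_px: float = 2.0,
) -> float:
    """Mean structure-tensor coherency (l1-l2)/(l1+l2) over the cell mask.

    The structure tensor is the Gaussian-smoothed (scale ``tensor_sigma_px``,
    reflective boundaries) outer product of central-difference image
    gradients; Sobel-style derivative kernels are avoided because their
    cross-smoothing correlates noise gradients and inflates the isotropic
    coherency floor.  Pixels with zero tensor trace are excluded, and a flat
    image (all gradients zero) is an error.
    """
    actin = np.asarray(actin, dtype=float)
    cell = _as_bool(cell_mask)
    if np.count_nonzero(cell) < (2 * int(np.ceil(3 * tensor_sigma_px)) + 1) ** 2:
        raise ValidationError("mask smaller than the tensor support")
    gr, gc = np.gradient(actin)
    Arr = ndimage.gaussian_filter(gr * gr, tensor_sigma_px, mode="reflect")
    Arc = ndimage.gaussian_filter(gr * gc, tensor_sigma_px, mode="reflect")
    Acc = ndimage.gaussian_filter(gc * gc, tensor_sigma_px, mode="reflect")
    trace = Arr + Acc
    # (l1 - l2) for a symmetric 2x2 matrix is the discriminant root
    spread = np.sqrt((Arr - Acc) ** 2 + 4.0 * Arc**2)
    valid = cell & (trace > 0)
    if not valid.any():
        raise DegenerateFitError("flat image: coherency undefined")
    return float(np.mean(spread[valid] / trace[valid]))


def spreading_ratio(mask_t0, mask_t1) -> float:
    """Area at the later time point over area at time zero."""
    a0 = int(np.count_nonzero(_as_bool(mask_t0)))
    a1 = int(np.count_nonzero(_as_bool(mask_t1)))
    if a0 == 0:
        raise ValidationError("empty mask at time 0")
    return a1 / a0
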