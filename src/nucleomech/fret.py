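"""Spectral FRET tension index (donor/acceptor emission-peak ratio).

The sensor readout is the inverted FRET index: the ratio between the donor
(~480 nm) and acceptor (~530 nm) emission peaks of a 460-600 nm, 10 nm-step
spectral series — the higher the value, the higher the envelope tension.
"Peak" means the maximum sampled channel within a +-10 nm window around the
nominal centre; no curve fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError, ValidationError
from .stacks import ImageStack, LabelMask

logger = logging.getLogger(__name__)

DONOR_WINDOW_NM = (470.0, 490.0)
ACCEPTOR_WINDOW_NM = (520.0, 540.0)


@dataclass
class EmissionSpectrum:
    """Background-subtracted mean emission spectrum of one region."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    region_id: int = 0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ValidationError("wavelengths and intensities must align")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be >= 0 after clamping")


@dataclass
class FretIndex:
    value: float
    donor_peak_nm: float
    acceptor_peak_nm: float
    region_id: int = 0


def extract_spectrum(
    stack: ImageStack,
    mask: LabelMask,
    label: int,
    background_label: int | None = None,
) -> EmissionSpectrum:
    """Per-channel mean over a region, minus the background-region mean, clamped at 0."""
    if stack.channel_wavelengths_nm is None:
        raise ValidationError("stack has no wavelength metadata")
    region = mask.region(label)
    if not region.any():
        raise ValidationError(f"empty region for label {label}")
    spec = stack.pixels[:, region].mean(axis=1)
    if background_label is not None:
        bg_region = mask.region(background_label)
        if bg_region.any():
            spec = spec - stack.pixels[:, bg_region].mean(axis=1)
        else:
            logger.warning("background label %d empty: no subtraction", background_label)
    return EmissionSpectrum(
        wavelengths_nm=np.asarray(stack.channel_wavelengths_nm),
        intensities=np.clip(spec, 0.0, None),
        region_id=label,
    )


def _window_peak(spectrum: EmissionSpectrum, window: tuple[float, float]) -> tuple[float, float]:
    sel = (spectrum.wavelengths_nm >= window[0]) & (spectrum.wavelengths_nm <= window[1])
    if not sel.any():
        raise ValidationError(f"no sampled wavelength inside window {window}")
    i = np.argmax(np.where(sel, spectrum.intensities, -np.inf))
    return float(spectrum.intensities[i]), float(spectrum.wavelengths_nm[i])


def inverted_fret_index(
    spectrum: EmissionSpectrum,
    donor_window: tuple[float, float] = DONOR_WINDOW_NM,
    acceptor_window: tuple[float, float] = ACCEPTOR_WINDOW_NM,
) -> FretIndex:
    """Donor peak over acceptor peak; higher value reads as higher tension."""
    donor, donor_nm = _window_peak(spectrum, donor_window)
    acceptor, acceptor_nm = _window_peak(spectrum, acceptor_window)
    if acceptor == 0:
        raise UndefinedRatioError(
            f"region {spectrum.region_id}: acceptor peak is zero, index undefined"
        )
    return FretIndex(
        value=donor / acceptor,
        donor_peak_nm=donor_nm,
        acceptor_peak_nm=acceptor_nm,
        region_id=spectrum.region_id,
    )


def per_pixel_index(
    stack: ImageStack,
    mask: LabelMask,
    label: int,
    background_label: int | None = None,
    donor_window: tuple[float, float] = DONOR_WINDOW_NM,
    acceptor_window: tuple[float, float] = ACCEPTOR_WINDOW_NM,
) -> float:
    """Alternative reduction: ratio per pixel, then mean over the region."""
    if stack.channel_wavelengths_nm is None:
        raise ValidationError("stack has no wavelength metadata")
    wl = np.asarray(stack.channel_wavelengths_nm)
    region = mask.region(label)
    if not region.any():
        raise ValidationError(f"empty region for label {label}")
    spectra = stack.pixels[:, region].astype(float)  # (channels, n_px)
    if background_label is not None and mask.region(background_label).any():
        spectra = spectra - stack.pixels[:, mask.region(background_label)].mean(
            axis=1, keepdims=True
        )
    spectra = np.clip(spectra, 0.0, None)
    dsel = (wl >= donor_window[0]) & (wl <= donor_window[1])
    asel = (wl >= acceptor_window[0]) & (wl <= acceptor_window[1])
    donor = spectra[dsel].max(axis=0)
    acceptor = spectra[asel].max(axis=0)
    valid = acceptor > 0
    if not valid.any():
        raise UndefinedRatioError("acceptor peak zero at every pixel")
    return float(np.mean(donor[valid] / acceptor[valid]))


def fret_per_cell(
    stack: ImageStack,
    ne_mask: LabelMask,
    background_label: int | None = None,
    donor_window: tuple[float, float] = DONOR_WINDOW_NM,
    acceptor_window: tuple[float, float] = ACCEPTOR_WINDOW_NM,
    per_pixel: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """One inverted FRET index per labeled NE region, plus box-plot summaries.

    Per-region failures are logged and reported as missing entries; the batch
    never aborts.
    """
    labels = [
        int(l) for l in ne_mask.label_ids if background_label is None or l != background_label
    ]
    if not labels:
        raise ValidationError("no labeled NE region in mask")
    rows = []
    for label in labels:
        try:
            if per_pixel:
                value = per_pixel_index(
                    stack, ne_mask, label, background_label, donor_window, acceptor_window
                )
                rows.append(
                    {"cell_id": label, "fret_index": value,
                     "donor_peak_nm": np.nan, "acceptor_peak_nm": np.nan}
                )
            else:
                spec = extract_spectrum(stack, ne_mask, label, background_label)
                idx = inverted_fret_index(spec, donor_window, acceptor_window)
                rows.append(
                    {
                        "cell_id": label,
                        "fret_index": idx.value,
                        "donor_peak_nm": idx.donor_peak_nm,
                        "acceptor_peak_nm": idx.acceptor_peak_nm,
                    }
                )
        except (UndefinedRatioError, ValidationError) as exc:
            logger.warning("region %d skipped: %s", label, exc)
    df = pd.DataFrame(rows, columns=["cell_id", "fret_index", "donor_peak_nm", "acceptor_peak_nm"])
    values = df["fret_index"].to_numpy()
    summary = {
        "n_cells": int(len(df)),
        "n_failed": int(len(labels) - len(df)),
        "median": float(np.median(values)) if len(df) else None,
        "q1": float(np.percentile(values, 25)) if len(df) else None,
        "q3": float(np.percentile(values, 75)) if len(df) else None,
    }
    return df, summary
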