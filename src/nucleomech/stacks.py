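"""Image containers and TIFF I/O.

An :class:`ImageStack` is a validated greyscale pixel array with the physical
metadata each assay needs: pixel size, frame interval (time series) or the
emission wavelength per channel (spectral series).  A :class:`LabelMask`
carries precomputed segmentations (0 = background, k > 0 = object k).

Coordinates follow the repo-wide convention: 0-based pixel indices, arrays are
indexed ``[row (y), col (x)]``, subpixel positions are continuous in the same
frame, and physical quantities are obtained through ``pixel_size_um``.

Metadata resolution order on read: explicit keyword arguments (typically from
a config file) win over a ``<file>.meta`` sidecar, which wins over JSON stored
in the TIFF ImageDescription tag.  Missing pixel size falls back to 1.0 with a
logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

from .errors import MetadataError, ValidationError

logger = logging.getLogger(__name__)

StackRole = Literal["time", "spectral", "multichannel"]


@dataclass
class ImageStack:
    """Greyscale image stack with physical metadata.

    Parameters
    ----------
    pixels
        2D ``(y, x)`` or 3D ``(t|c, y, x)`` intensity array, finite and >= 0.
    axis_order
        ``"yx"``, ``"tyx"`` or ``"cyx"``; declares the leading axis meaning.
    pixel_size_um
        Micrometres per pixel (isotropic).
    frame_interval_s
        Seconds between frames; required semantics for time series.
    channel_wavelengths_nm
        Strictly increasing emission centres, one per channel; required
        semantics for spectral series.  Mutually exclusive with
        ``frame_interval_s``.
    """

    pixels: np.ndarray
    axis_order: str = "tyx"
    pixel_size_um: float = 1.0
    frame_interval_s: float | None = None
    channel_wavelengths_nm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValidationError(
                f"expected 2D or 3D pixel array, got ndim={self.pixels.ndim}"
            )
        if self.axis_order not in ("yx", "tyx", "cyx"):
            raise ValidationError(f"unknown axis_order {self.axis_order!r}")
        if self.axis_order == "yx":
            self.axis_order = "tyx"
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("pixel intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.frame_interval_s is not None and self.channel_wavelengths_nm is not None:
            raise ValidationError(
                "frame_interval_s and channel_wavelengths_nm are mutually exclusive"
            )
        if self.channel_wavelengths_nm is not None:
            wl = tuple(float(w) for w in self.channel_wavelengths_nm)
            if len(wl) != self.pixels.shape[0]:
                raise MetadataError(
                    f"{len(wl)} wavelengths for {self.pixels.shape[0]} planes"
                )
            if np.any(np.diff(wl) <= 0):
                raise ValidationError("wavelengths must be strictly increasing")
            self.channel_wavelengths_nm = wl

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def frame(self, i: int) -> np.ndarray:
        return self.pixels[i]


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k > 0 = object k."""

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValidationError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def region(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# TIFF I/O


def _read_sidecar(path: Path) -> dict:
    sidecar = Path(str(path) + ".meta")
    if not sidecar.exists():
        return {}
    meta: dict = {}
    for line in sidecar.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise MetadataError(f"malformed sidecar line: {line!r}")
        key, _, value = line.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def _read_tag_meta(tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description
    if not desc:
        return {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return {}
    return meta if isinstance(meta, dict) else {}


def _parse_wavelengths(value) -> tuple[float, ...]:
    if isinstance(value, str):
        value = [v for v in value.replace(",", " ").split() if v]
    return tuple(float(v) for v in value)


def read_stack(
    path: str | Path,
    role: StackRole = "time",
    *,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_wavelengths_nm: Sequence[float] | None = None,
) -> ImageStack:
    """Read a multi-page greyscale TIFF into a validated :class:`ImageStack`.

    ``role`` selects which temporal/spectral metadata is required.  Explicit
    keyword arguments override sidecar metadata, which overrides TIFF tags.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            pixels = tif.asarray()
            tag_meta = _read_tag_meta(tif)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"unreadable TIFF {path}: {exc}") from exc

    meta = dict(tag_meta)
    meta.update(_read_sidecar(path))
    if pixel_size_um is not None:
        meta["pixel_size_um"] = pixel_size_um
    if frame_interval_s is not None:
        meta["frame_interval_s"] = frame_interval_s
    if channel_wavelengths_nm is not None:
        meta["channel_wavelengths_nm"] = list(channel_wavelengths_nm)

    if "pixel_size_um" not in meta:
        logger.warning("%s: no pixel size metadata, falling back to 1.0 um/px", path)
        meta["pixel_size_um"] = 1.0

    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise MetadataError(f"{path}: expected 2D or 3D TIFF, got ndim={pixels.ndim}")

    kwargs: dict = {"pixel_size_um": float(meta["pixel_size_um"])}
    if role == "spectral":
        if "channel_wavelengths_nm" not in meta:
            raise MetadataError(f"{path}: spectral stack requires channel wavelengths")
        wl = _parse_wavelengths(meta["channel_wavelengths_nm"])
        if len(wl) != pixels.shape[0]:
            raise MetadataError(
                f"{path}: {len(wl)} wavelengths for {pixels.shape[0]} planes"
            )
        kwargs["channel_wavelengths_nm"] = wl
        axis_order = "cyx"
    elif role == "time":
        if "frame_interval_s" in meta:
            kwargs["frame_interval_s"] = float(meta["frame_interval_s"])
        axis_order = "tyx"
    else:  # multichannel: no temporal/spectral semantics
        axis_order = "cyx"
    return ImageStack(pixels=pixels, axis_order=axis_order, **kwargs)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF with JSON metadata in ImageDescription."""
    meta = {"axis_order": stack.axis_order, "pixel_size_um": stack.pixel_size_um}
    if stack.frame_interval_s is not None:
        meta["frame_interval_s"] = stack.frame_interval_s
    if stack.channel_wavelengths_nm is not None:
        meta["channel_wavelengths_nm"] = list(stack.channel_wavelengths_nm)
    tifffile.imwrite(
        Path(path), stack.pixels, description=json.dumps(meta), photometric="minisblack"
    )


def read_mask(path: str | Path, pixel_size_um: float | None = None) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray()
        meta = _read_tag_meta(tif)
    meta.update(_read_sidecar(path))
    if pixel_size_um is None:
        pixel_size_um = float(meta.get("pixel_size_um", 1.0))
    return LabelMask(labels=np.asarray(labels), pixel_size_um=pixel_size_um)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    meta = {"pixel_size_um": mask.pixel_size_um}
    tifffile.imwrite(
        Path(path),
        mask.labels.astype(np.int32),
        description=json.dumps(meta),
        photometric="minisblack",
    )
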