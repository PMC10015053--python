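"""Particle-tracking microrheology: detection, proximity linking, MSD.

Beads are detected per frame as intensity-weighted centroids of above-
threshold connected regions, linked across consecutive frames by a greedy
mutual-nearest-neighbour rule (the proximity principle: the closest positions
in successive frames belong to the same particle), and summarized as the
time-averaged mean squared displacement

    msd(tau) = < [x(t) - x(t - tau)]^2 + [y(t) - y(t - tau)]^2 >_t

with an optional pair-count-weighted ensemble average across tracks.  A
least-squares line ``msd = 4 D tau + b`` turns the curve into a diffusivity;
the intercept absorbs static localization noise (b = 4 sigma_loc^2).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ParticleTrack:
    """One tracked object: ordered samples (frame, t, x, y) in um."""

    particle_id: int
    frames: np.ndarray
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    complete: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError("frame indices must be strictly increasing")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ValidationError("positions must be finite")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MSDCurve:
    """MSD on a strictly increasing lag grid with per-lag pair counts."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    mode: str = "time"  # "time" | "time+ensemble"

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValidationError("lags must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValidationError("msd must be >= 0")
        if np.any(self.n_pairs < 1):
            raise ValidationError("every reported lag needs n_pairs >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags_s, "msd_um2": self.msd_um2, "n_pairs": self.n_pairs}
        )


# ---------------------------------------------------------------------------
# Detection


def _refine_centroid(
    frame: np.ndarray, x0: float, y0: float, radius: int, n_iter: int = 3
) -> tuple[float, float]:
    """Iterated windowed centroid with local median background subtraction.

    The window is re-centred on the running estimate each iteration so its
    truncation stays symmetric around the spot; weights are the window
    intensities minus the window median, clipped at zero.
    """
    ny, nx = frame.shape
    for _ in range(n_iter):
        xi, yi = int(round(x0)), int(round(y0))
        xs0, xs1 = max(0, xi - radius), min(nx, xi + radius + 1)
        ys0, ys1 = max(0, yi - radius), min(ny, yi + radius + 1)
        win = frame[ys0:ys1, xs0:xs1]
        w = np.clip(win - np.median(win), 0.0, None)
        total = w.sum()
        if total <= 0:
            break
        ys, xs = np.mgrid[ys0:ys1, xs0:xs1]
        x0 = float((xs * w).sum() / total)
        y0 = float((ys * w).sum() / total)
    return x0, y0


def detect_particles(
    frame: np.ndarray,
    threshold: float | str = "otsu",
    min_mass: float = 0.0,
    refine_radius: int = 8,
) -> list[tuple[float, float, float]]:
    """Detect bright spots as subpixel intensity-weighted centroids.

    Each above-threshold 8-connected region yields one detection ``(x, y,
    mass)`` where mass is the integrated intensity of the region.  The
    centroid is refined by an iterated windowed centroid of half-width
    ``refine_radius`` px with local median background subtraction, which
    removes the asymmetric cut-boundary bias of a plain region centroid.

    A flat (or saturated-flat) frame produces an empty result with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValidationError("frame must be finite")
    if frame.max() == frame.min():
        warnings.warn("flat frame: no particles detected")
        return []
    thr = float(threshold_otsu(frame)) if threshold == "otsu" else float(threshold)
    bw = frame > thr
    if not bw.any():
        warnings.warn("no pixels above threshold")
        return []
    labels, n = ndimage.label(bw, structure=np.ones((3, 3), dtype=bool))
    detections = []
    for k in range(1, n + 1):
        region = labels == k
        mass = float(frame[region].sum())
        if mass < min_mass:
            continue
        yy, xx = np.nonzero(region)
        w = np.clip(frame[yy, xx] - thr, 0.0, None)
        if w.sum() <= 0:
            continue
        cx0 = float((xx * w).sum() / w.sum())
        cy0 = float((yy * w).sum() / w.sum())
        cx, cy = _refine_centroid(frame, cx0, cy0, refine_radius)
        detections.append((cx, cy, mass))
    return detections


def detect_movie(
    movie: np.ndarray,
    threshold: float | str = "otsu",
    min_mass: float = 0.0,
) -> list[np.ndarray]:
    """Per-frame detection; returns a list of (n_i, 2) position arrays in px."""
    out = []
    for frame in movie:
        det = detect_particles(frame, threshold=threshold, min_mass=min_mass)
        out.append(np.array([(x, y) for x, y, _ in det]).reshape(-1, 2))
    return out


# ---------------------------------------------------------------------------
# Linking


def _mutual_nearest_pairs(
    prev: np.ndarray, curr: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-neighbour pairs within max_disp.

    Ties are resolved deterministically: ``argmin`` returns the lowest index,
    so equal-distance candidates fall to the lower id.
    """
    if len(prev) == 0 or len(curr) == 0:
        return []
    d = np.hypot(
        prev[:, None, 0] - curr[None, :, 0], prev[:, None, 1] - curr[None, :, 1]
    )
    nn_of_prev = np.argmin(d, axis=1)
    nn_of_curr = np.argmin(d, axis=0)
    pairs = []
    for i, j in enumerate(nn_of_prev):
        if nn_of_curr[j] == i and d[i, j] <= max_disp:
            pairs.append((i, int(j)))
    return pairs


def link_tracks(
    detections_per_frame: list[np.ndarray],
    max_disp_um: float,
    dt_s: float = 1.0,
    position_scale: float = 1.0,
) -> list[ParticleTrack]:
    """Link per-frame detections into tracks by the proximity principle.

    ``detections_per_frame`` holds (n_i, 2) arrays of positions; they are
    multiplied by ``position_scale`` (e.g. the pixel size) before linking so
    ``max_disp_um`` is physical.  No gap closing: an unmatched detection
    starts a new track, and a vanished particle's track simply ends.
    """
    if len(detections_per_frame) < 2:
        raise ValidationError("need detections for at least 2 frames")
    frames = [
        np.asarray(d, dtype=float).reshape(-1, 2) * position_scale
        for d in detections_per_frame
    ]
    n_frames = len(frames)

    next_id = 0
    # active[j] = (track_id, detection position) for detections in the latest frame
    tracks: dict[int, list[tuple[int, float, float]]] = {}
    active: dict[int, int] = {}
    for j, (x, y) in enumerate(frames[0]):
        tracks[next_id] = [(0, x, y)]
        active[j] = next_id
        next_id += 1
    for f in range(1, n_frames):
        pairs = _mutual_nearest_pairs(frames[f - 1], frames[f], max_disp_um)
        matched_prev = {i: j for i, j in pairs}
        new_active: dict[int, int] = {}
        for i, j in pairs:
            if i in active:
                tid = active[i]
                x, y = frames[f][j]
                tracks[tid].append((f, float(x), float(y)))
                new_active[j] = tid
        for j, (x, y) in enumerate(frames[f]):
            if j not in new_active:
                tracks[next_id] = [(f, float(x), float(y))]
                new_active[j] = next_id
                next_id += 1
        active = new_active
    out = []
    for tid in sorted(tracks):
        samples = tracks[tid]
        fr = np.array([s[0] for s in samples])
        out.append(
            ParticleTrack(
                particle_id=tid,
                frames=fr,
                t_s=fr * dt_s,
                x_um=np.array([s[1] for s in samples]),
                y_um=np.array([s[2] for s in samples]),
                complete=len(samples) == n_frames,
            )
        )
    return out


def tracks_from_table(df: pd.DataFrame, dt_s: float | None = None) -> list[ParticleTrack]:
    """Build tracks from a CSV-style table (particle_id, frame, x_um, y_um)."""
    required = {"particle_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"track table missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("particle_id"):
        grp = grp.sort_values("frame")
        if "t_s" in grp.columns:
            t = grp["t_s"].to_numpy(dtype=float)
        else:
            t = grp["frame"].to_numpy(dtype=float) * (dt_s or 1.0)
        out.append(
            ParticleTrack(
                particle_id=int(pid),
                frames=grp["frame"].to_numpy(),
                t_s=t,
                x_um=grp["x_um"].to_numpy(dtype=float),
                y_um=grp["y_um"].to_numpy(dtype=float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# MSD


def compute_msd(
    track: ParticleTrack,
    dt_s: float,
    max_lag_fraction: float = 0.25,
    max_lag: int | None = None,
) -> MSDCurve:
    """Time-averaged MSD of one track on the lag grid ``tau = k * dt``.

    The track must be uniformly sampled at ``dt_s``; lags run up to
    ``max_lag_fraction`` of the track length unless ``max_lag`` overrides.
    """
    if len(track) < 2:
        raise ValidationError("track needs >= 2 samples")
    if np.any(np.diff(track.frames) != 1):
        raise ValidationError(
            "non-uniform sampling: resample the track to a constant frame interval"
        )
    n = len(track)
    k_max = max_lag if max_lag is not None else max(1, int(np.floor(max_lag_fraction * n)))
    k_max = min(k_max, n - 1)
    lags = np.arange(1, k_max + 1) * dt_s
    msd = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=int)
    x, y = track.x_um, track.y_um
    for k in range(1, k_max + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        # fsum: exact accumulation, so the value matches an explicit
        # all-pairs double loop bit for bit
        msd[k - 1] = math.fsum(dx * dx + dy * dy) / (n - k)
        n_pairs[k - 1] = n - k
    return MSDCurve(lags_s=lags, msd_um2=msd, n_pairs=n_pairs, mode="time")


def ensemble_msd(
    tracks: list[ParticleTrack],
    dt_s: float,
    max_lag_fraction: float = 0.25,
    max_lag: int | None = None,
) -> MSDCurve:
    """Pair-count-weighted average of per-track time-averaged MSDs."""
    if not tracks:
        raise ValidationError("need at least one track")
    curves = [
        compute_msd(t, dt_s, max_lag_fraction=max_lag_fraction, max_lag=max_lag)
        for t in tracks
        if len(t) >= 2
    ]
    k_max = max(len(c.lags_s) for c in curves)
    total = np.zeros(k_max)
    counts = np.zeros(k_max, dtype=int)
    for c in curves:
        k = len(c.lags_s)
        total[:k] += c.msd_um2 * c.n_pairs
        counts[:k] += c.n_pairs
    keep = counts >= 1
    return MSDCurve(
        lags_s=np.arange(1, k_max + 1)[keep] * dt_s,
        msd_um2=total[keep] / counts[keep],
        n_pairs=counts[keep],
        mode="time+ensemble",
    )


def fit_diffusivity(
    curve: MSDCurve, fit_lags: int | None = None
) -> tuple[float, float]:
    """Least-squares line ``msd = 4 D tau + b`` over the first ``fit_lags`` lags.

    Returns ``(D, intercept)``; a negative D is reported as-is with a warning
    (sub-resolution motion).
    """
    n = len(curve.lags_s) if fit_lags is None else min(fit_lags, len(curve.lags_s))
    if n < 2:
        raise ValidationError("need >= 2 lags to fit a line")
    slope, intercept = np.polyfit(curve.lags_s[:n], curve.msd_um2[:n], 1)
    D = slope / 4.0
    if D < 0:
        warnings.warn(f"negative fitted diffusivity D={D:.3g} um^2/s")
    return float(D), float(intercept)
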