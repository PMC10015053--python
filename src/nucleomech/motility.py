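"""2D cell motility: nucleus tracking, speed, persistence, rose plots.

Nuclei are detected per frame (nucleus-scale Gaussian smoothing followed by
Otsu thresholding and intensity-weighted centroids) and linked with the same
mutual-nearest-neighbour rule used for beads.  Persistence is the
directionality ratio, net displacement over path length; the mean directional
autocorrelation of step headings is reported as an optional column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import microrheology as mr
from .errors import ValidationError

DEFAULT_FRAME_INTERVAL_MIN = 10.0
DEFAULT_MIN_TRACK_LENGTH = 12


@dataclass
class CellTrajectory:
    """Ordered (t_min, x_um, y_um) samples of one tracked nucleus."""

    cell_id: int
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        dts = np.diff(self.t_min)
        if len(dts) and (np.any(dts <= 0) or not np.allclose(dts, dts[0])):
            raise ValidationError("times must strictly increase at a constant interval")

    def __len__(self) -> int:
        return len(self.t_min)


def detect_nuclei(frame: np.ndarray, smooth_sigma_px: float = 5.0) -> np.ndarray:
    """Per-frame nucleus centroids (x, y) in px after nucleus-scale smoothing."""
    smoothed = gaussian_filter(np.asarray(frame, dtype=float), smooth_sigma_px)
    det = mr.detect_particles(smoothed, threshold="otsu")
    return np.array([(x, y) for x, y, _ in det]).reshape(-1, 2)


def track_nuclei(
    movie: np.ndarray | None = None,
    centroids_per_frame: list[np.ndarray] | None = None,
    max_disp_um: float = 50.0,
    pixel_size_um: float = 1.0,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    min_track_length: int = DEFAULT_MIN_TRACK_LENGTH,
    smooth_sigma_px: float = 5.0,
) -> list[CellTrajectory]:
    """Track nuclei across frames; short tracks are discarded.

    Either a movie (``(t, y, x)`` array) or precomputed per-frame centroid
    tables (px) may be supplied.  A division event — two current detections
    both nearest to one previous nucleus within ``max_disp_um`` — terminates
    the parent track; both daughters start fresh tracks.
    """
    if centroids_per_frame is None:
        if movie is None:
            raise ValidationError("need a movie or per-frame centroids")
        centroids_per_frame = [detect_nuclei(f, smooth_sigma_px) for f in movie]
    if len(centroids_per_frame) < 2:
        raise ValidationError("need >= 2 frames")

    frames = [
        np.asarray(c, dtype=float).reshape(-1, 2) * pixel_size_um
        for c in centroids_per_frame
    ]
    tracks = _link_with_divisions(frames, max_disp_um)
    out = []
    for t in tracks:
        if len(t.frames) < min_track_length:
            continue
        out.append(
            CellTrajectory(
                cell_id=t.particle_id,
                t_min=t.frames * frame_interval_min,
                x_um=t.x_um,
                y_um=t.y_um,
            )
        )
    return out


def _link_with_divisions(frames: list[np.ndarray], max_disp: float) -> list[mr.ParticleTrack]:
    """Mutual-NN linking that terminates a parent when two daughters appear."""
    n_frames = len(frames)
    next_id = 0
    tracks: dict[int, list[tuple[int, float, float]]] = {}
    active: dict[int, int] = {}
    for j, (x, y) in enumerate(frames[0]):
        tracks[next_id] = [(0, float(x), float(y))]
        active[j] = next_id
        next_id += 1
    for f in range(1, n_frames):
        prev, curr = frames[f - 1], frames[f]
        dividing: set[int] = set()
        if len(prev) and len(curr):
            d = np.hypot(
                prev[:, None, 0] - curr[None, :, 0], prev[:, None, 1] - curr[None, :, 1]
            )
            nn_of_curr = np.argmin(d, axis=0)
            within = d[nn_of_curr, np.arange(len(curr))] <= max_disp
            counts = np.bincount(nn_of_curr[within], minlength=len(prev))
            dividing = set(np.nonzero(counts >= 2)[0].tolist())
        pairs = mr._mutual_nearest_pairs(prev, curr, max_disp)
        new_active: dict[int, int] = {}
        for i, j in pairs:
            if i in dividing or i not in active:
                continue
            tid = active[i]
            x, y = curr[j]
            tracks[tid].append((f, float(x), float(y)))
            new_active[j] = tid
        for j, (x, y) in enumerate(curr):
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
            mr.ParticleTrack(
                particle_id=tid,
                frames=fr,
                t_s=fr.astype(float),
                x_um=np.array([s[1] for s in samples]),
                y_um=np.array([s[2] for s in samples]),
                complete=len(samples) == n_frames,
            )
        )
    return out


def trajectories_from_table(df: pd.DataFrame) -> list[CellTrajectory]:
    """Build trajectories from a table (cell_id, t_min | frame, x_um, y_um)."""
    required = {"cell_id", "x_um", "y_um"}
    if missing := required - set(df.columns):
        raise ValidationError(f"trajectory table missing columns: {sorted(missing)}")
    out = []
    for cid, grp in df.groupby("cell_id"):
        if "t_min" in grp.columns:
            grp = grp.sort_values("t_min")
            t = grp["t_min"].to_numpy(dtype=float)
        else:
            grp = grp.sort_values("frame")
            t = grp["frame"].to_numpy(dtype=float) * DEFAULT_FRAME_INTERVAL_MIN
        out.append(
            CellTrajectory(
                cell_id=int(cid),
                t_min=t,
                x_um=grp["x_um"].to_numpy(dtype=float),
                y_um=grp["y_um"].to_numpy(dtype=float),
            )
        )
    return out


def trajectory_metrics(traj: CellTrajectory) -> dict:
    """Mean speed, persistence (directionality ratio), and path geometry.

    ``mean_speed = path_length / elapsed_time``; ``persistence =
    net_displacement / path_length`` (0 for a zero-length path).  The optional
    ``directional_autocorrelation`` column is the mean cosine between
    consecutive step headings.
    """
    if len(traj) < 2:
        raise ValidationError("trajectory needs >= 2 samples")
    dx = np.diff(traj.x_um)
    dy = np.diff(traj.y_um)
    steps = np.hypot(dx, dy)
    path_length = float(steps.sum())
    net = float(np.hypot(traj.x_um[-1] - traj.x_um[0], traj.y_um[-1] - traj.y_um[0]))
    elapsed = float(traj.t_min[-1] - traj.t_min[0])
    mean_speed = path_length / elapsed
    persistence = net / path_length if path_length > 0 else 0.0

    moving = steps > 0
    if np.count_nonzero(moving) >= 2:
        ux, uy = dx[moving] / steps[moving], dy[moving] / steps[moving]
        dacf = float(np.mean(ux[1:] * ux[:-1] + uy[1:] * uy[:-1]))
    else:
        dacf = np.nan
    return {
        "cell_id": traj.cell_id,
        "mean_speed_um_min": mean_speed,
        "persistence": persistence,
        "path_length_um": path_length,
        "net_displacement_um": net,
        "directional_autocorrelation": dacf,
    }


def metrics_table(trajs: list[CellTrajectory]) -> pd.DataFrame:
    if not trajs:
        raise ValidationError("need at least one trajectory")
    return pd.DataFrame([trajectory_metrics(t) for t in trajs])


def rose_plot_data(trajs: list[CellTrajectory]) -> pd.DataFrame:
    """Origin-centred coordinates: each trajectory translated to start at (0,0)."""
    if not trajs:
        raise ValidationError("need at least one trajectory")
    frames = []
    for t in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "t_min": t.t_min,
                    "x_um": t.x_um - t.x_um[0],
                    "y_um": t.y_um - t.y_um[0],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
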