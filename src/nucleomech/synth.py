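"""Synthetic fixtures with known ground truth for every assay.

Each generator returns its data plus a :class:`GroundTruth` record holding the
generating parameters and the seed, sufficient to regenerate the fixture
bit-identically.  Conventions: the cell "front" is the +x direction; all
randomness flows through one ``numpy`` Generator seeded per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import binary_erosion, gaussian_filter
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .errors import ValidationError
from .stacks import ImageStack, LabelMask

SPECTRAL_GRID_NM = tuple(range(460, 601, 10))  # 15 channels


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic fixture, keyed by name."""

    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __getitem__(self, key):
        return self.params[key]

    def to_dict(self) -> dict:
        return {"seed": self.seed, **self.params}


# ---------------------------------------------------------------------------
# Brownian beads


def simulate_brownian_tracks(
    D: float,
    n_particles: int = 100,
    n_frames: int = 500,
    dt: float = 0.01,
    loc_noise_um: float = 0.0,
    seed: int | None = None,
    origin_spacing_um: float = 10.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Brownian tracks: per-axis step variance ``2*D*dt``, positions in um.

    Observed positions are the true positions plus isotropic Gaussian
    localization noise added after the displacement (camera model).  Particles
    start on a square grid with ``origin_spacing_um`` spacing so that linking
    fixtures have a controlled inter-particle distance.
    """
    if D < 0 or loc_noise_um < 0 or dt <= 0:
        raise ValidationError("D, loc_noise_um must be >= 0 and dt > 0")
    if n_frames < 2 or n_particles < 1:
        raise ValidationError("need n_frames >= 2 and n_particles >= 1")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_particles)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    origins = np.c_[gx.ravel(), gy.ravel()][:n_particles] * origin_spacing_um

    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_particles, n_frames - 1, 2))
    true_pos = np.concatenate(
        [origins[:, None, :], origins[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )
    noise = rng.normal(0.0, loc_noise_um, size=true_pos.shape) if loc_noise_um else 0.0
    obs = true_pos + noise

    pid = np.repeat(np.arange(n_particles), n_frames)
    frame = np.tile(np.arange(n_frames), n_particles)
    df = pd.DataFrame(
        {
            "particle_id": pid,
            "frame": frame,
            "t_s": frame * dt,
            "x_um": obs[..., 0].ravel(),
            "y_um": obs[..., 1].ravel(),
            "true_x_um": true_pos[..., 0].ravel(),
            "true_y_um": true_pos[..., 1].ravel(),
        }
    )
    gt = GroundTruth(
        params={
            "D_um2_s": D,
            "n_particles": n_particles,
            "n_frames": n_frames,
            "dt_s": dt,
            "loc_noise_um": loc_noise_um,
            "origin_spacing_um": origin_spacing_um,
        },
        seed=seed,
    )
    return df, gt


def render_particle_movie(
    tracks: pd.DataFrame,
    image_shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.1,
    psf_sigma_px: float = 2.0,
    peak_intensity: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    frame_interval_s: float = 0.01,
) -> ImageStack:
    """Render tracked particles as Gaussian spots plus additive Gaussian noise.

    Particle positions are taken from the ``x_um``/``y_um`` columns and mapped
    to pixels via ``pixel_size_um``.  Spots whose centre falls outside the
    frame are clipped with a warning.
    """
    import logging

    if psf_sigma_px <= 0:
        raise ValidationError("psf_sigma_px must be > 0")
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    n_frames = int(tracks["frame"].max()) + 1
    movie = np.full((n_frames, ny, nx), float(background))
    half = int(np.ceil(6 * psf_sigma_px))
    clipped = 0
    for frame_idx, grp in tracks.groupby("frame"):
        img = movie[int(frame_idx)]
        for x_um, y_um in zip(grp["x_um"], grp["y_um"]):
            cx = x_um / pixel_size_um
            cy = y_um / pixel_size_um
            if not (0 <= cx < nx and 0 <= cy < ny):
                clipped += 1
                continue
            x0, x1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
            y0, y1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            gx = np.exp(-((xs - cx) ** 2) / (2 * psf_sigma_px**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * psf_sigma_px**2))
            img[y0:y1, x0:x1] += peak_intensity * gy[:, None] * gx[None, :]
    if clipped:
        logging.getLogger(__name__).warning(
            "%d particle positions outside the frame were clipped", clipped
        )
    if noise_sd > 0:
        movie += rng.normal(0.0, noise_sd, size=movie.shape)
        movie = np.clip(movie, 0.0, None)
    return ImageStack(
        pixels=movie,
        axis_order="tyx",
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )


# ---------------------------------------------------------------------------
# Spectral FRET stacks


def synth_spectral_stack(
    donor_amp,
    acceptor_amp,
    donor_peak_nm: float = 480.0,
    acceptor_peak_nm: float = 530.0,
    peak_sigma_nm: float = 15.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (32, 32),
    seed: int | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """15-channel emission stack: per-pixel sum of two Gaussian bands + noise.

    ``donor_amp``/``acceptor_amp`` may be scalars or 2D maps of ``shape`` so a
    single stack can hold many regions with different amplitude ratios.
    """
    wl = np.asarray(SPECTRAL_GRID_NM, dtype=float)
    for peak in (donor_peak_nm, acceptor_peak_nm):
        if not (wl[0] <= peak <= wl[-1]):
            raise ValidationError(f"peak {peak} nm outside captured range")
    donor_amp = np.broadcast_to(np.asarray(donor_amp, dtype=float), shape)
    acceptor_amp = np.broadcast_to(np.asarray(acceptor_amp, dtype=float), shape)
    if np.any(donor_amp < 0) or np.any(acceptor_amp < 0):
        raise ValidationError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    dband = np.exp(-((wl - donor_peak_nm) ** 2) / (2 * peak_sigma_nm**2))
    aband = np.exp(-((wl - acceptor_peak_nm) ** 2) / (2 * peak_sigma_nm**2))
    pixels = (
        donor_amp[None] * dband[:, None, None] + acceptor_amp[None] * aband[:, None, None]
    )
    if noise_sd > 0:
        pixels = np.clip(pixels + rng.normal(0.0, noise_sd, pixels.shape), 0.0, None)
    stack = ImageStack(
        pixels=pixels, axis_order="cyx", channel_wavelengths_nm=SPECTRAL_GRID_NM
    )
    gt = GroundTruth(
        params={
            "donor_amp": float(donor_amp.mean()),
            "acceptor_amp": float(acceptor_amp.mean()),
            "amp_ratio": float(donor_amp.mean() / acceptor_amp.mean())
            if acceptor_amp.mean() > 0
            else np.inf,
            "donor_peak_nm": donor_peak_nm,
            "acceptor_peak_nm": acceptor_peak_nm,
            "peak_sigma_nm": peak_sigma_nm,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Photon decays


def synth_photon_decay(
    tau_ns: float,
    n_photons: int = 10_000,
    window_ns: float = 12.5,
    n_bins: int = 256,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Ideal TCSPC histogram: exponential arrivals truncated to [0, window].

    Returns ``(bin_edges_ns, counts, ground_truth)``.
    """
    if tau_ns <= 0:
        raise ValidationError("tau_ns must be > 0")
    if window_ns <= tau_ns / 10:
        raise ValidationError("window_ns must exceed tau_ns / 10")
    if n_photons < 1:
        raise ValidationError("n_photons must be >= 1")
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling of the truncated exponential
    u = rng.random(n_photons)
    arrivals = -tau_ns * np.log1p(-u * (1.0 - np.exp(-window_ns / tau_ns)))
    edges = np.linspace(0.0, window_ns, n_bins + 1)
    counts, _ = np.histogram(arrivals, bins=edges)
    gt = GroundTruth(
        params={
            "tau_ns": tau_ns,
            "n_photons": n_photons,
            "window_ns": window_ns,
            "n_bins": n_bins,
        },
        seed=seed,
    )
    return edges, counts, gt


# ---------------------------------------------------------------------------
# Nuclei with invaginations


def _ellipse_polygon(a_um: float, b_um: float, n_vertices: int = 720) -> Polygon:
    th = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    return Polygon(np.c_[a_um * np.cos(th), b_um * np.sin(th)])


def synth_nucleus(
    semi_axes_um: tuple[float, float] = (8.0, 5.0),
    invaginations: Sequence[tuple[float, float, float]] = (),
    pixel_size_um: float = 0.1,
    margin_um: float = 2.0,
    seed: int | None = None,
) -> tuple[LabelMask, np.ndarray, Polygon, GroundTruth]:
    """Elliptical nucleus with slit invaginations of known geometry.

    Each invagination is ``(angle_deg, depth_um, width_um)``: a rectangular
    slit entering the ellipse radially at the boundary point with parametric
    angle ``angle_deg``.  Returns the rasterized mask, a 1-px nuclear-envelope
    skeleton image (the 8-connected boundary of the mask), the exact analytic
    outline polygon, and ground truth whose ``eop`` is computed from exact
    polygon arithmetic (outline length / convex-envelope length).
    """
    a, b = semi_axes_um
    if a <= 0 or b <= 0:
        raise ValidationError("semi-axes must be > 0")
    ellipse = _ellipse_polygon(a, b)
    slits = []
    for angle_deg, depth, width in invaginations:
        if depth >= min(a, b):
            raise ValidationError("invagination depth must be < smaller semi-axis")
        if depth <= 0 or width <= 0:
            raise ValidationError("invagination depth and width must be > 0")
        th = np.deg2rad(angle_deg)
        entry = np.array([a * np.cos(th), b * np.sin(th)])
        inward = -entry / np.hypot(*entry)
        normal = np.array([-inward[1], inward[0]])
        # extend 1 um outward so the difference cleanly opens the boundary
        p_out = entry - 1.0 * inward
        p_in = entry + depth * inward
        slit = Polygon(
            [
                p_out + 0.5 * width * normal,
                p_in + 0.5 * width * normal,
                p_in - 0.5 * width * normal,
                p_out - 0.5 * width * normal,
            ]
        )
        slits.append(slit)
    for i in range(len(slits)):
        for j in range(i + 1, len(slits)):
            if slits[i].intersects(slits[j]):
                raise ValidationError(f"invaginations {i} and {j} overlap")
    region = ellipse
    for slit in slits:
        region = region.difference(slit)
    if region.geom_type != "Polygon" or region.interiors:
        raise ValidationError("invaginations split or puncture the nucleus")

    hull = region.convex_hull
    eop_true = region.exterior.length / hull.exterior.length
    # analytic reference: smooth perimeter + two slit walls per invagination
    eop_analytic = (
        ellipse.exterior.length + 2.0 * sum(d for _, d, _ in invaginations)
    ) / hull.exterior.length

    # rasterize: shift into positive pixel coordinates
    coords = np.asarray(region.exterior.coords)
    offset = np.array([a + margin_um, b + margin_um])
    px = (coords + offset) / pixel_size_um
    shape = (
        int(np.ceil(2 * (b + margin_um) / pixel_size_um)),
        int(np.ceil(2 * (a + margin_um) / pixel_size_um)),
    )
    mask = np.zeros(shape, dtype=np.int32)
    rr, cc = draw_polygon(px[:, 1], px[:, 0], shape=shape)
    mask[rr, cc] = 1
    boundary = (mask > 0) & ~binary_erosion(mask > 0, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    skeleton = boundary.astype(np.uint8)

    gt = GroundTruth(
        params={
            "semi_axes_um": list(semi_axes_um),
            "invaginations": [list(v) for v in invaginations],
            "pixel_size_um": pixel_size_um,
            "eop": eop_true,
            "eop_analytic": eop_analytic,
            "perimeter_um": region.exterior.length,
            "hull_perimeter_um": hull.exterior.length,
            "offset_um": list(offset),
        },
        seed=seed,
    )
    return LabelMask(mask, pixel_size_um), skeleton, region, gt


# ---------------------------------------------------------------------------
# Polarized nuclei


def _ellipse_mask(shape, center, a_px, b_px, angle_rad) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xx - center[0]
    dy = yy - center[1]
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def synth_polarized_cell(
    front_fraction: float,
    n_cells: int = 50,
    image_shape: tuple[int, int] = (64, 64),
    quantile: float = 0.80,
    randomize_orientation: bool = True,
    seed: int | None = None,
) -> tuple[list[dict], GroundTruth]:
    """Per-cell nuclear-signal fixtures with a controlled front bias.

    Each cell carries a signal image, a nucleus mask, a Golgi centroid placed
    on the front side, and the true front axis angle.  Top-quantile pixels are
    planted so each lands in the front half independently with probability
    ``front_fraction`` (binomial across the ``ceil((1-quantile)*n)`` planted
    pixels).
    """
    if not (0.0 <= front_fraction <= 1.0):
        raise ValidationError("front_fraction must be in [0, 1]")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    cells = []
    for _ in range(n_cells):
        angle = rng.uniform(0, 2 * np.pi) if randomize_orientation else 0.0
        a_px = rng.uniform(0.30, 0.42) * nx
        b_px = rng.uniform(0.22, 0.32) * ny
        center = (nx / 2.0 + rng.uniform(-1, 1), ny / 2.0 + rng.uniform(-1, 1))
        mask = _ellipse_mask(image_shape, center, a_px, b_px, angle)
        n_mask = int(mask.sum())
        n_top = int(np.ceil((1.0 - quantile) * n_mask))

        signal = np.zeros(image_shape)
        signal[mask] = rng.normal(100.0, 5.0, size=n_mask).clip(1.0)

        yy, xx = np.nonzero(mask)
        u = np.cos(angle) * (xx - center[0]) + np.sin(angle) * (yy - center[1])
        # 1 px guard band around the midline keeps planted pixels on their
        # intended side even after the pipeline re-estimates the centroid
        front_idx = np.nonzero(u > 1.0)[0]
        rear_idx = np.nonzero(u < -1.0)[0]
        go_front = rng.random(n_top) < front_fraction
        k_front = min(int(go_front.sum()), front_idx.size)
        k_rear = min(n_top - k_front, rear_idx.size)
        chosen = np.concatenate(
            [
                rng.choice(front_idx, size=k_front, replace=False),
                rng.choice(rear_idx, size=k_rear, replace=False),
            ]
        )
        signal[yy[chosen], xx[chosen]] = 200.0 + rng.uniform(0, 20, size=chosen.size)

        golgi = (
            center[0] + 1.15 * a_px * np.cos(angle),
            center[1] + 1.15 * a_px * np.sin(angle),
        )
        cells.append(
            {
                "signal": signal,
                "mask": LabelMask((mask).astype(np.int32)),
                "golgi_centroid": golgi,
                "angle_rad": angle,
            }
        )
    gt = GroundTruth(
        params={
            "front_fraction": front_fraction,
            "n_cells": n_cells,
            "quantile": quantile,
            "image_shape": list(image_shape),
        },
        seed=seed,
    )
    return cells, gt


# ---------------------------------------------------------------------------
# Multichannel cell images


def synth_cell_image(
    nuc_intensity: float = 100.0,
    cyto_intensity: float = 50.0,
    n_fa_blobs: int = 20,
    actin_pattern: str = "stripes",
    noise_sd: float = 0.0,
    image_shape: tuple[int, int] = (192, 192),
    pixel_size_um: float = 0.2,
    blob_sigma_px: float = 1.5,
    blob_peak: float = 150.0,
    stripe_period_px: float = 8.0,
    seed: int | None = None,
) -> tuple[ImageStack, LabelMask, LabelMask, GroundTruth]:
    """Four-channel cell: nucleus stain, YAP-like signal, vinculin blobs, actin.

    Channels are ordered (nucleus, yap, vinculin, actin).  Focal-adhesion
    blobs are placed inside the cell but outside the nucleus with mutual
    separation > 3x the blob diameter; infeasible packing raises.
    """
    if nuc_intensity < 0 or cyto_intensity < 0:
        raise ValidationError("intensities must be >= 0")
    if actin_pattern not in ("stripes", "isotropic"):
        raise ValidationError("actin_pattern must be 'stripes' or 'isotropic'")
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    center = (nx / 2.0, ny / 2.0)
    cell = _ellipse_mask(image_shape, center, 0.45 * nx, 0.42 * ny, 0.0)
    nucleus = _ellipse_mask(image_shape, center, 0.18 * nx, 0.15 * ny, 0.0)

    nuc_ch = np.where(nucleus, 200.0, 0.0)
    yap_ch = np.where(nucleus, float(nuc_intensity), 0.0) + np.where(
        cell & ~nucleus, float(cyto_intensity), 0.0
    )

    # rejection-sample blob centres with enforced separation
    min_sep = 3.0 * (2.0 * blob_sigma_px * 2.355 / 2.0)  # 3 x FWHM-ish diameter
    candidates = np.c_[np.nonzero(cell & ~nucleus)][:, ::-1]  # (x, y)
    centres: list[np.ndarray] = []
    attempts = 0
    while len(centres) < n_fa_blobs:
        attempts += 1
        if attempts > 20_000:
            raise ValidationError("cannot pack focal-adhesion blobs at this separation")
        c = candidates[rng.integers(len(candidates))].astype(float)
        if all(np.hypot(*(c - p)) > min_sep for p in centres):
            centres.append(c)
    vin_ch = np.zeros(image_shape)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for cx, cy in centres:
        vin_ch += blob_peak * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * blob_sigma_px**2)
        )
    vin_ch[~cell] = 0.0

    if actin_pattern == "stripes":
        actin = 100.0 + 80.0 * np.sin(2 * np.pi * xx / stripe_period_px)
    else:
        actin = gaussian_filter(rng.normal(100.0, 40.0, image_shape), 1.0)
    actin = np.clip(np.where(cell, actin, 0.0), 0.0, None)

    pixels = np.stack([nuc_ch, yap_ch, vin_ch, actin])
    if noise_sd > 0:
        pixels = np.clip(pixels + rng.normal(0.0, noise_sd, pixels.shape), 0.0, None)
    stack = ImageStack(pixels=pixels, axis_order="cyx", pixel_size_um=pixel_size_um)
    gt = GroundTruth(
        params={
            "nuc_intensity": nuc_intensity,
            "cyto_intensity": cyto_intensity,
            "nc_ratio": nuc_intensity / cyto_intensity if cyto_intensity > 0 else np.inf,
            "n_fa_blobs": n_fa_blobs,
            "actin_pattern": actin_pattern,
            "blob_centres_px": [list(c) for c in centres],
            "pixel_size_um": pixel_size_um,
        },
        seed=seed,
    )
    return (
        stack,
        LabelMask(nucleus.astype(np.int32), pixel_size_um),
        LabelMask(cell.astype(np.int32), pixel_size_um),
        gt,
    )


# ---------------------------------------------------------------------------
# Cell trajectories


def simulate_cell_trajectories(
    speed_um_min: float = 0.5,
    rot_diffusion: float = 0.05,
    n_cells: int = 30,
    dt_min: float = 10.0,
    duration_h: float = 18.0,
    seed: int | None = None,
    origin_spacing_um: float = 200.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Persistent random walk: constant step length, diffusing heading.

    The heading angle receives Gaussian increments of variance
    ``2 * rot_diffusion * dt`` per step.  The default 10-min interval over
    18 h yields 109 samples per cell.
    """
    if speed_um_min < 0 or rot_diffusion < 0:
        raise ValidationError("speed and rot_diffusion must be >= 0")
    n_samples = int(round(duration_h * 60.0 / dt_min)) + 1
    if n_samples < 2:
        raise ValidationError("need at least 2 samples per trajectory")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_cells)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    origins = np.c_[gx.ravel(), gy.ravel()][:n_cells] * origin_spacing_um

    headings0 = rng.uniform(0, 2 * np.pi, size=n_cells)
    dthetas = rng.normal(
        0.0, np.sqrt(2.0 * rot_diffusion * dt_min), size=(n_cells, n_samples - 1)
    )
    theta = headings0[:, None] + np.cumsum(dthetas, axis=1)
    step = speed_um_min * dt_min
    dx = step * np.cos(theta)
    dy = step * np.sin(theta)
    pos = np.zeros((n_cells, n_samples, 2))
    pos[:, 0] = origins
    pos[:, 1:, 0] = origins[:, None, 0] + np.cumsum(dx, axis=1)
    pos[:, 1:, 1] = origins[:, None, 1] + np.cumsum(dy, axis=1)

    cid = np.repeat(np.arange(n_cells), n_samples)
    frame = np.tile(np.arange(n_samples), n_cells)
    df = pd.DataFrame(
        {
            "cell_id": cid,
            "frame": frame,
            "t_min": frame * dt_min,
            "x_um": pos[..., 0].ravel(),
            "y_um": pos[..., 1].ravel(),
        }
    )
    gt = GroundTruth(
        params={
            "speed_um_min": speed_um_min,
            "rot_diffusion": rot_diffusion,
            "n_cells": n_cells,
            "dt_min": dt_min,
            "duration_h": duration_h,
            "n_samples": n_samples,
        },
        seed=seed,
    )
    return df, gt
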