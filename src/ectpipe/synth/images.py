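"""Synthetic imaging modalities: wire videos, brightfield stills, Ca²⁺ dye
stacks and sarcomere (Z-disc) lattices — each with a complete ground-truth
record.

These emulate the geometry and noise structure the analysis stages must cope
with, not microscope optics: wires are Gaussian-profile parabolic arcs, the
tissue silhouette is a dark ellipse between two bright wires, Z-discs are
oriented anisotropic Gaussian bars, and noise is additive Gaussian scaled by
a requested signal-to-noise ratio.
"""

from __future__ import annotations

import numpy as np

from ..models import biexp_pulse
from ..timeseries import TimeSeries
from .groundtruth import GroundTruth

__all__ = [
    "gen_wire_video",
    "gen_brightfield",
    "gen_ca_video",
    "gen_sarcomere_image",
]


def wire_arc(x: np.ndarray, anchors, sag: float) -> np.ndarray:
    """Row position of a parabolic wire through the two anchors at each column.

    The arc passes through both anchors and its mid-span perpendicular offset
    from the anchor chord equals ``sag`` (in +row direction).
    """
    (x0, y0), (x1, y1) = anchors
    s = (x - x0) / (x1 - x0)
    chord = y0 + (y1 - y0) * s
    return chord + sag * 4.0 * s * (1.0 - s)


def gen_wire_video(
    deflection_trace: TimeSeries | np.ndarray,
    anchors: tuple[tuple[float, float], tuple[float, float]] = ((10.0, 20.0), (245.0, 20.0)),
    thickness: float = 2.0,
    img_shape: tuple[int, int] = (64, 256),
    snr: float = 10.0,
    seed: int = 0,
    amplitude: float = 100.0,
    background: float = 10.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a fluorescent-wire video whose mid-span sag follows a trace.

    Each frame shows a Gaussian cross-section (sd ``thickness`` px) parabolic
    arc through the two fixed ``anchors``; the commanded per-frame sag (px)
    comes from ``deflection_trace``.  Gaussian noise of sd ``amplitude/snr``
    is added.  Returns a float32 (frames, rows, cols) stack.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    sags = (
        deflection_trace.y
        if isinstance(deflection_trace, TimeSeries)
        else np.asarray(deflection_trace, dtype=float)
    )
    rows, cols = img_shape
    (x0, y0), (x1, y1) = anchors
    max_y = max(y0, y1) + float(np.max(sags, initial=0.0))
    if max_y + 3 * thickness >= rows or min(y0, y1) - 3 * thickness < 0:
        raise ValueError("wire leaves the frame at maximal deflection")

    xs = np.arange(cols, dtype=float)
    ys = np.arange(rows, dtype=float)[:, None]
    inside = (xs >= x0) & (xs <= x1)
    rng = np.random.default_rng(seed)
    noise_sd = amplitude / snr
    stack = np.empty((len(sags), rows, cols), dtype=np.float32)
    for i, sag in enumerate(sags):
        yc = wire_arc(xs, anchors, float(sag))
        frame = background + amplitude * np.where(
            inside, np.exp(-((ys - yc) ** 2) / (2.0 * thickness**2)), 0.0
        )
        frame = frame + rng.normal(0.0, noise_sd, size=(rows, cols))
        stack[i] = frame.astype(np.float32)
    gt = GroundTruth(
        "wire_video",
        {
            "sags_px": sags,
            "anchors": anchors,
            "thickness": thickness,
            "img_shape": img_shape,
            "snr": snr,
            "amplitude": amplitude,
            "background": background,
            "fs": deflection_trace.fs if isinstance(deflection_trace, TimeSeries) else None,
        },
        seed,
    )
    return stack, gt


def gen_brightfield(
    axes_mm: tuple[float, float] = (0.8, 0.4),
    px_size: float = 0.005,
    img_shape: tuple[int, int] = (260, 480),
    center_px: tuple[float, float] | None = None,
    wire_gap_px: float = 4.0,
    wire_width_px: float = 3.0,
    noise_sd: float = 4.0,
    seed: int = 0,
    tissue_level: float = 70.0,
    background_level: float = 180.0,
    wire_level: float = 250.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Brightfield still: dark elliptical tissue between two bright wires.

    ``axes_mm`` are the ellipse semi-axes (a, b) in mm, major axis along the
    image columns; the true silhouette area ``pi*a*b`` (mm²) and the
    rasterized pixel-count mask are both recorded in the ground truth.  Two
    bright horizontal wires run tangent above and below the tissue.
    """
    a, b = axes_mm
    rows, cols = img_shape
    cy, cx = center_px if center_px is not None else (rows / 2.0, cols / 2.0)
    a_px, b_px = a / px_size, b / px_size
    if a_px >= cols / 2 - 2 or b_px >= rows / 2 - 2:
        raise ValueError("ellipse does not fit in the image")

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    mask = ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0

    rng = np.random.default_rng(seed)
    img = np.full(img_shape, background_level, dtype=float)
    img[mask] = tissue_level
    for sign in (-1.0, 1.0):
        ywire = cy + sign * (b_px + wire_gap_px)
        band = np.exp(-((yy - ywire) ** 2) / (2.0 * wire_width_px**2))
        img = img + (wire_level - img) * band
    img = img + rng.normal(0.0, noise_sd, size=img_shape)
    gt = GroundTruth(
        "brightfield",
        {
            "axes_mm": axes_mm,
            "area_mm2": float(np.pi * a * b),
            "px_size": px_size,
            "mask_px_count": int(mask.sum()),
            "center_px": (cy, cx),
            "img_shape": img_shape,
            "noise_sd": noise_sd,
        },
        seed,
    )
    return img.astype(np.float32), gt


def gen_ca_video(
    trace: TimeSeries,
    img_shape: tuple[int, int] = (64, 64),
    tissue_frac: float = 0.6,
    artifact_frac: float = 0.01,
    base_intensity: float = 50.0,
    background: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Dye-video stack whose tissue-region intensity follows a ΔF trace.

    A central elliptical tissue region (covering ``tissue_frac`` of each
    axis) carries ``base_intensity + trace``; a fraction ``artifact_frac``
    of tissue pixels are replaced by saturated constant hot spots.  The
    ground truth records the tissue and artifact masks and the programmed
    trace.
    """
    rows, cols = img_shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = rows / 2.0, cols / 2.0
    tissue = ((xx - cx) / (tissue_frac * cols / 2)) ** 2 + (
        (yy - cy) / (tissue_frac * rows / 2)
    ) ** 2 <= 1.0
    rng = np.random.default_rng(seed)
    art = np.zeros(img_shape, dtype=bool)
    idx = np.flatnonzero(tissue)
    n_art = int(round(artifact_frac * idx.size))
    if n_art:
        art.flat[rng.choice(idx, size=n_art, replace=False)] = True

    n_frames = len(trace)
    stack = np.empty((n_frames, rows, cols), dtype=np.float32)
    for i in range(n_frames):
        frame = np.full(img_shape, background, dtype=float)
        frame[tissue] = base_intensity + trace.y[i]
        frame[art] = 255.0
        frame += rng.normal(0.0, noise_sd, size=img_shape)
        stack[i] = frame.astype(np.float32)
    gt = GroundTruth(
        "ca_video",
        {
            "tissue_mask": tissue,
            "artifact_mask": art,
            "trace_y": trace.y,
            "fs": trace.fs,
            "base_intensity": base_intensity,
            "background": background,
            "noise_sd": noise_sd,
        },
        seed,
    )
    return stack, gt


def gen_sarcomere_image(
    spacing_um: float = 1.72,
    angle_mean_deg: float = 0.0,
    angle_sd_deg: float = 10.0,
    px_size_um: float = 0.1,
    n_domains: int = 25,
    domain_px: int = 80,
    zdisc_len_um: float = 1.4,
    zdisc_width_px: float = 1.5,
    fibril_spacing_um: float = 3.0,
    amplitude: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """α-actinin-like Z-disc lattice tiled into independently oriented domains.

    The image is a near-square grid of ``n_domains`` square tiles of side
    ``domain_px``.  Each tile holds parallel myofibrils (lateral spacing
    ``fibril_spacing_um``) of short Z-disc bars every ``spacing_um`` along
    the fibril axis; the per-tile Z-disc orientation is drawn from a normal
    with mean ``angle_mean_deg`` and sd ``angle_sd_deg`` and folded to
    [0°, 180°).  The sarcomere (link) angle — the direction from one Z-disc
    to its neighbor — is the disc orientation + 90°.

    Ground truth records every disc center (x, y in px), its orientation, a
    domain id, and the true link list (consecutive discs along a fibril).
    """
    ncols = int(np.ceil(np.sqrt(n_domains)))
    nrows = int(np.ceil(n_domains / ncols))
    rows, cols = nrows * domain_px, ncols * domain_px
    rng = np.random.default_rng(seed)

    angles = np.mod(rng.normal(angle_mean_deg, angle_sd_deg, size=n_domains), 180.0)
    spacing_px = spacing_um / px_size_um
    fib_px = fibril_spacing_um / px_size_um
    sig_par = (zdisc_len_um / px_size_um) / 2.355  # FWHM -> sd, along the disc

    centers: list[tuple[float, float]] = []  # (x, y) px
    orients: list[float] = []
    domains: list[int] = []
    links: list[tuple[int, int]] = []
    img = np.full((rows, cols), background, dtype=float)
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)

    margin = sig_par * 2.0 + 2.0
    for d in range(n_domains):
        r0, c0 = (d // ncols) * domain_px, (d % ncols) * domain_px
        theta = np.deg2rad(angles[d])  # disc orientation (long axis)
        # fibril axis is perpendicular to the discs
        ux, uy = -np.sin(theta), np.cos(theta)
        vx, vy = np.cos(theta), np.sin(theta)
        ctr_x, ctr_y = c0 + domain_px / 2.0, r0 + domain_px / 2.0
        half = domain_px / 2.0
        n_steps = int(np.ceil(half * 1.5 / spacing_px))
        n_fibs = int(np.ceil(half * 1.5 / fib_px))
        first_in_fib: dict[int, int] = {}
        for j in range(-n_fibs, n_fibs + 1):
            prev = -1
            for k in range(-n_steps, n_steps + 1):
                x = ctr_x + k * spacing_px * ux + j * fib_px * vx
                y = ctr_y + k * spacing_px * uy + j * fib_px * vy
                if not (
                    c0 + margin <= x < c0 + domain_px - margin
                    and r0 + margin <= y < r0 + domain_px - margin
                ):
                    prev = -1
                    continue
                centers.append((x, y))
                orients.append(angles[d])
                domains.append(d)
                idx = len(centers) - 1
                if prev >= 0:
                    links.append((prev, idx))
                prev = idx

    for (x, y), ang in zip(centers, orients):
        th = np.deg2rad(ang)
        # rotated anisotropic Gaussian bar, rendered on a local patch
        rad = int(np.ceil(3 * sig_par)) + 3
        r_lo, r_hi = int(max(0, y - rad)), int(min(rows, y + rad + 1))
        c_lo, c_hi = int(max(0, x - rad)), int(min(cols, x + rad + 1))
        py, px = yy[r_lo:r_hi, c_lo:c_hi] - y, xx[r_lo:r_hi, c_lo:c_hi] - x
        d_par = px * np.cos(th) + py * np.sin(th)
        d_perp = -px * np.sin(th) + py * np.cos(th)
        img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
            -(d_par**2) / (2 * sig_par**2) - (d_perp**2) / (2 * zdisc_width_px**2)
        )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=(rows, cols))

    link_angles = []
    for i, j in links:
        dx, dy = centers[j][0] - centers[i][0], centers[j][1] - centers[i][1]
        link_angles.append(float(np.mod(np.rad2deg(np.arctan2(dy, dx)), 180.0)))
    gt = GroundTruth(
        "sarcomere_image",
        {
            "spacing_um": spacing_um,
            "angle_mean_deg": angle_mean_deg,
            "angle_sd_deg": angle_sd_deg,
            "px_size_um": px_size_um,
            "domain_angles_deg": angles,
            "centers_px": centers,
            "orientations_deg": orients,
            "domain_ids": domains,
            "links": links,
            "link_angles_deg": link_angles,
            "img_shape": (rows, cols),
            "noise_sd": noise_sd,
        },
        seed,
    )
    return img.astype(np.float32), gt
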