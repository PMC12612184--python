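"""Reproducible synthetic inputs with machine-readable ground truth.

Every generator takes a frozen recipe plus an RNG seed and returns both
the synthetic data and a truth table, enabling closed-loop parameter
recovery tests for the imaging, orientation, coverage and expression
modules.  Identical recipe + seed give byte-identical output.

What is emulated
----------------
* ``make_image``: multichannel fluorescence fields — nuclei as Gaussian
  blobs (Hoechst-like), fibrous cells as Gaussian-profile ribbons
  (F-actin / marker-like) whose axial orientations follow a uniform, a
  von Mises, or a two-family orthogonal-mixture model; constant + linear
  gradient background; Gaussian and optional Poisson noise.
* ``make_growth_series``: a colony expanding radially from a central
  seeding point at constant programmed speed, as binary masks and/or
  nuclei fields per imaging day, clipped at the well rim; truth areas
  are ``pi * min(r(t), a)^2``.
* ``make_ct_table``: qPCR Ct tables with programmed fold changes
  (``Ct_target = baseline - log2(fold) + noise``) against a housekeeping
  gene, replicated per condition.

Angles are axial, degrees in [-90, 90), counter-clockwise from the
image x axis with y up — the same convention the orientation module
reports.  Images live on the projected (flattened) plane; the dome's
projection distortion is not simulated, matching the deflate-and-image
acquisition workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImageRecipe",
    "GrowthRecipe",
    "CtRecipe",
    "make_image",
    "make_growth_series",
    "make_ct_table",
    "make_label_ellipses",
    "stripe_image",
    "sample_axial_angles",
]


# ---------------------------------------------------------------------------
# Angle sampling
# ---------------------------------------------------------------------------


def sample_axial_angles(
    n: int,
    rng: np.random.Generator,
    model: str = "uniform",
    mu_deg: float = 0.0,
    kappa: float = 4.0,
    mixture_angle_deg: float = 90.0,
    mixture_weight: float = 0.5,
) -> np.ndarray:
    """Sample axial orientations (deg, [-90, 90)) from an orientation model.

    ``model`` is ``'uniform'``, ``'vonmises'`` (axial von Mises: the
    doubled angle 2*theta follows von Mises(2*mu, kappa)), or
    ``'two-family'`` — a mixture of two von Mises families at ``mu`` and
    ``mu + mixture_angle_deg`` with weight ``mixture_weight`` on the
    first.
    """
    if model == "uniform":
        return rng.uniform(-90.0, 90.0, size=n)
    if model == "vonmises":
        doubled = rng.vonmises(math.radians(2.0 * mu_deg), kappa, size=n)
        return (np.degrees(doubled) / 2.0 + 90.0) % 180.0 - 90.0
    if model == "two-family":
        first = rng.random(n) < mixture_weight
        mus = np.where(first, mu_deg, mu_deg + mixture_angle_deg)
        doubled = rng.vonmises(0.0, kappa, size=n) + np.radians(2.0 * mus)
        return (np.degrees(doubled) / 2.0 + 90.0) % 180.0 - 90.0
    raise ValueError(f"unknown orientation model {model!r}")


# ---------------------------------------------------------------------------
# Rendering primitives (math frame: x = col, y = -row)
# ---------------------------------------------------------------------------


def _render_blobs(image, xs, ys, radii, amps):
    """Additively render isotropic Gaussian blobs (sigma = radius / 2)."""
    h, w = image.shape
    for x0, y0, rad, amp in zip(xs, ys, radii, amps):
        sig = rad / 2.0
        ext = int(math.ceil(3.0 * rad))
        c0, c1 = max(0, int(x0) - ext), min(w, int(x0) + ext + 1)
        r0, r1 = max(0, int(-y0) - ext), min(h, int(-y0) + ext + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        dx = cols[None, :] - x0
        dy = (-rows[:, None]) - y0
        image[r0:r1, c0:c1] += amp * np.exp(-(dx**2 + dy**2) / (2.0 * sig**2))


def _render_fibers(image, xs, ys, angles_deg, lengths, widths, amps):
    """Additively render straight Gaussian-profile ribbons (fibres)."""
    h, w = image.shape
    for x0, y0, ang, length, width, amp in zip(xs, ys, angles_deg, lengths, widths, amps):
        th = math.radians(ang)
        ct, st = math.cos(th), math.sin(th)
        half = length / 2.0
        margin = 4.0 * width
        ext_x = abs(ct) * half + margin
        ext_y = abs(st) * half + margin
        c0, c1 = max(0, int(x0 - ext_x)), min(w, int(x0 + ext_x) + 1)
        r0, r1 = max(0, int(-y0 - ext_y)), min(h, int(-y0 + ext_y) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        dx = cols[None, :] - x0
        dy = (-rows[:, None]) - y0
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        over = np.maximum(np.abs(u) - half, 0.0)
        image[r0:r1, c0:c1] += amp * np.exp(-(v**2 + over**2) / (2.0 * width**2))


def _place_points(rng, n, size, layout, center, r_inner, r_outer, min_sep, margin):
    """Random (x, y) positions in the math frame (y in [-(size-1), 0])."""
    placed_x, placed_y = [], []
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while len(placed_x) < n and attempts < max_attempts:
        attempts += 1
        if layout == "uniform":
            x = rng.uniform(margin, size - 1 - margin)
            y = -rng.uniform(margin, size - 1 - margin)
        elif layout in ("disc", "annulus"):
            lo = 0.0 if layout == "disc" else r_inner
            rad = math.sqrt(rng.uniform(lo**2, r_outer**2))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            x = center[0] + rad * math.cos(phi)
            y = center[1] + rad * math.sin(phi)
            if not (0 <= x < size and -size < y <= 0):
                continue
        else:
            raise ValueError(f"unknown layout {layout!r}")
        if min_sep > 0 and placed_x:
            d2 = (np.array(placed_x) - x) ** 2 + (np.array(placed_y) - y) ** 2
            if (d2 < min_sep**2).any():
                continue
        placed_x.append(x)
        placed_y.append(y)
    if len(placed_x) < n:
        raise RuntimeError(
            f"placed only {len(placed_x)}/{n} objects with min separation {min_sep}"
        )
    return np.array(placed_x), np.array(placed_y)


# ---------------------------------------------------------------------------
# Image recipe
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageRecipe:
    """Recipe for one multichannel synthetic fluorescence image.

    Intensities are arbitrary fluorescence units on a float image;
    channel names follow the chip staining scheme (nuclei / green /
    red).  ``fiber_channel_amps`` maps marker channels to the ribbon
    peak amplitude in that channel, emulating per-condition marker
    levels.
    """

    size_px: int = 1024
    pixel_size_um: float = 2.0
    seed: int = 0
    # nuclei
    n_nuclei: int = 100
    nucleus_radius_px: float = 6.0
    nucleus_radius_jitter: float = 0.15  # lognormal-ish relative spread
    nucleus_amp: float = 100.0
    nuclei_layout: str = "uniform"  # uniform | disc | annulus
    nuclei_min_separation_px: float = 0.0
    # fibres
    n_fibers: int = 150
    fiber_length_px: float = 120.0
    fiber_width_px: float = 3.0
    orientation_model: str = "uniform"  # uniform | vonmises | two-family
    orientation_mu_deg: float = 0.0
    orientation_kappa: float = 4.0
    mixture_angle_deg: float = 90.0
    mixture_weight: float = 0.5
    fiber_channel_amps: dict = field(default_factory=lambda: {"green": 80.0, "red": 40.0})
    # placement region for disc/annulus layouts (px, math frame)
    region_center_px: tuple[float, float] | None = None
    region_r_inner_px: float = 0.0
    region_r_outer_px: float | None = None
    # background and noise
    background_level: float = 10.0
    background_gradient: float = 5.0  # peak-to-peak linear gradient amplitude
    noise_gaussian_sd: float = 2.0
    noise_poisson: bool = False


def make_image(recipe: ImageRecipe) -> tuple[dict[str, np.ndarray], dict[str, pd.DataFrame]]:
    """Render a multichannel image and its ground-truth tables.

    Returns ``(channels, truth)`` where ``channels`` maps ``nuclei`` /
    marker names to float arrays and ``truth`` holds ``"nuclei"``
    (x, y, radius) and ``"fibers"`` (x, y, angle_deg, length, width)
    DataFrames in pixel/math-frame coordinates.  Warns when the render
    saturates more than 95 % of pixels.
    """
    rng = np.random.default_rng(recipe.seed)
    size = recipe.size_px
    center = recipe.region_center_px or (size / 2.0, -size / 2.0)
    r_outer = recipe.region_r_outer_px or size / 2.0

    channels: dict[str, np.ndarray] = {"nuclei": np.zeros((size, size))}
    for ch in recipe.fiber_channel_amps:
        channels[ch] = np.zeros((size, size))

    # nuclei
    nx, ny = _place_points(
        rng,
        recipe.n_nuclei,
        size,
        recipe.nuclei_layout,
        center,
        recipe.region_r_inner_px,
        r_outer,
        recipe.nuclei_min_separation_px,
        margin=2.0 * recipe.nucleus_radius_px,
    )
    radii = recipe.nucleus_radius_px * np.exp(
        rng.normal(0.0, recipe.nucleus_radius_jitter, size=recipe.n_nuclei)
    )
    _render_blobs(channels["nuclei"], nx, ny, radii, np.full(recipe.n_nuclei, recipe.nucleus_amp))
    truth_nuclei = pd.DataFrame({"x_px": nx, "y_px": ny, "radius_px": radii})

    # fibres
    fx, fy = _place_points(
        rng, recipe.n_fibers, size, "uniform", center, 0.0, r_outer, 0.0,
        margin=recipe.fiber_width_px,
    )
    angles = sample_axial_angles(
        recipe.n_fibers,
        rng,
        recipe.orientation_model,
        recipe.orientation_mu_deg,
        recipe.orientation_kappa,
        recipe.mixture_angle_deg,
        recipe.mixture_weight,
    )
    lengths = np.full(recipe.n_fibers, recipe.fiber_length_px)
    widths = np.full(recipe.n_fibers, recipe.fiber_width_px)
    for ch, amp in recipe.fiber_channel_amps.items():
        _render_fibers(channels[ch], fx, fy, angles, lengths, widths, np.full(recipe.n_fibers, amp))
    truth_fibers = pd.DataFrame(
        {"x_px": fx, "y_px": fy, "angle_deg": angles, "length_px": lengths, "width_px": widths}
    )

    # background gradient (random direction) + noise, per channel
    rows = np.arange(size)[:, None] / max(size - 1, 1)
    cols = np.arange(size)[None, :] / max(size - 1, 1)
    for ch in channels:
        phi = rng.uniform(0.0, 2.0 * math.pi)
        grad = recipe.background_gradient * (
            (cols - 0.5) * math.cos(phi) + (rows - 0.5) * math.sin(phi)
        )
        img = channels[ch] + recipe.background_level + grad
        if recipe.noise_poisson:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if recipe.noise_gaussian_sd > 0:
            img = img + rng.normal(0.0, recipe.noise_gaussian_sd, size=img.shape)
        channels[ch] = img
        if np.mean(img >= 0.95 * img.max()) > 0.95:
            import warnings

            warnings.warn(f"channel {ch!r} is >95% saturated", stacklevel=2)

    return channels, {"nuclei": truth_nuclei, "fibers": truth_fibers}


# ---------------------------------------------------------------------------
# Growth series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthRecipe:
    """A colony expanding radially at constant speed from a central droplet."""

    initial_radius_mm: float = 1.0
    speed_mm_per_day: float = 0.35
    days: tuple[float, ...] = (3.0, 6.0, 9.0)
    well_radius_mm: float = 4.0
    pixel_size_um: float = 5.0
    nuclei_density_per_mm2: float = 500.0
    nucleus_radius_um: float = 7.0
    nucleus_amp: float = 100.0
    noise_gaussian_sd: float = 1.0
    seed: int = 0
    render_nuclei: bool = False


def make_growth_series(recipe: GrowthRecipe):
    """Generate per-day colony data with analytic truth areas.

    Returns ``(masks, nuclei_images, truth)``: binary colony masks per
    day, nuclei-channel images (``None`` entries unless
    ``render_nuclei``), and a DataFrame with the programmed radius
    (clipped to the well) and truth area ``pi * min(r, a)^2`` per day.
    """
    rng = np.random.default_rng(recipe.seed)
    a = recipe.well_radius_mm
    px_mm = recipe.pixel_size_um * 1e-3
    size = int(round(2.0 * a / px_mm))
    c = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    r_px_sq = (yy - c) ** 2 + (xx - c) ** 2

    masks, nuclei_imgs, rows = [], [], []
    for day in recipe.days:
        r_t = recipe.initial_radius_mm + recipe.speed_mm_per_day * day
        r_clip = min(r_t, a)
        masks.append(r_px_sq <= (r_clip / px_mm) ** 2)
        rows.append(
            {
                "day": day,
                "radius_mm": r_clip,
                "clipped": r_t > a,
                "area_mm2": math.pi * r_clip**2,
            }
        )
        if recipe.render_nuclei:
            area = math.pi * r_clip**2
            n = rng.poisson(recipe.nuclei_density_per_mm2 * area)
            rads = np.sqrt(rng.uniform(0.0, r_clip**2, size=n)) / px_mm
            phis = rng.uniform(0.0, 2.0 * math.pi, size=n)
            nx = c + rads * np.cos(phis)
            ny = -(c) + rads * np.sin(phis)  # math frame: y = -row
            img = np.zeros((size, size))
            rpx = recipe.nucleus_radius_um / recipe.pixel_size_um
            _render_blobs(img, nx, ny, np.full(n, rpx), np.full(n, recipe.nucleus_amp))
            if recipe.noise_gaussian_sd > 0:
                img += rng.normal(0.0, recipe.noise_gaussian_sd, size=img.shape)
            nuclei_imgs.append(img)
        else:
            nuclei_imgs.append(None)
    return masks, nuclei_imgs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtRecipe:
    """Programmed fold changes for a synthetic qPCR experiment.

    ``fold_changes`` maps ``(cell_type, condition, gene) -> true fold``
    relative to the reference condition; the reference stratum (fold 1)
    is added automatically for every (cell_type, gene).  Target Ct is
    ``baseline_ct - log2(fold) + N(0, sd)``; the housekeeping gene reads
    ``housekeeping_ct + N(0, sd)`` in every sample.
    """

    fold_changes: dict = field(
        default_factory=lambda: {("keratocyte", "high", "ACTA2"): 10.0}
    )
    baseline_ct: float = 26.0
    housekeeping_ct: float = 18.0
    housekeeping_gene: str = "GAPDH"
    reference_condition: str = "flat"
    noise_sd: float = 0.2
    n_replicates: int = 3
    seed: int = 0


def make_ct_table(recipe: CtRecipe) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format Ct table plus its truth table.

    Returns ``(table, truth)``: the table has columns ``sample_id,
    cell_type, condition, gene, ct`` (housekeeping rows included for
    every sample); the truth lists the programmed fold per stratum.
    """
    rng = np.random.default_rng(recipe.seed)
    strata = dict(recipe.fold_changes)
    for cell_type, _cond, gene in list(strata):
        strata.setdefault((cell_type, recipe.reference_condition, gene), 1.0)

    rows = []
    samples = {}  # (cell_type, condition, replicate) -> sample_id
    for (cell_type, condition, gene), fold in sorted(strata.items()):
        for rep in range(recipe.n_replicates):
            key = (cell_type, condition, rep)
            if key not in samples:
                samples[key] = f"{cell_type}-{condition}-r{rep + 1}"
            ct = recipe.baseline_ct - math.log2(fold) + rng.normal(0.0, recipe.noise_sd)
            rows.append(
                {
                    "sample_id": samples[key],
                    "cell_type": cell_type,
                    "condition": condition,
                    "gene": gene,
                    "ct": ct,
                }
            )
    # one housekeeping measurement per sample
    for (cell_type, condition, _rep), sid in sorted(samples.items(), key=lambda kv: kv[1]):
        rows.append(
            {
                "sample_id": sid,
                "cell_type": cell_type,
                "condition": condition,
                "gene": recipe.housekeeping_gene,
                "ct": recipe.housekeeping_ct + rng.normal(0.0, recipe.noise_sd),
            }
        )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {"cell_type": ct_, "condition": cond, "gene": g, "true_fold": f}
            for (ct_, cond, g), f in sorted(strata.items())
        ]
    )
    return table, truth


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------


def stripe_image(
    size_px: int = 256, angle_deg: float = 0.0, period_px: float = 12.0, amplitude: float = 100.0
) -> np.ndarray:
    """Sinusoidal parallel stripes oriented at ``angle_deg`` (math frame)."""
    th = math.radians(angle_deg)
    rows = np.arange(size_px)[:, None].astype(float)
    cols = np.arange(size_px)[None, :].astype(float)
    x, y = cols, -rows
    phase = 2.0 * math.pi * (-(x * math.sin(th)) + y * math.cos(th)) / period_px
    return amplitude * (0.5 + 0.5 * np.sin(phase))


def make_label_ellipses(
    n: int = 100,
    mu_deg: float = 0.0,
    kappa: float = 8.0,
    aspect: float = 3.0,
    major_px: float = 20.0,
    seed: int = 0,
    model: str = "vonmises",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label image of non-overlapping ellipses at sampled axial angles.

    Ellipses are placed on a jittered grid so labels never merge; the
    truth table gives each object's angle and aspect ratio.  Useful as a
    ground-truth fixture for per-cell elongation-axis measurement.
    """
    rng = np.random.default_rng(seed)
    cell = int(math.ceil(2.2 * major_px))
    per_side = int(math.ceil(math.sqrt(n)))
    size = per_side * cell
    labels = np.zeros((size, size), dtype=int)
    angles = sample_axial_angles(n, rng, model=model, mu_deg=mu_deg, kappa=kappa)
    semi_major, semi_minor = major_px / 2.0, major_px / (2.0 * aspect)
    rows_out = []
    k = 0
    for gi in range(per_side):
        for gj in range(per_side):
            if k >= n:
                break
            x0 = gj * cell + cell / 2.0 + rng.uniform(-2, 2)
            y0 = -(gi * cell + cell / 2.0 + rng.uniform(-2, 2))
            th = math.radians(angles[k])
            ct, st = math.cos(th), math.sin(th)
            r0, r1 = gi * cell, (gi + 1) * cell
            c0, c1 = gj * cell, (gj + 1) * cell
            dx = np.arange(c0, c1)[None, :] - x0
            dy = (-np.arange(r0, r1)[:, None]) - y0
            u = dx * ct + dy * st
            v = -dx * st + dy * ct
            inside = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
            labels[r0:r1, c0:c1][inside] = k + 1
            rows_out.append(
                {"cell_id": k + 1, "angle_deg": angles[k], "aspect_ratio": aspect}
            )
            k += 1
    return labels, pd.DataFrame(rows_out)
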