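"""Per-spot intensity extraction and the eight quality flags.

The measurement disc is the 21-pixel circle of 250 μm diameter around the
(refined) spot center; local background is the median over a square window
around the center with a 275 μm exclusion circle, large artifacts and
overly large spots masked out.  Net intensity = disc mean - background
median, log2-transformed when positive.

Seven component flags mark unreliable spots (artifact, overshine, KS,
no-contrast, saturated, shape, position); the overall flag is their OR.
Flagged spots are excluded from every normalization step downstream, never
repaired or imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

from .imaging import (
    SATURATION_LEVEL,
    EnhancedImage,
    GridGeometry,
    PhosphorImage,
    auto_rotate,
    enhance,
    fit_slide_grid,
    reverse_transform,
)
from .layout import ArrayLayout
from .spots import FLAG_NAMES, SpotTable

__all__ = ["QuantifyParams", "refine_center", "quantify_spot", "flag_spot",
           "artifact_mask", "quantify_image"]


@dataclass(frozen=True)
class QuantifyParams:
    """Geometry and thresholds of quantification and flagging (μm unless noted)."""

    disc_diameter: float = 250.0          # 21 px measurement disc at 50 μm/px
    refine_range: float = 100.0           # center refinement range (2 px)
    bg_halfwidth: float = 275.0           # half of the 550 μm background square
    bg_exclusion_radius: float = 275.0    # inscribed circle excluded from background
    min_bg_pixels: int = 10
    saturation_level: float = SATURATION_LEVEL
    saturation_count: int = 3             # "more than 3 of the 21 spot pixels"
    ks_alpha: float = 0.01
    shape_window: float = 500.0           # 12 x 12 px analysis window
    shape_threshold_percentile: float = 80.0
    aspect_bright: float = 1.6            # applies when net_log2 > 8
    aspect_weak: float = 2.0
    bright_log2: float = 8.0
    position_tolerance: float = 100.0     # user-configurable
    position_brightest_fraction: float = 0.20
    overshine_sd_mult: float = 3.0
    artifact_coverage: float = 0.30       # window fraction covered by an artifact
    artifact_min_area_factor: float = 2.0   # x disc area, for elongated objects
    artifact_max_spot_area_px: int = 200    # larger than any credible single spot
    oversize_area_factor: float = 4.0       # x disc area -> excluded from bg


def _disc_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius_px))
    dy, dx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    keep = dx ** 2 + dy ** 2 <= radius_px ** 2
    return dx[keep], dy[keep]


def _window(img: np.ndarray, cx: int, cy: int, half: int) -> np.ndarray:
    return img[max(cy - half, 0):cy + half + 1, max(cx - half, 0):cx + half + 1]


def refine_center(image: PhosphorImage, nominal: tuple[float, float],
                  params: QuantifyParams = QuantifyParams()) -> tuple[int, int]:
    """Integer-pixel center within ±2 px of nominal maximizing disc mean."""
    dx_off, dy_off = _disc_offsets((params.disc_diameter / 2.0) / image.pixel_pitch)
    cx0, cy0 = int(round(nominal[0])), int(round(nominal[1]))
    rng = int(round(params.refine_range / image.pixel_pitch))
    h, w = image.pixels.shape
    best, best_c = -np.inf, (cx0, cy0)
    for dy in range(-rng, rng + 1):
        for dx in range(-rng, rng + 1):
            cx, cy = cx0 + dx, cy0 + dy
            xs, ys = cx + dx_off, cy + dy_off
            if xs.min() < 0 or ys.min() < 0 or xs.max() >= w or ys.max() >= h:
                continue
            m = image.pixels[ys, xs].mean()
            if m > best:
                best, best_c = m, (cx, cy)
    return best_c


def artifact_mask(image: PhosphorImage, params: QuantifyParams = QuantifyParams(),
                  threshold_percentile: float = 87.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Masks of artifact pixels and of oversized-spot pixels.

    Connected components above the global threshold count as artifacts when
    they are elongated (aspect > 1.6) and larger than twice the measurement
    disc, or larger than any credible single spot.  Components merely
    oversized (4x disc) are not flagged but are excluded from background
    estimation.
    """
    disc_area = len(_disc_offsets((params.disc_diameter / 2.0) / image.pixel_pitch)[0])
    thr = np.percentile(image.pixels, threshold_percentile)
    labels = measure.label(image.pixels > thr)
    art = np.zeros(image.pixels.shape, dtype=bool)
    oversize = np.zeros(image.pixels.shape, dtype=bool)
    for prop in measure.regionprops(labels):
        is_big = prop.area > params.artifact_max_spot_area_px
        minor = prop.axis_minor_length
        aspect = prop.axis_major_length / minor if minor > 0 else np.inf
        elongated = (aspect > params.aspect_bright
                     and prop.area > params.artifact_min_area_factor * disc_area)
        ys, xs = prop.coords[:, 0], prop.coords[:, 1]
        if is_big or elongated:
            art[ys, xs] = True
        elif prop.area > params.oversize_area_factor * disc_area:
            oversize[ys, xs] = True
    return art, oversize


def quantify_spot(image: PhosphorImage, center: tuple[int, int],
                  params: QuantifyParams = QuantifyParams(),
                  exclusions: np.ndarray | None = None) -> tuple[float, dict]:
    """Net log2 intensity of one spot plus its raw components.

    Returns ``(net_log2, components)``; net_log2 is NaN when net <= 0 (the
    no-contrast condition) or when fewer than ``min_bg_pixels`` background
    pixels survive the exclusions (the spot is then an artifact candidate).
    """
    px = image.pixels
    h, w = px.shape
    pitch = image.pixel_pitch
    cx, cy = int(round(center[0])), int(round(center[1]))
    dx_off, dy_off = _disc_offsets((params.disc_diameter / 2.0) / pitch)
    xs, ys = np.clip(cx + dx_off, 0, w - 1), np.clip(cy + dy_off, 0, h - 1)
    disc_vals = px[ys, xs]

    # floor: 275 μm at 50 μm/px -> ±5 px, an 11 x 11 = 550 μm window
    half = int(params.bg_halfwidth / pitch)
    gy, gx = np.meshgrid(np.arange(cy - half, cy + half + 1),
                         np.arange(cx - half, cx + half + 1), indexing="ij")
    inb = (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h)
    dist2 = (gx - cx) ** 2 + (gy - cy) ** 2
    ring = inb & (dist2 > (params.bg_exclusion_radius / pitch) ** 2)
    bgx, bgy = gx[ring], gy[ring]
    if exclusions is not None:
        keep = ~exclusions[bgy, bgx]
        bgx, bgy = bgx[keep], bgy[keep]
    bg_vals = px[bgy, bgx]

    comps = {
        "disc_vals": disc_vals,
        "bg_vals": bg_vals,
        "mean": float(disc_vals.mean()),
        "bg_median": float(np.median(bg_vals)) if bg_vals.size else np.nan,
        "bg_sd": float(bg_vals.std(ddof=1)) if bg_vals.size > 1 else np.nan,
        "bg_n": int(bg_vals.size),
        "bg_failed": bg_vals.size < params.min_bg_pixels,
    }
    if comps["bg_failed"]:
        comps["net"] = np.nan
        return np.nan, comps
    net = comps["mean"] - comps["bg_median"]
    comps["net"] = net
    return (float(np.log2(net)) if net > 0 else np.nan), comps


def _shape_and_position(image, enhanced, center, net_log2, comps, params):
    """Shape (roundness) and position (centroid offset) flags."""
    pitch = image.pixel_pitch
    cx, cy = int(round(center[0])), int(round(center[1]))
    half = max(1, int(round(params.shape_window / 2.0 / pitch)))
    win = _window(image.pixels, cx, cy, half)
    if win.size == 0:
        return 1, 1  # conservatively unreliable
    thr = np.percentile(win, params.shape_threshold_percentile)
    mask = win >= thr  # >= so plateaus of equal-valued object pixels survive
    shape_flag = 0
    labels = measure.label(mask)
    if labels.max() > 0:
        # component closest to the window center carries the spot
        props = measure.regionprops(labels, intensity_image=win)
        ctr = np.array([min(cy, half), min(cx, half)], dtype=float)
        main = min(props, key=lambda p: np.hypot(*(np.array(p.centroid) - ctr)))
        minor = main.axis_minor_length
        aspect = main.axis_major_length / minor if minor > 0 else np.inf
        limit = (params.aspect_bright if (np.isfinite(net_log2) and net_log2 > params.bright_log2)
                 else params.aspect_weak)
        shape_flag = int(aspect > limit)
    # position: intensity-weighted centroid of the 20% brightest window pixels
    k = max(1, int(round(params.position_brightest_fraction * win.size)))
    flat = win.ravel()
    idx = np.argpartition(flat, -k)[-k:]
    yy, xx = np.unravel_index(idx, win.shape)
    wsum = flat[idx].sum()
    if wsum <= 0:
        return shape_flag, 1
    cyw = (yy * flat[idx]).sum() / wsum
    cxw = (xx * flat[idx]).sum() / wsum
    dist_um = np.hypot(cxw - min(cx, half), cyw - min(cy, half)) * pitch
    return shape_flag, int(dist_um > params.position_tolerance)


def flag_spot(image: PhosphorImage, enhanced: EnhancedImage | None,
              center: tuple[int, int], net_log2: float, comps: dict,
              neighbors: list[tuple[tuple[float, float], float]] = (),
              params: QuantifyParams = QuantifyParams(),
              art_mask: np.ndarray | None = None) -> dict:
    """Compute the seven component flags for one quantified spot.

    ``neighbors`` lists ``((x_px, y_px), net_log2)`` of adjacent spots, used
    for the overshine test.  Missing inputs set the corresponding flag
    conservatively to 1.
    """
    pitch = image.pixel_pitch
    cx, cy = int(round(center[0])), int(round(center[1]))
    flags = dict.fromkeys(FLAG_NAMES, 0)

    disc_vals, bg_vals = comps["disc_vals"], comps["bg_vals"]

    # Artifact: failed background, or a large artifact object shadowing the
    # spot's neighbourhood (>30% of the background window or of the disc).
    if comps["bg_failed"]:
        flags["artifact"] = 1
    elif art_mask is not None:
        half = int(params.bg_halfwidth / pitch)
        win = _window(art_mask, cx, cy, half)
        dx_off, dy_off = _disc_offsets((params.disc_diameter / 2.0) / pitch)
        h, w = art_mask.shape
        xs = np.clip(cx + dx_off, 0, w - 1)
        ys = np.clip(cy + dy_off, 0, h - 1)
        if win.mean() > params.artifact_coverage or art_mask[ys, xs].mean() > params.artifact_coverage:
            flags["artifact"] = 1

    # Saturated: more than saturation_count of the 21 disc pixels above the
    # reverse-transformed saturation level.
    flags["saturated"] = int((disc_vals > params.saturation_level).sum()
                             > params.saturation_count)

    # KS: spot indistinguishable from local background (off-spot marker).
    if bg_vals.size >= 2:
        p_ks = stats.ks_2samp(disc_vals, bg_vals, method="asymp").pvalue
        flags["ks"] = int(p_ks >= params.ks_alpha)
    else:
        flags["ks"] = 1

    # No contrast: non-positive net intensity, or an enhanced response that
    # is negative over the whole disc.
    no_contrast = (not np.isfinite(net_log2)) and not comps["bg_failed"]
    if enhanced is not None and not no_contrast:
        dx_off, dy_off = _disc_offsets((params.disc_diameter / 2.0) / pitch)
        eh, ew = enhanced.pixels.shape
        evals = enhanced.pixels[np.clip(cy + dy_off, 0, eh - 1),
                                np.clip(cx + dx_off, 0, ew - 1)]
        no_contrast = bool((evals < 0).all())
    flags["no_contrast"] = int(no_contrast)

    # Overshine: a bright neighbour whose intensity decreases monotonically
    # into this spot's area, while the disc mean exceeds background + 3 SD.
    if neighbors and np.isfinite(comps.get("bg_sd", np.nan)):
        above = comps["mean"] > comps["bg_median"] + params.overshine_sd_mult * comps["bg_sd"]
        if above:
            h, w = image.pixels.shape
            for (nx, ny), n_net in neighbors:
                if not (np.isfinite(n_net) and n_net > params.bright_log2):
                    continue
                # sample 5 points from the midpoint toward this spot's center
                mx, my = (nx + cx) / 2.0, (ny + cy) / 2.0
                ts = np.linspace(0.0, 1.0, 5)
                sx = np.clip(np.round(mx + (cx - mx) * ts).astype(int), 0, w - 1)
                sy = np.clip(np.round(my + (cy - my) * ts).astype(int), 0, h - 1)
                prof = image.pixels[sy, sx]
                if np.all(np.diff(prof) <= 0):
                    flags["overshine"] = 1
                    break

    # Shape / position need a detectable object: only meaningful when the
    # spot has positive net signal (off-spots are covered by ks/no-contrast).
    if np.isfinite(net_log2):
        flags["shape"], flags["position"] = _shape_and_position(
            image, enhanced, center, net_log2, comps, params)
    return flags


def quantify_image(
    image: PhosphorImage,
    layout: ArrayLayout,
    bounds: tuple[float, float, float, float] | None = None,
    params: QuantifyParams = QuantifyParams(),
    geometry: GridGeometry | None = None,
    slide_id: str = "slide",
    condition: str = "",
    rotate: bool = True,
) -> SpotTable:
    """Full slide driver: enhance, grid, refine, quantify and flag every spot.

    ``bounds`` (pixel rectangle of the spotted area) replaces the original
    interactive boundary clicks; alternatively a pre-fitted ``geometry``
    may be supplied.  Quantification reads the reverse-transformed image;
    the enhanced image is used only for gridding and flags.
    """
    if image.transform_state == "raw":
        image = reverse_transform(image)
    enh = enhance(image, layout)
    angle = 0.0
    if geometry is None:
        if rotate:
            enh_rot, angle = auto_rotate(enh)
            if abs(angle) > 0.05:  # avoid interpolation blur for aligned slides
                from scipy import ndimage as ndi

                image = PhosphorImage(
                    np.clip(ndi.rotate(image.pixels, angle, reshape=False, order=1), 0, None),
                    image.pixel_pitch, image.transform_state)
                enh = enh_rot
        if bounds is None:
            raise ValueError("either bounds or a fitted geometry is required")
        geometry = fit_slide_grid(enh, bounds, layout, rotation_angle=angle)

    art, oversize = artifact_mask(image, params)
    bg_excl = art | oversize

    shape = (layout.n_sets, layout.set_rows, layout.set_cols)
    values = np.full(shape, np.nan)
    flags = {name: np.zeros(shape, dtype=bool) for name in FLAG_NAMES}
    centers = np.empty(shape + (2,), dtype=int)
    comps_all = np.empty(shape, dtype=object)

    for s in range(layout.n_sets):
        for r in range(layout.set_rows):
            for c in range(layout.set_cols):
                ctr = refine_center(image, tuple(geometry.centers_px[s, r, c]), params)
                centers[s, r, c] = ctr
                v, comps = quantify_spot(image, ctr, params, exclusions=bg_excl)
                values[s, r, c] = v
                comps_all[s, r, c] = comps

    for s in range(layout.n_sets):
        for r in range(layout.set_rows):
            for c in range(layout.set_cols):
                neigh = []
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < layout.set_rows and 0 <= cc < layout.set_cols:
                            neigh.append((tuple(centers[s, rr, cc].astype(float)),
                                          values[s, rr, cc]))
                f = flag_spot(image, enh, tuple(centers[s, r, c]), values[s, r, c],
                              comps_all[s, r, c], neigh, params, art)
                for name in FLAG_NAMES:
                    flags[name][s, r, c] = bool(f[name])

    return SpotTable(layout, values, flags, slide_id=slide_id, condition=condition)
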