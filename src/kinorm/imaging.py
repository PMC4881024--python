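"""Phosphorimager image model, enhancement, gridding and synthetic rendering.

The scanner stores a square-root-compressed 16-bit image; analysis starts
by reversing that compression (``I = raw^2 / TF``, TF = 42752), after which
pixel values are proportional to deposited radioactivity and saturate near
95000.  A matched-filter enhancement chain (median filter, negated
Laplacian-of-Gaussian at the spot scale, morphological opening, final
smoothing) produces an image used exclusively for gridding and quality
control; intensity quantification always reads the reverse-transformed raw
image.

The synthetic renderer is the fixture generator for the whole pipeline: it
draws each spot as a 2-D Gaussian (FWHM ~ spot diameter) on a noisy
background, adds stripe/blemish artifacts on request, and applies the
forward square-root compression so that rendered TIFFs behave like scanner
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import morphology

from .layout import ArrayLayout, SpotAddress

__all__ = [
    "PhosphorImage",
    "TransformSpec",
    "EnhancedImage",
    "GridGeometry",
    "TransformStateError",
    "GeometryError",
    "reverse_transform",
    "forward_transform",
    "enhance",
    "auto_rotate",
    "locate_blocks",
    "fit_grid",
    "fit_slide_grid",
    "ArtifactSpec",
    "generate_synthetic_image",
    "nominal_bounds",
    "read_tiff",
    "write_tiff",
]

SATURATION_LEVEL = 95000.0  # on the reverse-transformed scale


class TransformStateError(RuntimeError):
    """Operation applied to an image in the wrong transform state."""


class GeometryError(ValueError):
    """User-supplied bounds inconsistent with the array layout."""


@dataclass(frozen=True)
class TransformSpec:
    """Square-root compression factor of the scanner (default 42752)."""

    tf: float = 42752.0

    def __post_init__(self):
        if self.tf <= 0:
            raise ValueError("TF must be positive")


@dataclass
class PhosphorImage:
    """2-D nonnegative pixel intensities with a physical pixel pitch (μm)."""

    pixels: np.ndarray
    pixel_pitch: float = 50.0
    transform_state: str = "raw"  # or "reverse_transformed"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.transform_state == "raw" and self.pixels.size and self.pixels.max() > 65535:
            raise ValueError("raw pixel values exceed the 16-bit range")


@dataclass
class EnhancedImage:
    """Output of the enhancement chain; signed values are expected."""

    pixels: np.ndarray
    pixel_pitch: float
    provenance: dict = field(default_factory=dict)


def reverse_transform(image: PhosphorImage, spec: TransformSpec = TransformSpec()) -> PhosphorImage:
    """Undo the scanner's square-root compression: I = raw^2 / TF."""
    if image.transform_state != "raw":
        raise TransformStateError("image is already reverse-transformed")
    return PhosphorImage(image.pixels ** 2 / spec.tf, image.pixel_pitch,
                         "reverse_transformed")


def forward_transform(intensity: np.ndarray, spec: TransformSpec = TransformSpec()) -> np.ndarray:
    """Scanner-side compression: raw = sqrt(I * TF), clipped to 16 bit."""
    raw = np.sqrt(np.clip(intensity, 0, None) * spec.tf)
    return np.clip(np.rint(raw), 0, 65535)


# -------------------------------------------------------------- enhancement

def enhance(image: PhosphorImage, layout: ArrayLayout,
            median_size: int = 3, opening_radius_um: float = 50.0,
            final_sigma: float = 1.0) -> EnhancedImage:
    """Noise-suppressing, spot-matched enhancement chain.

    median filter -> negated Laplacian of Gaussian tuned to the spot radius
    -> grayscale opening removing structures below ~100 μm -> Gaussian
    smoothing.  Positive response marks round objects of roughly the right
    size; the result is used for gridding and QC only.
    """
    if image.transform_state != "reverse_transformed":
        raise TransformStateError("enhance expects a reverse-transformed image")
    if min(image.pixels.shape) < 2 * median_size + 1:
        raise ValueError("image smaller than the filter support")
    spot_radius_px = (layout.spot_diameter / 2.0) / image.pixel_pitch
    sigma = spot_radius_px / np.sqrt(2.0)  # LoG zero-crossing at the spot edge
    x = ndimage.median_filter(image.pixels, size=median_size)
    x = -ndimage.gaussian_laplace(x, sigma=sigma)
    open_r = max(1, int(round(opening_radius_um / image.pixel_pitch)))
    x = morphology.opening(x, morphology.disk(open_r))
    x = ndimage.gaussian_filter(x, sigma=final_sigma)
    return EnhancedImage(x, image.pixel_pitch, {
        "median_size": median_size, "log_sigma": sigma,
        "opening_radius_px": open_r, "final_sigma": final_sigma,
    })


def auto_rotate(enh: EnhancedImage, max_angle: float = 3.0,
                percentile: float = 87.0, step: float = 0.1
                ) -> tuple[EnhancedImage, float]:
    """Align spot columns vertically; returns the rotated image and angle.

    Thresholds the enhanced image at its 87th percentile and scans rotation
    angles in ``[-max_angle, +max_angle]`` (coarse 0.5°, then ``step``°),
    maximizing the variance of the column-sum profile: sharp column peaks
    mean vertical alignment.  An optimum at the bound is clamped with a
    warning.
    """
    thr = np.percentile(enh.pixels, percentile)
    binary = (enh.pixels > thr).astype(float)

    def score(angle: float) -> float:
        rot = ndimage.rotate(binary, angle, reshape=False, order=1)
        return float(np.var(rot.sum(axis=0)))

    coarse = np.arange(-max_angle, max_angle + 1e-9, 0.5)
    best = max(coarse, key=score)
    lo = max(-max_angle, best - 0.5)
    hi = min(max_angle, best + 0.5)
    fine = np.arange(lo, hi + 1e-9, step)
    best = float(max(fine, key=score))
    if abs(abs(best) - max_angle) < 1e-9:
        warnings.warn(f"rotation optimum at the +/-{max_angle} degree bound; clamped",
                      stacklevel=2)
    rotated = ndimage.rotate(enh.pixels, best, reshape=False, order=1)
    return EnhancedImage(rotated, enh.pixel_pitch,
                         {**enh.provenance, "rotation_deg": best}), best


# ----------------------------------------------------------------- gridding

@dataclass
class Block:
    """One pin block: its set/block indices and pixel-space rectangle."""

    set_index: int
    block_row: int
    block_col: int
    x0: float  # pixel coords of the block rectangle in the full image
    y0: float
    width: float
    height: float
    pixels: np.ndarray  # subimage (enhanced), cropped to the rectangle


@dataclass
class GridGeometry:
    """Fitted grid for a whole slide: per-spot centers in pixels and μm."""

    rotation_angle: float
    user_bounds: tuple[float, float, float, float]
    centers_px: np.ndarray  # (n_sets, set_rows, set_cols, 2) as (x, y)
    layout: ArrayLayout
    pixel_pitch: float

    def center_px(self, addr: SpotAddress) -> tuple[float, float]:
        x, y = self.centers_px[addr.set_index, addr.row, addr.col]
        return float(x), float(y)


def locate_blocks(enh: EnhancedImage, user_bounds: tuple[float, float, float, float],
                  layout: ArrayLayout, tolerance: float = 0.10) -> list[Block]:
    """Partition the user-indicated spot area into per-pin blocks.

    ``user_bounds`` is ``(x0, y0, x1, y1)`` in pixels enclosing the spotted
    area (outer spot edges).  The area is divided proportionally into
    ``n_sets * (set_rows/block) * (set_cols/block)`` block rectangles; bounds
    deviating more than ``tolerance`` from the layout's nominal size raise a
    geometry error.
    """
    x0, y0, x1, y1 = user_bounds
    if x1 <= x0 or y1 <= y0:
        raise GeometryError("empty bounds rectangle")
    pitch_px = layout.spot_pitch / enh.pixel_pitch
    nominal_w = layout.set_cols * pitch_px
    nominal_h = layout.total_rows * pitch_px
    w, h = x1 - x0, y1 - y0
    if abs(w - nominal_w) > tolerance * nominal_w or abs(h - nominal_h) > tolerance * nominal_h:
        raise GeometryError(
            f"bounds {w:.0f}x{h:.0f} px deviate more than {tolerance:.0%} from the "
            f"nominal {nominal_w:.0f}x{nominal_h:.0f} px spotted area")
    bpr = layout.set_rows // layout.block_size   # blocks per set, vertically
    bpc = layout.set_cols // layout.block_size
    blocks = []
    row_step = h / (layout.n_sets * bpr)
    col_step = w / bpc
    img = enh.pixels
    for s in range(layout.n_sets):
        for br in range(bpr):
            for bc in range(bpc):
                bx0 = x0 + bc * col_step
                by0 = y0 + (s * bpr + br) * row_step
                iy0, iy1 = int(np.floor(by0)), int(np.ceil(by0 + row_step))
                ix0, ix1 = int(np.floor(bx0)), int(np.ceil(bx0 + col_step))
                sub = img[max(iy0, 0):iy1, max(ix0, 0):ix1]
                blocks.append(Block(s, br, bc, bx0, by0, col_step, row_step, sub))
    return blocks


def _detect_round_objects(block: Block, layout: ArrayLayout, pixel_pitch: float):
    """Weighted centroids of round, spot-sized objects in one block.

    Bright objects (96th-percentile threshold) get weight 3, objects found
    only at the 85th-percentile threshold weight 1; non-round or wrongly
    sized components are discarded as artifacts.
    """
    from skimage import measure

    img = block.pixels
    spot_r_px = (layout.spot_diameter / 2.0) / pixel_pitch
    area_lo = 0.25 * np.pi * spot_r_px ** 2
    area_hi = 6.0 * np.pi * spot_r_px ** 2
    centroids, weights = [], []
    # percentile thresholds guarded against pure-noise blocks: a genuine
    # spot response must stand clear of the block's noise floor
    med = np.median(img)
    mad = np.median(np.abs(img - med)) or 1e-12
    bright_mask = img > max(np.percentile(img, 96), med + 6 * 1.4826 * mad)
    weak_mask = img > max(np.percentile(img, 85), med + 4 * 1.4826 * mad)
    bright_labels = measure.label(bright_mask)
    weak_labels = measure.label(weak_mask)
    seen_weak = set()
    for weight, labels in ((3.0, bright_labels), (1.0, weak_labels)):
        for prop in measure.regionprops(labels, intensity_image=img):
            if weight == 1.0:
                # a weak component containing a bright detection is the same spot
                ys, xs = prop.coords[:, 0], prop.coords[:, 1]
                if bright_mask[ys, xs].any():
                    continue
            if not (area_lo <= prop.area <= area_hi):
                continue
            minor = prop.axis_minor_length
            if minor > 0 and prop.axis_major_length / minor > 1.6:
                continue
            cy, cx = prop.centroid_weighted
            centroids.append((cx, cy))
            weights.append(weight)
    if not centroids:
        return np.empty((0, 2)), np.empty(0)
    return np.asarray(centroids, dtype=float), np.asarray(weights)


def fit_grid(block: Block, layout: ArrayLayout, pixel_pitch: float,
             trans_step: float = 0.25, scale_range: float = 0.05,
             match_radius_um: float = 125.0) -> np.ndarray:
    """Fit an ideal block grid to the detected round objects.

    Searches grid translation (±half a pitch, ``trans_step`` px steps) and
    pitch scale (±5%), scoring the summed weights of objects whose centroid
    falls within 125 μm of a grid node.  Returns the ``block_size x
    block_size x 2`` array of (x, y) centers in full-image pixel
    coordinates; with no detected objects the nominal grid is returned with
    a warning.
    """
    b = layout.block_size
    pitch_px = layout.spot_pitch / pixel_pitch
    # nominal node positions inside the block rectangle (centered)
    off_x = block.x0 + (block.width - (b - 1) * pitch_px) / 2.0
    off_y = block.y0 + (block.height - (b - 1) * pitch_px) / 2.0
    centroids, weights = _detect_round_objects(block, layout, pixel_pitch)
    nominal = _grid_nodes(off_x, off_y, pitch_px, b)
    if centroids.size == 0:
        warnings.warn("no objects detected in block; using the nominal grid",
                      stacklevel=2)
        return nominal
    # centroids are block-subimage coordinates; shift to full-image frame
    cx = centroids[:, 0] + np.floor(block.x0)
    cy = centroids[:, 1] + np.floor(block.y0)
    r_match = match_radius_um / pixel_pitch
    half = pitch_px / 2.0
    shifts = np.arange(-half, half + 1e-9, trans_step)
    scales = np.linspace(1 - scale_range, 1 + scale_range, 11)

    best = (-np.inf, 0.0, 0.0, 1.0)
    for scale in sorted(scales, key=lambda s: abs(s - 1.0)):  # ties favour scale 1
        step = pitch_px * scale
        ox = off_x + (pitch_px - step) * (b - 1) / 2.0  # keep the grid centered
        oy = off_y + (pitch_px - step) * (b - 1) / 2.0
        # wrap-around residual of each centroid to its nearest node, then
        # clip to the grid extent so outside objects do not contribute
        rx = cx[None, :] - ox - shifts[:, None]
        ry = cy[None, :] - oy - shifts[:, None]
        kx = np.clip(np.rint(rx / step), 0, b - 1)
        ky = np.clip(np.rint(ry / step), 0, b - 1)
        dx = rx - kx * step
        dy_all = ry - ky * step
        # score all (shift_x, shift_y) pairs: distance uses dx from shift_x
        # and dy from shift_y independently (separable by construction)
        d2x = dx ** 2  # (n_shifts, n_obj)
        d2y = dy_all ** 2
        within = (d2x[:, None, :] + d2y[None, :, :]) <= r_match ** 2
        scores = within @ weights  # (n_shifts_x, n_shifts_y)
        i, j = np.unravel_index(np.argmax(scores), scores.shape)
        if scores[i, j] > best[0]:
            best = (float(scores[i, j]), float(shifts[i]), float(shifts[j]), float(scale))
    _, sx, sy, scale = best
    step = pitch_px * scale
    ox = off_x + (pitch_px - step) * (b - 1) / 2.0 + sx
    oy = off_y + (pitch_px - step) * (b - 1) / 2.0 + sy
    # polish: weighted least-squares fit of translation AND pitch scale to
    # the matched centroids (the discrete search only resolves trans_step
    # and has score plateaus in scale)
    for _ in range(3):
        kx = np.clip(np.rint((cx - ox) / step), 0, b - 1)
        ky = np.clip(np.rint((cy - oy) / step), 0, b - 1)
        rx = cx - (ox + kx * step)
        ry = cy - (oy + ky * step)
        m = rx ** 2 + ry ** 2 <= r_match ** 2
        if m.sum() < 3:
            break
        w_m = weights[m]
        u, v = kx[m], ky[m]
        ubar = np.average(u, weights=w_m)
        vbar = np.average(v, weights=w_m)
        cxbar = np.average(cx[m], weights=w_m)
        cybar = np.average(cy[m], weights=w_m)
        denom = np.sum(w_m * ((u - ubar) ** 2 + (v - vbar) ** 2))
        if denom > 0:
            step_new = float(np.sum(w_m * ((u - ubar) * (cx[m] - cxbar)
                                           + (v - vbar) * (cy[m] - cybar))) / denom)
            # keep the refit inside a sane band around the nominal pitch
            step = float(np.clip(step_new, pitch_px * (1 - 2 * scale_range),
                                 pitch_px * (1 + 2 * scale_range)))
        ox = float(cxbar - step * ubar)
        oy = float(cybar - step * vbar)
    return _grid_nodes(ox, oy, step, b)


def _grid_nodes(ox: float, oy: float, step: float, b: int) -> np.ndarray:
    jj, ii = np.meshgrid(np.arange(b), np.arange(b), indexing="ij")
    out = np.empty((b, b, 2))
    out[..., 0] = ox + ii * step
    out[..., 1] = oy + jj * step
    return out


def fit_slide_grid(enh: EnhancedImage, user_bounds, layout: ArrayLayout,
                   rotation_angle: float = 0.0) -> GridGeometry:
    """Locate all pin blocks and fit each one; assemble per-spot centers."""
    blocks = locate_blocks(enh, user_bounds, layout)
    b = layout.block_size
    centers = np.empty((layout.n_sets, layout.set_rows, layout.set_cols, 2))
    for blk in blocks:
        nodes = fit_grid(blk, layout, enh.pixel_pitch)
        r0, c0 = blk.block_row * b, blk.block_col * b
        centers[blk.set_index, r0:r0 + b, c0:c0 + b] = nodes
    return GridGeometry(rotation_angle, tuple(user_bounds), centers, layout,
                        enh.pixel_pitch)


# ------------------------------------------------------------ synthetic data

@dataclass(frozen=True)
class ArtifactSpec:
    """Artifacts to inject into a rendered slide (transformed-intensity scale).

    stripes: (axis, position_um, width_um, intensity) with axis 'h' or 'v';
    blemishes: (x_um, y_um, radius_um, intensity);
    oversized: spot addresses rendered at twice the nominal diameter.
    """

    stripes: tuple = ()
    blemishes: tuple = ()
    oversized: tuple = ()


def nominal_bounds(layout: ArrayLayout, pixel_pitch: float = 50.0,
                   margin_px: float | None = None) -> tuple[float, float, float, float]:
    """Pixel bounds of the spotted area for a synthetically rendered slide."""
    pitch_px = layout.spot_pitch / pixel_pitch
    if margin_px is None:
        margin_px = 2.0 * pitch_px
    x0 = margin_px - pitch_px / 2.0
    y0 = margin_px - pitch_px / 2.0
    x1 = x0 + layout.set_cols * pitch_px
    y1 = y0 + layout.total_rows * pitch_px
    return (x0, y0, x1, y1)


def _disc_offsets(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    dy, dx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    keep = dx ** 2 + dy ** 2 <= radius_px ** 2
    return np.column_stack([dx[keep], dy[keep]])


def generate_synthetic_image(
    table,
    artifacts: ArtifactSpec = ArtifactSpec(),
    seed: int = 0,
    pixel_pitch: float = 50.0,
    background_mean: float = 100.0,
    background_sd: float = 10.0,
    edge_sigma_um: float = 75.0,
    center_jitter_um: float = 0.0,
    spec: TransformSpec = TransformSpec(),
) -> tuple[PhosphorImage, dict]:
    """Render a SpotTable to a raw (square-root-compressed) scanner image.

    Each spot with a finite net log2 intensity is drawn as a flat disc of
    the nominal spot diameter convolved with a Gaussian excitation spread
    (``edge_sigma_um``), giving the fuzzy boundary of real phosphor scans
    while keeping tails compact enough that neighbours stay separable.  The
    amplitude is set so that the mean over the 21-pixel measurement disc
    exceeds the background by exactly ``2**net_log2``.  Requested artifacts
    are added, then the forward transform and 16-bit quantization are
    applied.  Returns the image plus render info (bounds, clipped-pixel
    count, per-spot centers in px).
    """
    from scipy.special import erf

    layout = table.layout
    rng = np.random.default_rng(seed)
    pitch_px = layout.spot_pitch / pixel_pitch
    margin = 2.0 * pitch_px
    height = int(np.ceil(layout.total_rows * pitch_px + 2 * margin))
    width = int(np.ceil(layout.set_cols * pitch_px + 2 * margin))
    img = rng.normal(background_mean, background_sd, size=(height, width))
    np.clip(img, 0, None, out=img)

    spot_r_px = (layout.spot_diameter / 2.0) / pixel_pitch
    edge_sigma = edge_sigma_um / pixel_pitch

    def profile(d: np.ndarray, r: float) -> np.ndarray:
        # radial profile of a unit disc of radius r blurred by edge_sigma
        return 0.5 * (1.0 - erf((d - r) / (np.sqrt(2.0) * edge_sigma)))

    disc = _disc_offsets(spot_r_px)
    d_meas = np.hypot(disc[:, 0], disc[:, 1])
    disc_gain = float(profile(d_meas, spot_r_px).mean())

    half = int(np.ceil(2 * spot_r_px + 4 * edge_sigma))
    dyy, dxx = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1),
                           indexing="ij")
    oversized = {tuple(a) for a in artifacts.oversized}
    centers_px = np.empty((layout.n_sets, layout.set_rows, layout.set_cols, 2))
    for s in range(layout.n_sets):
        for r in range(layout.set_rows):
            for c in range(layout.set_cols):
                x_um, y_um = layout.spot_center(s, r, c)
                if center_jitter_um > 0:
                    # uniform over a disc of radius center_jitter_um
                    rho = center_jitter_um * np.sqrt(rng.uniform())
                    phi = rng.uniform(0, 2 * np.pi)
                    x_um += rho * np.cos(phi)
                    y_um += rho * np.sin(phi)
                px = margin + x_um / pixel_pitch
                py = margin + y_um / pixel_pitch
                centers_px[s, r, c] = (px, py)
                v = table.values[s, r, c]
                if not np.isfinite(v):
                    continue
                r_spot = spot_r_px * (2.0 if (s, r, c) in oversized else 1.0)
                amp = (2.0 ** v) / disc_gain
                ix, iy = int(round(px)), int(round(py))
                d = np.hypot(dxx + ix - px, dyy + iy - py)
                patch = amp * profile(d, r_spot)
                img[iy - half:iy + half + 1, ix - half:ix + half + 1] += patch

    for axis, pos_um, width_um, intensity in artifacts.stripes:
        p = int(round(margin + pos_um / pixel_pitch))
        wpx = max(1, int(round(width_um / pixel_pitch)))
        if axis == "h":
            img[p - wpx // 2:p - wpx // 2 + wpx, :] += intensity
        else:
            img[:, p - wpx // 2:p - wpx // 2 + wpx] += intensity
    for x_um, y_um, radius_um, intensity in artifacts.blemishes:
        cxp = margin + x_um / pixel_pitch
        cyp = margin + y_um / pixel_pitch
        rp = radius_um / pixel_pitch
        yy, xx = np.ogrid[:height, :width]
        img[(xx - cxp) ** 2 + (yy - cyp) ** 2 <= rp ** 2] += intensity

    raw = forward_transform(img, spec)
    n_clipped = int(np.sum(np.sqrt(img * spec.tf) > 65535))
    info = {
        "bounds": nominal_bounds(layout, pixel_pitch, margin),
        "centers_px": centers_px,
        "n_clipped": n_clipped,
        "margin_px": margin,
        "background_mean": background_mean,
        "background_sd": background_sd,
    }
    return PhosphorImage(raw, pixel_pitch, "raw"), info


# ------------------------------------------------------------------ file IO

def read_tiff(path, pixel_pitch: float = 50.0) -> PhosphorImage:
    import tifffile

    return PhosphorImage(tifffile.imread(path).astype(float), pixel_pitch, "raw")


def write_tiff(image: PhosphorImage, path) -> None:
    import tifffile

    if image.transform_state != "raw":
        raise TransformStateError("only raw (16-bit) images are written to TIFF")
    tifffile.imwrite(path, image.pixels.astype(np.uint16))
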