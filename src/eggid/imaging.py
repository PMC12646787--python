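"""Raw phenotype extraction from calibrated multichannel egg photographs.

An egg arrives as a set of co-registered reflectance rasters (red, green,
blue, ultraviolet and luminance, each scaled to [0, 1]) plus a boolean mask
of egg pixels and a pixel scale.  This module measures everything the
downstream trait PCA consumes:

* spot segmentation by Phansalkar local adaptive thresholding after a
  Gaussian flat-field correction,
* mean colour and brightness of spots and background,
* a ten-bin luminance histogram of the whole egg,
* a granularity spectrum (band-pass pattern energy and skewness) at twelve
  geometric scales over the whole egg and its blunt / middle / sharp thirds,
* spot size, coverage and longitudinal dispersion metrics,
* shape metrics (length, width, volume and surface of the solid of
  revolution, ellipse deviation, aspect ratio).

Images are expected at a common working scale (the study convention is
30 px/mm) with the long axis horizontal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from skimage import measure

logger = logging.getLogger("eggid")

CHANNELS = ("R", "G", "B", "UV", "LUM")

#: Geometric progression of pattern scales, as fractions of egg length:
#: (1/sqrt(2))**i for i = 0..11, i.e. 1 down to ~0.0221.
N_SCALES_DEFAULT = 12

#: Wavelength of peak response of a difference-of-Gaussians band-pass with
#: sigma ratio sqrt(2), in units of the smaller sigma: the DoG transfer
#: function exp(-2 pi^2 s^2 f^2) - exp(-4 pi^2 s^2 f^2) is maximal at
#: f* = sqrt(ln 2) / (sqrt(2) pi s), i.e. lambda* = s * sqrt(2) pi / sqrt(ln 2).
_DOG_PEAK_WAVELENGTH = np.sqrt(2.0) * np.pi / np.sqrt(np.log(2.0))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CalibratedEggImage:
    """A single egg as co-registered reflectance rasters.

    Parameters
    ----------
    channels:
        Mapping of channel name (``R, G, B, UV, LUM``) to a 2-D float raster
        of reflectance in [0, 1].  All rasters share one shape.
    mask:
        Boolean raster marking egg pixels (single connected component).
    scale:
        Pixels per millimetre (> 0).
    egg_id, clutch_id:
        Opaque identifiers.
    blunt_end:
        ``"left"`` or ``"right"``: which end of the horizontal long axis is
        the blunt pole.
    """

    channels: dict[str, np.ndarray]
    mask: np.ndarray
    scale: float
    egg_id: str = ""
    clutch_id: str = ""
    blunt_end: str = "left"

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1 or (
            self.channels and next(iter(shapes.values())) != self.mask.shape
        ):
            raise ValueError("channel rasters and mask must share dimensions")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.blunt_end not in ("left", "right"):
            raise ValueError("blunt_end must be 'left' or 'right'")
        self.mask = self.mask.astype(bool)

    def validate(self) -> None:
        """Check the full set of invariants (reflectance range, connectivity)."""
        for ch, a in self.channels.items():
            if a.min() < -1e-9 or a.max() > 1 + 1e-9:
                raise ValueError(f"channel {ch} outside [0, 1]")
        if not self.mask.any():
            raise ValueError("no egg pixels")
        _, n = ndimage.label(self.mask)
        if n != 1:
            raise ValueError("mask must be a single connected component")


@dataclass
class SpotSegmentation:
    """Result of spot detection inside the shrunken analysis mask."""

    spot_mask: np.ndarray
    components: list[int]  # pixel area of each connected spot region
    analysis_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.spot_mask & ~self.analysis_mask):
            raise ValueError("spot_mask must lie inside analysis_mask")
        if sum(self.components) != int(self.spot_mask.sum()):
            raise ValueError("component areas must sum to spot pixel count")

    @property
    def n_spots(self) -> int:
        return len(self.components)


@dataclass
class RegionPartition:
    """Whole-egg mask and its three thirds along the long axis."""

    whole: np.ndarray
    blunt: np.ndarray
    middle: np.ndarray
    sharp: np.ndarray

    def __post_init__(self) -> None:
        union = self.blunt | self.middle | self.sharp
        if not np.array_equal(union, self.whole):
            raise ValueError("thirds must cover the whole mask")
        overlap = (
            self.blunt.astype(int) + self.middle.astype(int) + self.sharp.astype(int)
        )
        if overlap.max() > 1:
            raise ValueError("thirds must be pairwise disjoint")

    def regions(self) -> dict[str, np.ndarray]:
        return {
            "whole": self.whole,
            "blunt": self.blunt,
            "middle": self.middle,
            "sharp": self.sharp,
        }


REGION_NAMES = ("whole", "blunt", "middle", "sharp")


@dataclass
class RawFeatureVector:
    """All measured quantities of one egg, pre-PCA."""

    colour: np.ndarray  # 10: mean R,G,B,UV,brightness x {spots, background}
    luminance_bins: np.ndarray  # 10 proportions, sum 1
    pattern_energy: np.ndarray  # n_scales x 4 regions
    pattern_skewness: np.ndarray  # n_scales x 4 regions
    spot_metrics: np.ndarray  # 5
    shape: np.ndarray  # 6
    egg_id: str = ""
    clutch_id: str = ""

    def __post_init__(self) -> None:
        if abs(float(self.luminance_bins.sum()) - 1.0) > 1e-9:
            raise ValueError("luminance bins must sum to 1")
        cov = float(self.spot_metrics[1])
        if not 0.0 <= cov <= 100.0:
            raise ValueError("coverage must be in [0, 100]")
        length, width = float(self.shape[0]), float(self.shape[1])
        if not (length >= width > 0):
            raise ValueError("length >= width > 0 required")
        if float(self.shape[2]) <= 0 or float(self.shape[3]) <= 0:
            raise ValueError("volume and surface must be positive")

    def as_dict(self) -> dict[str, float]:
        """Flatten into the documented CSV column layout."""
        out: dict[str, float] = {}
        for name, val in zip(colour_columns(), self.colour):
            out[name] = float(val)
        for i, val in enumerate(self.luminance_bins):
            out[f"lum_bin_{i + 1:02d}"] = float(val)
        n_scales = self.pattern_energy.shape[0]
        for i in range(n_scales):
            for j, reg in enumerate(REGION_NAMES):
                out[f"energy_s{i:02d}_{reg}"] = float(self.pattern_energy[i, j])
        for i in range(n_scales):
            for j, reg in enumerate(REGION_NAMES):
                out[f"skew_s{i:02d}_{reg}"] = float(self.pattern_skewness[i, j])
        for name, val in zip(spot_columns(), self.spot_metrics):
            out[name] = float(val)
        for name, val in zip(shape_columns(), self.shape):
            out[name] = float(val)
        return out


def colour_columns() -> list[str]:
    return [
        f"{part}_{ch}"
        for part in ("spot", "bg")
        for ch in ("R", "G", "B", "UV", "brightness")
    ]


def spot_columns() -> list[str]:
    return ["spot_area_mm2", "spot_coverage_pct", "disp_mean", "disp_sd", "disp_cv"]


def shape_columns() -> list[str]:
    return [
        "length_mm",
        "width_mm",
        "volume_mm3",
        "surface_mm2",
        "ellipse_dev",
        "aspect_ratio",
    ]


def feature_columns(n_scales: int = N_SCALES_DEFAULT) -> list[str]:
    """The full, ordered raw-feature CSV schema."""
    cols = colour_columns()
    cols += [f"lum_bin_{i + 1:02d}" for i in range(10)]
    cols += [
        f"energy_s{i:02d}_{reg}" for i in range(n_scales) for reg in REGION_NAMES
    ]
    cols += [f"skew_s{i:02d}_{reg}" for i in range(n_scales) for reg in REGION_NAMES]
    cols += spot_columns()
    cols += shape_columns()
    return cols


# ---------------------------------------------------------------------------
# Low-level filtering helpers
# ---------------------------------------------------------------------------


def _edge_normalised_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve with renormalisation at the borders (no dark-edge bias)."""
    num = signal.fftconvolve(img, kernel, mode="same")
    den = signal.fftconvolve(np.ones_like(img), kernel, mode="same")
    return num / np.maximum(den, 1e-12)


def _gaussian_kernel_2d(sigma: float, max_shape: tuple[int, int]) -> np.ndarray:
    # truncate at 3 sigma or the image extent, whichever is smaller
    ry = min(int(np.ceil(3 * sigma)), max_shape[0] - 1)
    rx = min(int(np.ceil(3 * sigma)), max_shape[1] - 1)
    y = np.arange(-ry, ry + 1)[:, None]
    x = np.arange(-rx, rx + 1)[None, :]
    k = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    return k / k.sum()


def _disk_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y <= r * r).astype(float)


# ---------------------------------------------------------------------------
# Illumination correction
# ---------------------------------------------------------------------------


def correct_illumination(
    img: CalibratedEggImage, blur_radius_px: int = 2048
) -> CalibratedEggImage:
    """Divide each channel by its Gaussian-blurred field.

    The blurred image estimates the smooth illumination component; dividing
    by it flattens gradients while preserving local reflectance ratios.  The
    result is rescaled so the within-mask mean of each channel is unchanged,
    then clipped to [0, 1].  The blur sigma is capped at half the smaller
    image dimension, so very large radii degrade gracefully on small crops.
    """
    if blur_radius_px < 1:
        raise ValueError("blur_radius_px must be >= 1")
    mask = img.mask
    if not mask.any():
        raise ValueError("no egg pixels")
    shape = mask.shape
    sigma = min(float(blur_radius_px), 0.5 * min(shape))
    kernel = _gaussian_kernel_2d(sigma, shape)
    out: dict[str, np.ndarray] = {}
    for ch, arr in img.channels.items():
        arr = np.asarray(arr, dtype=float)
        blurred = _edge_normalised_convolve(arr, kernel)
        ratio = arr / np.maximum(blurred, 1e-9)
        target_mean = float(arr[mask].mean())
        ratio_mean = float(ratio[mask].mean())
        corrected = ratio * (target_mean / max(ratio_mean, 1e-12))
        out[ch] = np.clip(corrected, 0.0, 1.0)
    return CalibratedEggImage(
        channels=out,
        mask=mask.copy(),
        scale=img.scale,
        egg_id=img.egg_id,
        clutch_id=img.clutch_id,
        blunt_end=img.blunt_end,
    )


# ---------------------------------------------------------------------------
# Mask shrinking and region partition
# ---------------------------------------------------------------------------


def shrink_mask(
    mask: np.ndarray, egg_width_px: float, fraction: float = 0.03
) -> np.ndarray:
    """Erode the egg mask by ``fraction`` of the egg width.

    The darker rim of an egg photograph produces spurious spot detections;
    trimming a 3 %-of-width margin removes it.  Erosion uses the Euclidean
    distance transform, equivalent to a disk structuring element.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    radius = int(round(fraction * egg_width_px))
    if radius <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask)
    eroded = dist > radius
    if not eroded.any():
        raise ValueError("egg too small for margin")
    return eroded


def egg_width_px(mask: np.ndarray) -> float:
    """Maximum vertical extent of the mask (long axis assumed horizontal)."""
    cols = np.asarray(mask, dtype=bool).sum(axis=0)
    return float(cols.max())


def partition_regions(mask: np.ndarray, blunt_end: str = "left") -> RegionPartition:
    """Split the egg mask into blunt / middle / sharp thirds along the long axis."""
    mask = np.asarray(mask, dtype=bool)
    xs = np.where(mask.any(axis=0))[0]
    if xs.size == 0:
        raise ValueError("mask is empty")
    x0, x1 = xs[0], xs[-1]
    # column index boundaries at thirds of the x-extent
    b1 = x0 + (x1 - x0 + 1) / 3.0
    b2 = x0 + 2.0 * (x1 - x0 + 1) / 3.0
    col = np.arange(mask.shape[1])[None, :]
    left = mask & (col < b1)
    mid = mask & (col >= b1) & (col < b2)
    right = mask & (col >= b2)
    if blunt_end == "left":
        blunt, sharp = left, right
    else:
        blunt, sharp = right, left
    return RegionPartition(whole=mask, blunt=blunt, middle=mid, sharp=sharp)


def detect_blunt_end(mask: np.ndarray) -> str:
    """Heuristic orientation: the blunt pole is the wider half.

    Convenience only — supply the true orientation in metadata whenever it is
    known; the heuristic fails on nearly symmetric eggs.
    """
    mask = np.asarray(mask, dtype=bool)
    xs = np.where(mask.any(axis=0))[0]
    cx = (xs[0] + xs[-1]) / 2.0
    col = np.arange(mask.shape[1])[None, :]
    left_area = int((mask & (col < cx)).sum())
    right_area = int((mask & (col >= cx)).sum())
    return "left" if left_area >= right_area else "right"


# ---------------------------------------------------------------------------
# Spot segmentation (Phansalkar local thresholding)
# ---------------------------------------------------------------------------


def phansalkar_threshold(
    lum: np.ndarray,
    radius_px: int = 50,
    k: float = 0.25,
    p: float = 2.0,
    q: float = 10.0,
    r_norm: float = 0.5,
) -> np.ndarray:
    """Per-pixel Phansalkar threshold surface.

    T = m * (1 + p * exp(-q * m) + k * ((s / r_norm) - 1)) with m, s the
    local mean and standard deviation in a disk neighbourhood of
    ``radius_px``.  Designed for low-contrast stained objects; the
    exponential term keeps dark regions from dissolving into noise.
    """
    lum = np.asarray(lum, dtype=float)
    kernel = _disk_kernel(radius_px)
    m = _edge_normalised_convolve(lum, kernel)
    e2 = _edge_normalised_convolve(lum * lum, kernel)
    s = np.sqrt(np.maximum(e2 - m * m, 0.0))
    return m * (1.0 + p * np.exp(-q * m) + k * ((s / r_norm) - 1.0))


def segment_spots(
    img: CalibratedEggImage,
    analysis_mask: np.ndarray | None = None,
    radius_px: int = 50,
    k: float = 0.25,
    p: float = 2.0,
    q: float = 10.0,
    r_norm: float = 0.5,
    shrink_fraction: float = 0.03,
) -> SpotSegmentation:
    """Detect dark maculation inside the (shrunken) egg mask.

    Pixels whose luminance falls below the local Phansalkar threshold are
    spots; connected components use 8-connectivity.  Zero spots is a valid
    outcome (immaculate egg).
    """
    if analysis_mask is None:
        analysis_mask = shrink_mask(img.mask, egg_width_px(img.mask), shrink_fraction)
    lum = np.asarray(img.channels["LUM"], dtype=float)
    thresh = phansalkar_threshold(lum, radius_px=radius_px, k=k, p=p, q=q, r_norm=r_norm)
    spot_mask = (lum < thresh) & analysis_mask
    labels = measure.label(spot_mask, connectivity=2)
    areas = np.bincount(labels.ravel())[1:].tolist() if labels.max() else []
    return SpotSegmentation(
        spot_mask=spot_mask,
        components=[int(a) for a in areas],
        analysis_mask=np.asarray(analysis_mask, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Colour and luminance statistics
# ---------------------------------------------------------------------------


def colour_stats(img: CalibratedEggImage, seg: SpotSegmentation) -> np.ndarray:
    """Mean R, G, B, UV and brightness over spots and over background.

    Background = analysis mask minus spots.  A spotless egg gets its spot
    means set equal to the background means (with a logged warning) so the
    downstream PCA never sees missing values.
    """
    bg_mask = seg.analysis_mask & ~seg.spot_mask
    if not bg_mask.any():
        raise ValueError("background region is empty")
    order = ("R", "G", "B", "UV", "LUM")
    bg = np.array([float(img.channels[ch][bg_mask].mean()) for ch in order])
    if seg.spot_mask.any():
        sp = np.array([float(img.channels[ch][seg.spot_mask].mean()) for ch in order])
    else:
        logger.warning("egg %s has no spots; spot colour set to background", img.egg_id)
        sp = bg.copy()
    return np.concatenate([sp, bg])


def luminance_histogram(img: CalibratedEggImage) -> np.ndarray:
    """Proportion of whole-egg pixels in ten luminance bins [0,0.1)...[0.9,1.0]."""
    mask = img.mask
    if not mask.any():
        raise ValueError("no egg pixels")
    vals = np.asarray(img.channels["LUM"], dtype=float)[mask]
    idx = np.minimum((vals * 10).astype(int), 9)  # last bin closed
    counts = np.bincount(idx, minlength=10).astype(float)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Granularity spectrum
# ---------------------------------------------------------------------------


def pattern_scales(n_scales: int = N_SCALES_DEFAULT) -> np.ndarray:
    """Scale fractions (1/sqrt(2))**i, i = 0..n_scales-1 (1 down to ~0.0221)."""
    return (1.0 / np.sqrt(2.0)) ** np.arange(n_scales)


def granularity_spectrum(
    img: CalibratedEggImage,
    regions: RegionPartition,
    n_scales: int = N_SCALES_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass pattern energy and skewness per scale and region.

    Each scale fraction is converted to a spatial period d = fraction x egg
    length (px) and realised as a difference-of-Gaussians band-pass with
    sigma ratio sqrt(2) whose peak response sits at period d.  Energy is the
    standard deviation of the filtered pixels in the region; skewness the
    third standardised moment (0 where the s.d. vanishes).  The DC component
    cancels exactly, so adding a constant to the image changes nothing.
    """
    mask = regions.whole
    for name, reg in regions.regions().items():
        if int(reg.sum()) < 3:
            raise ValueError(f"region {name} has fewer than 3 pixels")
    lum = np.asarray(img.channels["LUM"], dtype=float)
    mean_val = float(lum[mask].mean())
    filled = np.where(mask, lum, mean_val)  # suppress edge bleed
    xs = np.where(mask.any(axis=0))[0]
    egg_len_px = float(xs[-1] - xs[0] + 1)
    fracs = pattern_scales(n_scales)
    energy = np.zeros((n_scales, 4))
    skewness = np.zeros((n_scales, 4))
    for i, frac in enumerate(fracs):
        d = frac * egg_len_px
        sigma = max(d / _DOG_PEAK_WAVELENGTH, 0.4)
        low = ndimage.gaussian_filter(filled, sigma)
        high = ndimage.gaussian_filter(filled, np.sqrt(2.0) * sigma)
        band = low - high
        for j, reg in enumerate(regions.regions().values()):
            px = band[reg]
            sd = float(px.std())
            energy[i, j] = sd
            skewness[i, j] = float(stats.skew(px)) if sd > 1e-12 else 0.0
    return energy, skewness


# ---------------------------------------------------------------------------
# Spot metrics
# ---------------------------------------------------------------------------


def spot_metrics(
    seg: SpotSegmentation, regions: RegionPartition, scale: float
) -> np.ndarray:
    """Mean spot area, coverage and longitudinal dispersion of maculation.

    Dispersion summarises how evenly spots are spread along the long axis:
    mean, population s.d. (n = 3) and coefficient of variation
    (s.d./mean x 100) of the per-third coverages.
    """
    n_spot_px = int(seg.spot_mask.sum())
    n_analysis = int(seg.analysis_mask.sum())
    mean_area_mm2 = (
        float(np.mean(seg.components)) / (scale * scale) if seg.components else 0.0
    )
    coverage = 100.0 * n_spot_px / n_analysis if n_analysis else 0.0
    zone_cov = []
    for name in ("blunt", "middle", "sharp"):
        reg = regions.regions()[name] & seg.analysis_mask
        n_reg = int(reg.sum())
        n_sp = int((seg.spot_mask & reg).sum())
        zone_cov.append(100.0 * n_sp / n_reg if n_reg else 0.0)
    zone_cov = np.asarray(zone_cov)
    disp_mean = float(zone_cov.mean())
    disp_sd = float(zone_cov.std())  # population s.d., n = 3
    disp_cv = 100.0 * disp_sd / disp_mean if disp_mean > 0 else 0.0
    return np.array([mean_area_mm2, coverage, disp_mean, disp_sd, disp_cv])


# ---------------------------------------------------------------------------
# Shape metrics
# ---------------------------------------------------------------------------


def _half_width_profile(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-width r(x) in pixels from per-column pixel counts."""
    counts = mask.sum(axis=0).astype(float)
    xs = np.where(counts > 0)[0]
    return xs.astype(float), counts[xs] / 2.0


def shape_metrics(
    mask: np.ndarray, scale: float, n_stations: int = 400
) -> np.ndarray:
    """Length, width, volume, surface, ellipse deviation and aspect ratio.

    The egg is treated as a solid of revolution about its long (horizontal)
    axis.  The half-width profile r(x) comes from per-column pixel counts,
    lightly smoothed and resampled to ``n_stations`` stations; then

        volume  = pi * integral r(x)^2 dx
        surface = 2 pi * integral sqrt(r^2 + (r r')^2) dx

    (the second form keeps the integrand finite at the poles).  Ellipse
    deviation is the mean absolute radial deviation of the outline from the
    best-fit ellipse, normalised by egg length.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if (
        mask[0, :].any()
        or mask[-1, :].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
    ):
        raise ValueError("egg clipped: mask touches image border")

    xs, r = _half_width_profile(mask)
    length_px = xs[-1] - xs[0] + 1.0
    width_px = 2.0 * r.max()
    length_mm = length_px / scale
    width_mm = width_px / scale

    # resample the squared profile g = r^2 on a fine grid; g is smooth at the
    # poles where r' diverges, so differentiate g rather than r
    x_fine = np.linspace(xs[0], xs[-1], max(n_stations, 2 * len(xs)))
    r_s = ndimage.gaussian_filter1d(r, 2.0, mode="nearest")
    r_fine = np.interp(x_fine, xs, r_s)
    g = r_fine**2
    dx = x_fine[1] - x_fine[0]
    volume_px3 = np.pi * np.trapezoid(g, dx=dx)
    dg = np.gradient(g, dx)
    surface_px2 = 2.0 * np.pi * np.trapezoid(np.sqrt(g + 0.25 * dg * dg), dx=dx)
    volume_mm3 = volume_px3 / scale**3
    surface_mm2 = surface_px2 / scale**2

    ellipse_dev = _ellipse_deviation(mask, length_px)
    aspect = length_mm / width_mm
    return np.array(
        [length_mm, width_mm, volume_mm3, surface_mm2, ellipse_dev, aspect]
    )


def _ellipse_deviation(mask: np.ndarray, length_px: float) -> float:
    contours = measure.find_contours(mask.astype(float), 0.5)
    outline = max(contours, key=len)  # (row, col) points
    if hasattr(measure.EllipseModel, "from_estimate"):
        model = measure.EllipseModel.from_estimate(outline[:, ::-1])  # (x, y)
        if not model:
            return 0.0
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = measure.EllipseModel()
        if not model.estimate(outline[:, ::-1]):
            return 0.0
        xc, yc, a, b, theta = model.params
    pts = outline[:, ::-1] - (xc, yc)
    # rotate into the ellipse frame
    c, s = np.cos(-theta), np.sin(-theta)
    u = pts[:, 0] * c - pts[:, 1] * s
    v = pts[:, 0] * s + pts[:, 1] * c
    ang = np.arctan2(v, u)
    r_pt = np.hypot(u, v)
    denom = np.hypot(b * np.cos(ang), a * np.sin(ang))
    r_ell = a * b / np.maximum(denom, 1e-12)
    return float(np.mean(np.abs(r_pt - r_ell)) / length_px)


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


@dataclass
class ImagingParams:
    """Tunables of the imaging stage; defaults are the study conventions."""

    blur_radius_px: int = 2048
    phansalkar_radius_px: int = 50
    phansalkar_k: float = 0.25
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    phansalkar_r: float = 0.5
    shrink_fraction: float = 0.03
    n_scales: int = N_SCALES_DEFAULT


def extract_features(
    img: CalibratedEggImage, params: ImagingParams | None = None
) -> RawFeatureVector:
    """Run the full imaging pipeline on one egg.

    Order: flat-field correction, mask shrink, spot segmentation, colour and
    luminance statistics, granularity spectrum, spot and shape metrics.
    """
    params = params or ImagingParams()
    img.validate()
    corrected = correct_illumination(img, params.blur_radius_px)
    analysis = shrink_mask(
        corrected.mask, egg_width_px(corrected.mask), params.shrink_fraction
    )
    seg = segment_spots(
        corrected,
        analysis_mask=analysis,
        radius_px=params.phansalkar_radius_px,
        k=params.phansalkar_k,
        p=params.phansalkar_p,
        q=params.phansalkar_q,
        r_norm=params.phansalkar_r,
    )
    regions = partition_regions(corrected.mask, corrected.blunt_end)
    colour = colour_stats(corrected, seg)
    lum_hist = luminance_histogram(corrected)
    energy, skewness = granularity_spectrum(corrected, regions, params.n_scales)
    spots = spot_metrics(seg, regions, corrected.scale)
    shape = shape_metrics(corrected.mask, corrected.scale)
    return RawFeatureVector(
        colour=colour,
        luminance_bins=lum_hist,
        pattern_energy=energy,
        pattern_skewness=skewness,
        spot_metrics=spots,
        shape=shape,
        egg_id=img.egg_id,
        clutch_id=img.clutch_id,
    )
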