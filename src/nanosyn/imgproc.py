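"""Preprocessing, auto-thresholding and particle measurement.

The chain implements the standard punctum-detection protocol: rolling-ball
background subtraction, Gaussian smoothing, automatic binarisation
(moment-preserving for punctate channels, minimum-cross-entropy for
filamentous GFAP), connected-component particle detection with a minimum
size, and intensity measurement redirected to the *raw* image.

Both auto-thresholds are computed on a 256-bin histogram spanning the
image min–max range, because the original algorithms are defined on
8-bit histograms.  Histogram-level entry points are exposed so the threshold
rules can be verified against exhaustive-search oracles directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import (
    BinaryMask,
    ChannelImage,
    DegenerateHistogramError,
    ParameterError,
    PipelineConfig,
    PunctumRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "subtract_background",
    "gaussian_smooth",
    "threshold_moments",
    "threshold_li",
    "moments_threshold_hist",
    "li_threshold_hist",
    "binarize",
    "detect_particles",
    "measure_objects",
    "segment_channel",
    "SegmentationResult",
]


# ---------------------------------------------------------------------------
# background subtraction

def _ball_structure(radius_px: float, spacing: float = 1.0) -> np.ndarray:
    """Non-flat ball structuring element: height sqrt(r² − d²) within d ≤ r.

    ``spacing`` > 1 samples the same physical ball on a coarser grid
    (used by the shrink path for large radii).
    """
    n = int(np.floor(radius_px / spacing))
    ax = np.arange(-n, n + 1) * spacing
    X, Y = np.meshgrid(ax, ax)
    d2 = X * X + Y * Y
    inside = d2 <= radius_px * radius_px
    heights = np.full(X.shape, -np.inf)
    heights[inside] = np.sqrt(radius_px * radius_px - d2[inside])
    return heights


def _rolling_ball_background(pixels: np.ndarray, radius_px: float) -> np.ndarray:
    """Rolling-ball background: grey-scale opening with a ball element.

    For large radii the image is shrunk by a block-minimum, the ball is
    rolled on the coarse grid (same physical ball), and the background
    is re-expanded by bilinear zoom — capped by the image from above.
    """
    shrink = 1 if radius_px <= 16 else (4 if radius_px <= 64 else 8)
    if shrink == 1:
        se = _ball_structure(radius_px)
        bg = ndimage.grey_opening(pixels, structure=se, mode="nearest")
        return np.minimum(bg, pixels)

    h, w = pixels.shape
    ph = (-h) % shrink
    pw = (-w) % shrink
    padded = np.pad(pixels, ((0, ph), (0, pw)), mode="edge")
    small = padded.reshape(
        padded.shape[0] // shrink, shrink, padded.shape[1] // shrink, shrink
    ).min(axis=(1, 3))
    se = _ball_structure(radius_px, spacing=shrink)
    bg_small = ndimage.grey_opening(small, structure=se, mode="nearest")
    bg = ndimage.zoom(bg_small, shrink, order=1, mode="nearest",
                      grid_mode=True)[:h, :w]
    return np.minimum(bg, pixels)


def subtract_background(image: ChannelImage, radius_px: float) -> ChannelImage:
    """Rolling-ball background subtraction, clipped at zero.

    The background is the envelope traced by a ball of the given radius
    rolled under the intensity surface; the output is input − background
    and is everywhere ≤ input.  A flat image maps to zero; features
    narrower than the ball (single-pixel spikes, punctate objects) pass
    through essentially untouched.
    """
    if radius_px <= 0:
        raise ParameterError("background radius must be positive")
    bg = _rolling_ball_background(image.pixels, radius_px)
    return image.with_pixels(np.clip(image.pixels - bg, 0.0, None))


# ---------------------------------------------------------------------------
# smoothing

def gaussian_smooth(image: ChannelImage, sigma_px: float = 1.5) -> ChannelImage:
    """Convolve with a normalised Gaussian (reflective borders).

    Total intensity is conserved.  The protocol's "1.5 pixel" smoothing
    is interpreted as sigma = 1.5 px (configurable).
    """
    if sigma_px <= 0:
        raise ParameterError("sigma must be positive")
    out = ndimage.gaussian_filter(image.pixels, sigma=sigma_px, mode="reflect")
    return image.with_pixels(np.clip(out, 0.0, None))


# ---------------------------------------------------------------------------
# auto-thresholding (256-bin histogram rules)

def _image_histogram(pixels: np.ndarray, nbins: int = 256):
    mn = float(pixels.min())
    mx = float(pixels.max())
    if mx <= mn:
        raise DegenerateHistogramError("image has a single grey level")
    counts, edges = np.histogram(pixels, bins=nbins, range=(mn, mx))
    return counts, edges


def moments_threshold_hist(counts: np.ndarray) -> int:
    """Moment-preserving (Tsai) threshold on a histogram.

    Finds the two representative grey levels and mixing fraction that
    preserve the first three moments of the histogram, then returns the
    bin index ``t`` at which the cumulative histogram first reaches the
    background fraction.  Foreground is bins ``> t``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0 or np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("histogram needs ≥ 2 occupied bins")
    p = counts / counts.sum()
    i = np.arange(counts.size, dtype=float)
    m1 = float((p * i).sum())
    m2 = float((p * i**2).sum())
    m3 = float((p * i**3).sum())
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("zero variance histogram")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 <= z0:
        raise DegenerateHistogramError("degenerate moment solution")
    p0 = (z1 - m1) / (z1 - z0)  # background (low-level) fraction
    cum = np.cumsum(p)
    # tolerance guards the exactly-balanced two-spike case against
    # cumulative-sum rounding
    t = int(np.searchsorted(cum, p0 - 1e-9, side="left"))
    return min(max(t, 0), counts.size - 2)


def li_threshold_hist(counts: np.ndarray, tol: float = 1e-3) -> int:
    """Li minimum-cross-entropy threshold on a histogram.

    Iterates the Li–Tam fixed point t ← (μ_b − μ_f)/(ln μ_b − ln μ_f),
    where μ_b and μ_f are the class means below and above t, on bin
    coordinates shifted by +1 to keep the logarithms defined, then
    polishes the converged cut against the discrete cross-entropy
    objective over the neighbouring bins (the continuous fixed point can
    sit a bin or two off the discrete minimiser on noisy histograms).
    Returns the bin index ``t``; foreground is bins ``> t``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0 or np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("histogram needs ≥ 2 occupied bins")
    p = counts / counts.sum()
    u = np.arange(1, counts.size + 1, dtype=float)
    t = float((p * u).sum())
    for _ in range(200):
        below = u <= t
        wb = p[below].sum()
        wf = 1.0 - wb
        if wb <= 0:
            t = u[counts > 0][0] + 0.5
            continue
        if wf <= 0:
            t = u[counts > 0][-1] - 0.5
            continue
        mb = float((p[below] * u[below]).sum() / wb)
        mf = float((p[~below] * u[~below]).sum() / wf)
        t_new = (mb - mf) / (np.log(mb) - np.log(mf))
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    idx = int(np.floor(t - 1.0))
    idx = min(max(idx, 0), counts.size - 2)

    def cross_entropy(cut: int) -> float:
        w0 = p[: cut + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            return np.inf
        mu0 = (p[: cut + 1] * u[: cut + 1]).sum() / w0
        mu1 = (p[cut + 1:] * u[cut + 1:]).sum() / w1
        return (-(p[: cut + 1] * u[: cut + 1]).sum() * np.log(mu0)
                - (p[cut + 1:] * u[cut + 1:]).sum() * np.log(mu1))

    lo = max(idx - 3, 0)
    hi = min(idx + 3, counts.size - 2)
    return min(range(lo, hi + 1), key=cross_entropy)


def _threshold_value(image: ChannelImage, method: str, nbins: int = 256):
    counts, edges = _image_histogram(image.pixels, nbins)
    if method == "moments":
        t = moments_threshold_hist(counts)
    elif method == "li":
        t = li_threshold_hist(counts)
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    return t, float(edges[t + 1])


def threshold_moments(image: ChannelImage, nbins: int = 256) -> float:
    """Tsai moment-preserving threshold of an image (intensity units)."""
    return _threshold_value(image, "moments", nbins)[1]


def threshold_li(image: ChannelImage, nbins: int = 256) -> float:
    """Li minimum-cross-entropy threshold of an image (intensity units)."""
    return _threshold_value(image, "li", nbins)[1]


def binarize(
    image: ChannelImage,
    method: str = "moments",
    manual_threshold: Optional[float] = None,
    nbins: int = 256,
) -> BinaryMask:
    """Binarise an image with an automatic or manual threshold.

    Automatic methods mark as foreground all pixels falling in histogram
    bins strictly above the returned cut; a manual threshold marks
    pixels strictly greater than the given value.
    """
    if manual_threshold is not None:
        mask = image.pixels > manual_threshold
        prov = (image.label, "manual", float(manual_threshold))
    else:
        _, value = _threshold_value(image, method, nbins)
        mask = image.pixels >= value
        prov = (image.label, method, value)
    return BinaryMask(mask, image.pixel_size_nm, provenance=prov)


# ---------------------------------------------------------------------------
# particle detection and measurement

def detect_particles(mask: BinaryMask, min_px: int = 1) -> np.ndarray:
    """8-connected components of a mask with at least ``min_px`` pixels.

    Returns a label image with dense labels 1..N in raster-scan order of
    each object's first pixel.
    """
    if min_px < 1:
        raise ParameterError("min_px must be ≥ 1")
    labels = measure.label(mask.pixels, connectivity=2)
    if labels.max() == 0:
        return labels
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_px)
    keep = keep[keep > 0]
    remap = np.zeros(sizes.size, dtype=labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def measure_objects(labels: np.ndarray, raw: ChannelImage) -> list[PunctumRecord]:
    """Measure labelled objects on the raw (pre-processing-free) image.

    The mean intensity is taken from ``raw`` under each label — never
    from the background-subtracted or smoothed image — so brightness is
    reported in original camera units.
    """
    if labels.shape != raw.shape:
        raise ParameterError("label image and raw image shapes differ")
    h, w = labels.shape
    px_um = raw.pixel_size_um
    records = []
    for prop in measure.regionprops(labels, intensity_image=raw.pixels):
        r0, c0, r1, c1 = prop.bbox
        on_border = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        cy, cx = prop.centroid
        records.append(PunctumRecord.from_measurement(
            id=int(prop.label),
            pixel_count=int(prop.area),
            pixel_size_nm=raw.pixel_size_nm,
            centroid_um=((cx + 0.5) * px_um, (cy + 0.5) * px_um),
            mean_intensity=float(prop.intensity_mean),
            on_border=on_border,
        ))
    return records


@dataclass
class SegmentationResult:
    mask: BinaryMask
    labels: np.ndarray
    records: list[PunctumRecord]
    threshold: Optional[float]
    processed: ChannelImage


def segment_channel(
    image: ChannelImage,
    config: PipelineConfig = PipelineConfig(),
    role: str = "punctate",
    manual_threshold: Optional[float] = None,
    min_px: Optional[int] = None,
    bg_radius_px: Optional[float] = None,
) -> SegmentationResult:
    """Full detection chain for one channel.

    ``role`` selects the protocol constants: ``punctate`` uses the
    10-pixel background radius and the moments threshold, ``gfap`` the
    25-pixel radius and the Li threshold, and ``vglut2_manual`` the
    punctate preprocessing with a user-supplied threshold (some VGLUT2
    images need manual adjustment).  Measurements are redirected to the
    raw input image.  ``bg_radius_px`` overrides the role's rolling-ball
    radius (used to hold the ball at a constant physical size across
    pixel grids).  A degenerate (single-level) histogram yields an empty
    result with a warning rather than an error.
    """
    if role == "punctate":
        radius, method = config.bg_radius_punctate_px, config.threshold_punctate
    elif role == "gfap":
        radius, method = config.bg_radius_gfap_px, config.threshold_gfap
    elif role == "vglut2_manual":
        if manual_threshold is None:
            raise ParameterError("vglut2_manual requires manual_threshold")
        radius, method = config.bg_radius_punctate_px, "manual"
    else:
        raise ParameterError(f"unknown role {role!r}")
    if min_px is None:
        min_px = config.min_px_highres
    if bg_radius_px is not None:
        radius = bg_radius_px

    processed = gaussian_smooth(
        subtract_background(image, radius), config.gaussian_sigma_px
    )
    try:
        mask = binarize(processed, method=method,
                        manual_threshold=manual_threshold)
    except DegenerateHistogramError:
        warnings.warn(
            f"channel {image.label!r}: degenerate histogram, no foreground"
        )
        mask = BinaryMask(np.zeros(image.shape, dtype=bool),
                          image.pixel_size_nm,
                          provenance=(image.label, "degenerate", None))
    labels = detect_particles(mask, min_px=min_px)
    records = measure_objects(labels, image)
    return SegmentationResult(
        mask=mask,
        labels=labels,
        records=records,
        threshold=mask.provenance[2],
        processed=processed,
    )
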