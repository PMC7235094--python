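"""Shared containers and constants for the synapse nanostructure pipeline.

Conventions used throughout the package:

* Physical coordinates are ``(x, y)`` pairs in micrometres, with ``x``
  running along image columns and ``y`` along rows.  The centre of pixel
  ``(row, col)`` sits at ``((col + 0.5) * px, (row + 0.5) * px)`` where
  ``px`` is the pixel size in micrometres.
* Intensities are non-negative floats (photon counts for synthetic data,
  raw camera units for real data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Acquisition geometry of the two imaging arms this pipeline targets:
# widefield/Apotome "mapping" images and the correlative confocal/g-STED
# super-resolution images.  Arbitrary positive pixel sizes are accepted
# everywhere; these are the replica defaults.
HIGHRES_PIXEL_NM = 102.4
STED_PIXEL_NM = 19.97
HIGHRES_PSF_FWHM_NM = 320.0
CONFOCAL_PSF_FWHM_NM = 250.0
STED_PSF_FWHM_NM = 80.0

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


class ParameterError(ValueError):
    """A numeric parameter is outside its admissible range."""


class DegenerateHistogramError(ValueError):
    """Auto-thresholding was asked to split a single-valued histogram."""


class FrameMismatchError(ValueError):
    """Two inputs that must share a physical frame do not."""


@dataclass
class ChannelImage:
    """A single-plane grayscale intensity image with physical calibration.

    Parameters
    ----------
    pixels:
        2-D array of finite, non-negative intensities.
    pixel_size_nm:
        Lateral pixel size in nanometres.
    modality:
        One of ``highres`` (widefield mapping), ``confocal`` or ``sted``.
    label:
        Free-text channel name, e.g. ``"psd95"`` or ``"eaat2"``.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    modality: str = "highres"
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterError("image must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ParameterError("image intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be positive")
        if self.modality not in ("highres", "confocal", "sted"):
            raise ParameterError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (width, height) of the frame in micrometres."""
        h, w = self.pixels.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Copy of this image with the same calibration but new pixels."""
        return ChannelImage(pixels, self.pixel_size_nm, self.modality, self.label)


@dataclass
class BinaryMask:
    """Boolean foreground mask plus a record of how it was produced."""

    pixels: np.ndarray
    pixel_size_nm: float
    provenance: tuple = ("", "", None)  # (source label, method, threshold)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ParameterError("mask must be 2-D")
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PunctumRecord:
    """One segmented punctum measured on the raw (unprocessed) image.

    ``integrated_intensity`` is ``mean_intensity * pixel_count`` by
    construction, combining per-pixel brightness and object size into a
    proxy for total marker content.
    """

    id: int
    pixel_count: int
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y)
    mean_intensity: float
    integrated_intensity: float
    on_border: bool = False

    @classmethod
    def from_measurement(
        cls,
        id: int,
        pixel_count: int,
        pixel_size_nm: float,
        centroid_um: tuple[float, float],
        mean_intensity: float,
        on_border: bool = False,
    ) -> "PunctumRecord":
        area = pixel_count * (pixel_size_nm / 1000.0) ** 2
        return cls(
            id=id,
            pixel_count=pixel_count,
            area_um2=area,
            centroid_um=centroid_um,
            mean_intensity=float(mean_intensity),
            integrated_intensity=float(mean_intensity) * pixel_count,
            on_border=on_border,
        )


@dataclass
class PipelineConfig:
    """Numeric constants of the image-analysis procedure.

    Defaults follow the standard mapping protocol: a 10-pixel rolling-ball
    background subtraction for punctate channels and 25 pixels for
    filamentous GFAP, 1.5-pixel Gaussian smoothing, moment-preserving
    thresholding for punctate channels and Li minimum-cross-entropy for
    GFAP, an 8-pixel minimum particle size for nanocluster detection,
    the 1-pixel overlap colocalization rule, 10 nearest neighbours, a
    3 µm counting radius, a 200 nm edge–edge window and a 180° rotation
    for the spatial null.
    """

    bg_radius_punctate_px: float = 10.0
    bg_radius_gfap_px: float = 25.0
    gaussian_sigma_px: float = 1.5
    threshold_punctate: str = "moments"
    threshold_gfap: str = "li"
    min_particle_px: int = 8       # nanocluster detection
    min_px_highres: int = 2        # widefield punctum detection (config choice)
    overlap_min_px: int = 1
    nn_k: int = 10
    radius_count_um: float = 3.0
    edge_edge_max_nm: float = 200.0
    rotation_deg: float = 180.0
    isolation_radius_nm: float = 400.0  # operationalises "appeared to be alone"

    def __post_init__(self) -> None:
        for name in (
            "bg_radius_punctate_px",
            "bg_radius_gfap_px",
            "gaussian_sigma_px",
            "min_particle_px",
            "min_px_highres",
            "overlap_min_px",
            "nn_k",
            "radius_count_um",
            "edge_edge_max_nm",
            "isolation_radius_nm",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM → standard deviation (same units)."""
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    """Gaussian standard deviation → FWHM (same units)."""
    return sigma * FWHM_PER_SIGMA
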