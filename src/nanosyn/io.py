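"""Reading and writing calibrated single-plane TIFF images.

Pixel size is carried in the TIFF resolution tags and echoed in a
sidecar JSON (``<stem>.meta.json``) so calibration survives tools that
drop tags.  Masks are written as 8-bit 0/255 images.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .core import BinaryMask, ChannelImage, ParameterError

__all__ = ["write_channel", "read_channel", "write_mask", "read_mask"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_channel(image: ChannelImage, path, dtype=np.uint16) -> None:
    """Write a channel image as a grayscale TIFF with calibration.

    Intensities are rounded and clipped to the target dtype; resolution
    tags store pixels-per-centimetre, and a sidecar JSON records the
    exact pixel size, modality and label.
    """
    path = Path(path)
    info = np.iinfo(dtype)
    data = np.clip(np.round(image.pixels), info.min, info.max).astype(dtype)
    px_cm = 1e7 / image.pixel_size_nm  # pixels per centimetre
    tifffile.imwrite(path, data, resolution=(px_cm, px_cm),
                     resolutionunit="CENTIMETER")
    with open(_sidecar(path), "w") as fh:
        json.dump({
            "pixel_size_nm": image.pixel_size_nm,
            "modality": image.modality,
            "label": image.label,
        }, fh, indent=1)


def read_channel(path, pixel_size_nm: Optional[float] = None,
                 modality: str = "highres", label: str = "") -> ChannelImage:
    """Read a grayscale TIFF; calibration from sidecar, tags or argument."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ParameterError(f"{path}: expected a single-plane grayscale image")
    meta = {}
    if _sidecar(path).exists():
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
    if pixel_size_nm is None:
        pixel_size_nm = meta.get("pixel_size_nm")
    if pixel_size_nm is None:
        with tifffile.TiffFile(path) as tif:
            tags = tif.pages[0].tags
            res = tags.get("XResolution")
            unit = tags.get("ResolutionUnit")
            if res is not None and unit is not None and unit.value == 3:
                num, den = res.value
                pixel_size_nm = 1e7 * den / num
    if pixel_size_nm is None:
        raise ParameterError(
            f"{path}: no pixel size in sidecar or tags; pass pixel_size_nm")
    return ChannelImage(np.asarray(data, dtype=float),
                        pixel_size_nm=float(pixel_size_nm),
                        modality=meta.get("modality", modality),
                        label=meta.get("label", label))


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit 0/255 TIFF with calibration."""
    path = Path(path)
    px_cm = 1e7 / mask.pixel_size_nm
    tifffile.imwrite(path, (mask.pixels.astype(np.uint8) * 255),
                     resolution=(px_cm, px_cm), resolutionunit="CENTIMETER")
    with open(_sidecar(path), "w") as fh:
        json.dump({
            "pixel_size_nm": mask.pixel_size_nm,
            "provenance": list(mask.provenance),
        }, fh, indent=1)


def read_mask(path, pixel_size_nm: Optional[float] = None) -> BinaryMask:
    path = Path(path)
    data = tifffile.imread(path)
    meta = {}
    if _sidecar(path).exists():
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
    if pixel_size_nm is None:
        pixel_size_nm = meta.get("pixel_size_nm")
    if pixel_size_nm is None:
        raise ParameterError(f"{path}: pixel size unknown; pass pixel_size_nm")
    prov = tuple(meta.get("provenance", ("", "", None)))
    return BinaryMask(data > 0, float(pixel_size_nm), provenance=prov)
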