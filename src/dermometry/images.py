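"""Calibrated images, region masks, polylines, and their on-disk formats.

All rasters are 2-D float arrays with intensities in [0, 1]; physical
lengths are always recovered through the stored pixel size (um per pixel
for light microscopy, nm per pixel for TEM). Coordinates are (row, col),
0-based; polylines are ordered point sequences in pixel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

Modality = str  # "LM" | "TEM"


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D grayscale raster with a physical pixel size.

    Parameters
    ----------
    intensities
        2-D float array, values in [0, 1].
    pixel_size
        Physical length of one pixel edge: um for LM, nm for TEM.
    modality
        "LM" or "TEM".
    """

    intensities: np.ndarray
    pixel_size: float
    modality: Modality = "LM"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 2-D raster")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.modality not in ("LM", "TEM"):
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RegionMask:
    """Boolean raster congruent with the image it annotates."""

    member: np.ndarray
    layer_label: str = "none"  # papillary | reticular | none

    def __post_init__(self) -> None:
        m = np.asarray(self.member, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "member", m)

    @property
    def n_pixels(self) -> int:
        return int(self.member.sum())


@dataclass(frozen=True)
class Polyline:
    """Ordered (row, col) point sequence in pixel coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("polyline needs >= 2 (row, col) points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive polyline points must be distinct")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def arc_length(self) -> float:
        """Total path length in pixel units."""
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def chord_length(self) -> float:
        """Euclidean first-to-last distance in pixel units."""
        return float(np.hypot(*(self.points[-1] - self.points[0])))


# ---------------------------------------------------------------------------
# image I/O  (16-bit grayscale TIFF; pixel size carried in the TIFF
# description tag as JSON so round trips are lossless in calibration)
# ---------------------------------------------------------------------------

def save_image(image: CalibratedImage, path: str | Path) -> None:
    data = np.clip(image.intensities, 0.0, 1.0)
    raw = np.round(data * 65535.0).astype(np.uint16)
    meta = json.dumps({"pixel_size": image.pixel_size, "modality": image.modality})
    tifffile.imwrite(str(path), raw, description=meta)


def load_image(
    path: str | Path,
    pixel_size: float | None = None,
    modality: Modality | None = None,
) -> CalibratedImage:
    """Read a TIFF/PNG image; calibration comes from the TIFF description
    tag when present, else must be supplied explicitly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            raw = tf.asarray()
            desc = tf.pages[0].description or ""
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    else:  # PNG and friends via imageio-compatible skimage reader
        from skimage.io import imread

        raw = imread(str(path))
        meta = {}
    if raw.ndim == 3:  # RGB -> luminance; the classification criterion is
        raw = rgb_to_luminance(raw)  # a single intensity threshold
    raw = np.asarray(raw, dtype=float)
    if raw.dtype != float or raw.max() > 1.0:
        raw = raw / float(np.iinfo(np.uint16).max if raw.max() > 255 else 255)
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size")
    if ps is None:
        raise ValueError(f"{path}: no pixel size in file and none supplied")
    mod = modality if modality is not None else meta.get("modality", "LM")
    return CalibratedImage(np.clip(raw, 0.0, 1.0), float(ps), mod)


def rgb_to_luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an RGB(A) array, same dtype scale as input."""
    rgb = np.asarray(rgb, dtype=float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


# ---------------------------------------------------------------------------
# mask and polyline sidecar formats (JSON; masks as row-major run-length
# encoding so sidecars stay small and text-only)
# ---------------------------------------------------------------------------

def mask_to_rle(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    # runs of alternating values, starting with the value of flat[0]
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    return {
        "shape": list(np.asarray(mask).shape),
        "first": bool(flat[0]) if flat.size else False,
        "runs": runs,
    }


def rle_to_mask(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    n = int(np.prod(shape))
    flat = np.empty(n, dtype=bool)
    val = bool(rle["first"])
    pos = 0
    for run in rle["runs"]:
        flat[pos : pos + run] = val
        pos += run
        val = not val
    if pos != n:
        raise ValueError("RLE runs do not cover the raster")
    return flat.reshape(shape)


def save_mask(mask: RegionMask, path: str | Path) -> None:
    payload = mask_to_rle(mask.member)
    payload["layer_label"] = mask.layer_label
    Path(path).write_text(json.dumps(payload))


def load_mask(path: str | Path) -> RegionMask:
    payload = json.loads(Path(path).read_text())
    return RegionMask(rle_to_mask(payload), payload.get("layer_label", "none"))


def save_annotations(polylines: dict[str, Polyline], path: str | Path) -> None:
    """Write named polylines as JSON arrays of [row, col] pairs."""
    Path(path).write_text(
        json.dumps({k: v.points.tolist() for k, v in polylines.items()})
    )


def load_annotations(path: str | Path) -> dict[str, Polyline]:
    raw = json.loads(Path(path).read_text())
    return {k: Polyline(np.asarray(v, dtype=float)) for k, v in raw.items()}
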