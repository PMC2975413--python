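"""Image and report I/O.

Reads micrographs into :class:`GrayImage`, writes label maps, CSV
measurement reports and RGB overlays.  No science lives here: every
operation is format plumbing around the segmentation pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

# ITU-R 601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

REPORT_COLUMNS = [
    "label",
    "area_px",
    "perimeter_px",
    "roundness",
    "centroid_row",
    "centroid_col",
    "equivalent_diameter_px",
    "mean_intensity",
    "intensity_variance",
    "classification",
]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel intensity raster on a 0-255 scale.

    Parameters
    ----------
    pixels : ndarray of float, shape (height, width)
        Intensities, normalised to [0, 255] at load time regardless of
        the source bit depth.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected a non-empty 2-D image, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255] after normalization")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabelMap:
    """Integer raster partitioning an image into background (0) + segments.

    After :meth:`compact`, label values form the contiguous set {0..K}.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"expected a 2-D label map, got shape {lab.shape}")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", lab.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_segments(self) -> int:
        """Number of distinct non-background labels."""
        return int(np.unique(self.labels[self.labels > 0]).size)

    def compact(self) -> "LabelMap":
        """Renumber non-background labels to 1..K preserving order."""
        vals = np.unique(self.labels)
        vals = vals[vals > 0]
        lut = np.zeros(int(self.labels.max()) + 1 if self.labels.size else 1, dtype=np.int64)
        lut[vals] = np.arange(1, vals.size + 1)
        return LabelMap(lut[self.labels])


def read_image(path: str | os.PathLike) -> GrayImage:
    """Load a TIFF/PNG micrograph as a normalised grayscale image.

    RGB(A) input is converted with ITU-R 601 luma weights; 16-bit input
    is rescaled so 65535 maps to 255.  Raises ``IOError`` for unreadable
    files and ``ValueError`` for zero-size images.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    arr = np.asarray(arr)
    src_dtype = arr.dtype
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
    else:
        arr = arr.astype(float)
    if np.issubdtype(src_dtype, np.integer):
        # rescale 16-bit (or wider) to 0-255; 8-bit stays as-is
        maxval = np.iinfo(src_dtype).max
        if maxval > 255:
            arr = arr * (255.0 / maxval)
    arr = np.clip(arr, 0.0, 255.0)
    return GrayImage(arr)


def write_image(image: GrayImage, path: str | os.PathLike) -> None:
    """Write a grayscale image as 8-bit PNG/TIFF."""
    iio.imwrite(Path(path), np.round(image.pixels).astype(np.uint8))


def write_label_map(labels: LabelMap, path: str | os.PathLike) -> None:
    """Write a label map as a 16-bit PNG or TIFF."""
    if labels.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit output")
    iio.imwrite(Path(path), labels.labels.astype(np.uint16))


def read_label_map(path: str | os.PathLike) -> LabelMap:
    """Reload a label map written by :func:`write_label_map`."""
    try:
        arr = iio.imread(Path(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"could not read label map {path}: {exc}") from exc
    return LabelMap(np.asarray(arr).astype(np.int64))


def write_report(records, path: str | os.PathLike, renumber_from_one: bool = False) -> None:
    """Write per-segment measurements to CSV, one row per record.

    ``renumber_from_one`` shifts labels so the first granule is 1 even
    when the internal background-0 convention left a gap.
    """
    rows = []
    for i, r in enumerate(records):
        label = (i + 1) if renumber_from_one else r.label
        rows.append(
            {
                "label": label,
                "area_px": r.area,
                "perimeter_px": r.perimeter,
                "roundness": r.roundness,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "equivalent_diameter_px": r.equivalent_diameter,
                "mean_intensity": r.mean_intensity,
                "intensity_variance": r.intensity_variance,
                "classification": r.classification,
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"could not write report {path}: {exc}") from exc


def write_overlay(image: GrayImage, labels: LabelMap, path: str | os.PathLike) -> None:
    """Write an RGB PNG with segment boundaries drawn over the image."""
    from skimage.segmentation import find_boundaries

    rgb = np.repeat(np.round(image.pixels).astype(np.uint8)[..., None], 3, axis=2)
    edges = find_boundaries(labels.labels, mode="outer")
    rgb[edges] = (255, 0, 0)
    iio.imwrite(Path(path), rgb)
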