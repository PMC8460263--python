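"""Image, ROI, and measurement-table I/O plus the shared domain types.

Conventions used throughout the package: images are 2D row-major arrays
indexed ``[row, col]`` with 0-based integer indices; a pixel's center sits
at its integer coordinate; ROI polygons live in the same (x=col, y=row)
frame. Experimental metadata (acquisition time, genotype, channel role)
travels in a sidecar CSV keyed by filename, never in TIFF tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Micrograph",
    "RegionOfInterest",
    "read_micrograph",
    "write_micrograph",
    "read_roi",
    "write_roi",
    "rasterize_polygon",
    "read_metadata_sidecar",
    "write_measurement_table",
    "read_measurement_table",
]

CHANNEL_ROLES = ("lipid_dye", "protein", "brightfield")


@dataclass
class Micrograph:
    """A single-channel 2D micrograph with physical and experimental metadata.

    Parameters
    ----------
    pixels : ndarray
        2D array of non-negative intensities. After quantization every value
        lies in ``[0, 2**bit_depth - 1]``.
    pixel_size_nm : float
        Physical edge length of one pixel in nanometres. The default of
        120 nm/px corresponds to a 3-pixel dilation spanning 360 nm.
    bit_depth : int
        Dynamic range of the detector (confocal acquisitions here are
        12-bit, stored in 16-bit containers).
    time_hr : float or None
        Hours since the onset of the high-fat meal; ``None`` when the image
        is not part of a time course.
    channel_role : str
        One of ``lipid_dye``, ``protein``, ``brightfield``.
    genotype_label : str
        Free text, e.g. ``"reporter"`` or ``"wild_type"``.
    subject_id : str
        Identifier of the animal the image came from.
    """

    pixels: np.ndarray
    pixel_size_nm: float = 120.0
    bit_depth: int = 12
    time_hr: Optional[float] = None
    channel_role: str = "lipid_dye"
    genotype_label: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(
                f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}"
            )
        if np.any(np.asarray(self.pixels) < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return 2 ** self.bit_depth - 1

    def with_pixels(self, pixels: np.ndarray) -> "Micrograph":
        """Copy of this micrograph with the pixel grid replaced."""
        return replace(self, pixels=pixels)


@dataclass
class RegionOfInterest:
    """Binary mask delineating the tissue (``True`` = inside)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise ValueError("ROI mask must be a non-empty 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> "RegionOfInterest":
        if not self.mask.any():
            raise ValueError("ROI contains no pixels")
        return self


def read_micrograph(
    path: str | Path,
    *,
    page: int = 0,
    pixel_size_nm: float = 120.0,
    bit_depth: int = 12,
    time_hr: Optional[float] = None,
    channel_role: str = "lipid_dye",
    genotype_label: str = "",
    subject_id: str = "",
) -> Micrograph:
    """Read a grayscale TIFF page into a :class:`Micrograph`.

    Intensities are preserved bit-exactly. RGB input is rejected because
    channel extraction must be an explicit, recorded decision.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if page >= len(tif.pages):
                raise ValueError(
                    f"page {page} out of range for {path} ({len(tif.pages)} pages)"
                )
            arr = tif.pages[page].asarray()
    except FileNotFoundError:
        raise
    except ValueError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    if arr.ndim == 3:
        raise ValueError(
            f"{path} is multi-sample (RGB?); supply a grayscale image or extract "
            "a channel explicitly before reading"
        )
    return Micrograph(
        pixels=arr,
        pixel_size_nm=pixel_size_nm,
        bit_depth=bit_depth,
        time_hr=time_hr,
        channel_role=channel_role,
        genotype_label=genotype_label,
        subject_id=subject_id,
    )


def write_micrograph(image: Micrograph, path: str | Path) -> Path:
    """Write a micrograph to a grayscale TIFF (uint16 container)."""
    path = Path(path)
    pixels = np.asarray(image.pixels)
    if np.issubdtype(pixels.dtype, np.integer) or np.all(pixels == np.round(pixels)):
        out = pixels.astype(np.uint16)
    else:
        out = pixels.astype(np.float32)
    tifffile.imwrite(path, out)
    return path


def rasterize_polygon(
    vertices: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a polygon to a boolean mask by the even-odd rule.

    A pixel ``(row, col)`` is inside when a ray from its center ``(x=col,
    y=row)`` crosses the polygon boundary an odd number of times. Vertices
    are ``(x, y)`` pairs; the polygon closes automatically.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    n_rows, n_cols = shape
    ys, xs = np.mgrid[0:n_rows, 0:n_cols]
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    x1 = verts[:, 0]
    y1 = verts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    # even-odd crossing count with a horizontal ray towards +x
    for ax, ay, bx, by in zip(x1, y1, x2, y2):
        if ay == by:
            continue
        cond = (py >= min(ay, by)) & (py < max(ay, by))
        x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= cond & (px < x_cross)
    return inside.reshape(shape)


def read_roi(path: str | Path, shape: tuple[int, int]) -> RegionOfInterest:
    """Read an ROI from a binary-mask TIFF or a polygon vertex CSV.

    CSV files must have ``x,y`` columns (or two unnamed columns) giving
    polygon vertices; they are rasterized to ``shape`` with even-odd fill
    evaluated at pixel centers. TIFF masks must match ``shape`` exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table = pd.read_csv(path)
        if {"x", "y"}.issubset(table.columns):
            verts = table[["x", "y"]].to_numpy(dtype=float)
        else:
            verts = table.iloc[:, :2].to_numpy(dtype=float)
        mask = rasterize_polygon(verts, shape)
    else:
        arr = tifffile.imread(path)
        if arr.shape != tuple(shape):
            raise ValueError(
                f"ROI mask shape {arr.shape} does not match image shape {tuple(shape)}"
            )
        mask = arr.astype(bool)
    if not mask.any():
        raise ValueError(f"ROI from {path} contains no pixels")
    return RegionOfInterest(mask=mask)


def write_roi(roi: RegionOfInterest, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, roi.mask.astype(np.uint8))
    return path


def read_metadata_sidecar(path: str | Path) -> pd.DataFrame:
    """Read the per-file metadata CSV (filename, subject, genotype, time, role)."""
    table = pd.read_csv(path)
    required = {"filename", "subject_id", "genotype_label", "channel_role"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metadata sidecar missing columns: {sorted(missing)}")
    return table


MEASUREMENT_COLUMNS = ["subject_id", "genotype_label", "time_hr", "metric", "value"]


def write_measurement_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy measurement table, validating its key uniqueness.

    Rows are ``(subject_id, genotype_label, time_hr, metric, value)``;
    duplicate ``(subject, time, metric)`` keys are an error, non-finite
    values are kept only as explicit missing (NaN) entries.
    """
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    keys = table[["subject_id", "time_hr", "metric"]]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].head()
        raise ValueError(f"duplicate (subject, time, metric) keys, e.g.\n{dupes}")
    finite = table["value"].isna() | np.isfinite(table["value"].astype(float))
    if not finite.all():
        raise ValueError("measurement values must be finite or missing (NaN)")
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
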