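"""Tile I/O and conversion between transmitted-light RGB and optical density.

Stain mixing is multiplicative in transmitted intensity (Beer–Lambert law,
``I = I0 * exp(-M N)``) but linear in optical density ``D = -log(I / I0)``.
Every downstream step of the deconvolution pipeline therefore operates on
the OD representation produced here.

Conventions fixed by this module:

* natural logarithm (base only rescales OD and densities jointly and leaves
  stain-vector directions untouched);
* intensities are clamped to ``eps = 1`` count before the log, so a
  saturated-black pixel maps to the finite OD ``log(i0)`` instead of inf;
* images are flattened to 3 x P matrices in row-major (C) pixel order, rows
  being the red, green and blue OD channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "RgbImage",
    "OdImage",
    "rgb_to_od",
    "od_to_rgb",
    "read_tile",
    "write_tile",
    "write_float_tiff",
]

#: smallest resolvable intensity, in counts; floor applied before the log
DEFAULT_EPS = 1.0


@dataclass
class RgbImage:
    """A transmitted-light RGB tile.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Transmitted-light intensities in ``[0, i0]`` (float or integer).
    i0 : float
        Incident-light intensity; 255 for 8-bit data, 65535 for 16-bit.
    """

    pixels: np.ndarray
    i0: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected an H x W x 3 RGB array, got shape {self.pixels.shape}"
            )
        if self.i0 <= 0:
            raise ValueError(f"incident intensity i0 must be positive, got {self.i0}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class OdImage:
    """Optical-density image as a 3 x P matrix (rows = R, G, B channels).

    Columns enumerate pixels in row-major scan order of the source tile;
    ``shape`` retains the (H, W) geometry so density maps reshape back
    deterministically.
    """

    d: np.ndarray
    shape: tuple[int, int]
    i0: float = 255.0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.ndim != 2 or self.d.shape[0] != 3:
            raise ValueError(f"OD matrix must be 3 x P, got shape {self.d.shape}")
        h, w = self.shape
        if self.d.shape[1] != h * w:
            raise ValueError(
                f"OD matrix has {self.d.shape[1]} columns but shape {self.shape} "
                f"implies {h * w} pixels"
            )

    def channel_plane(self, idx: int) -> np.ndarray:
        """Return one OD colour channel reshaped to (H, W)."""
        return self.d[idx].reshape(self.shape)


def rgb_to_od(img: RgbImage, eps: float = DEFAULT_EPS) -> OdImage:
    """Convert a transmitted-light tile to optical density, ``D = -ln(I/I0)``.

    Intensities are clamped to ``[eps, i0]`` first so the result is finite
    and non-negative everywhere.
    """
    i = np.asarray(img.pixels, dtype=np.float64)
    i = np.clip(i, eps, img.i0)
    d = -np.log(i / img.i0)
    h, w = img.shape
    return OdImage(d=d.reshape(h * w, 3).T, shape=(h, w), i0=img.i0)


def od_to_rgb(od: OdImage, i0: float | None = None) -> RgbImage:
    """Invert the Beer–Lambert transform: ``I = I0 * exp(-D)``.

    Negative OD entries (brighter than the incident light, which is
    unphysical) are clipped to zero with a warning; output intensities are
    clipped to ``[0, i0]``.
    """
    if i0 is None:
        i0 = od.i0
    d = od.d
    if not np.all(np.isfinite(d)):
        raise ValueError("OD matrix contains non-finite entries")
    if np.any(d < 0):
        warnings.warn(
            "negative OD entries clipped to 0 (brighter than incident light)",
            stacklevel=2,
        )
        d = np.maximum(d, 0.0)
    intensity = i0 * np.exp(-d)
    h, w = od.shape
    pixels = np.clip(intensity.T.reshape(h, w, 3), 0.0, i0)
    return RgbImage(pixels=pixels, i0=i0)


def read_tile(path: str | Path, i0: float | None = None) -> RgbImage:
    """Read a PNG/TIFF/JPEG tile as an :class:`RgbImage`.

    Grayscale input is replicated to three channels and RGBA alpha is
    dropped, each with a warning. ``i0`` defaults to the full-scale value of
    the file's bit depth (255 or 65535).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: grayscale input replicated to RGB", stacklevel=2)
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: cannot interpret array of shape {arr.shape} as RGB")
    if arr.shape[2] == 4:
        warnings.warn(f"{path.name}: alpha channel dropped", stacklevel=2)
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path.name}: expected 3 colour channels, got {arr.shape[2]}")
    if i0 is None:
        i0 = 65535.0 if arr.dtype == np.uint16 else 255.0
    return RgbImage(pixels=arr, i0=float(i0))


def write_tile(img: RgbImage, path: str | Path) -> None:
    """Write a tile as 8-bit (or 16-bit when ``i0 > 255``) PNG/TIFF/JPEG."""
    path = Path(path)
    if img.i0 > 255:
        arr = np.clip(np.rint(img.pixels), 0, 65535).astype(np.uint16)
    else:
        arr = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_float_tiff(plane: np.ndarray, path: str | Path) -> None:
    """Export a single-channel map (OD channel, density map) as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(plane, dtype=np.float32))
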