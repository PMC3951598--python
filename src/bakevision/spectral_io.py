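"""Containers and file I/O for multispectral reflectance images.

A multispectral image is carried as a :class:`SpectralImage`: a reflectance
cube of shape ``(height, width, n_bands)`` with values in [0, 1] plus the
strictly increasing list of band-center wavelengths in nanometres.  On disk an
image is a band-interleaved multi-page TIFF (one page per band, pages ordered
by increasing wavelength, 32-bit float) with the wavelength grid in a JSON
sidecar rather than TIFF tags, which keeps the container readable by any TIFF
dialect.  Sample metadata travels as plain comma-separated UTF-8 tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SpectralImage",
    "CookieRecord",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
    "pseudo_rgb",
]


@dataclasses.dataclass
class SpectralImage:
    """Reflectance cube plus its ordered wavelength grid.

    Parameters
    ----------
    cube:
        ``(height, width, n_bands)`` float array, reflectance in [0, 1].
    wavelengths_nm:
        Band-center wavelengths, strictly increasing, length ``n_bands``.
    mask:
        Optional boolean surface mask of shape ``(height, width)``.
    """

    cube: np.ndarray
    wavelengths_nm: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError(f"cube must be 3-D (h, w, bands), got shape {self.cube.shape}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.cube.shape[2]:
            raise ValueError(
                f"wavelength grid length {len(self.wavelengths_nm)} does not match "
                f"{self.cube.shape[2]} bands"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.cube.shape[:2]:
                raise ValueError("mask shape does not match cube")

    @property
    def n_bands(self) -> int:
        return self.cube.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    def band_nearest(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


@dataclasses.dataclass
class CookieRecord:
    """One cookie's metadata: design set, condition, masses and panel votes."""

    id: str
    set: str
    time_min: float
    temp_c: float
    replicate: int
    initial_mass_g: float
    dried_mass_g: float
    votes_under: int
    votes_adequate: int
    votes_over: int

    def __post_init__(self) -> None:
        if self.dried_mass_g > self.initial_mass_g:
            raise ValueError("dried mass exceeds initial mass")
        if min(self.votes_under, self.votes_adequate, self.votes_over) < 0:
            raise ValueError("votes must be non-negative")


def _sidecar_path(tif_path: Path, sidecar: str | Path | None) -> Path:
    if sidecar is not None:
        return Path(sidecar)
    per_image = tif_path.with_suffix(".json")
    if per_image.exists():
        return per_image
    return tif_path.parent / "wavelengths.json"


def write_image(img: SpectralImage, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a cube as a multi-page float32 TIFF plus JSON wavelength sidecar.

    With the default ``sidecar=None`` the grid is written next to the image as
    ``<stem>.json``; dataset writers pass a shared ``wavelengths.json`` instead.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(img.cube.astype(np.float32), -1, 0)  # band-major pages
    tifffile.imwrite(path, pages)
    sidecar_path = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    payload = {"wavelengths_nm": [float(w) for w in img.wavelengths_nm]}
    sidecar_path.write_text(json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n")


def read_image(path: str | Path, sidecar: str | Path | None = None) -> SpectralImage:
    """Read a multi-page TIFF written by :func:`write_image`.

    The wavelength grid comes from ``sidecar`` if given, else ``<stem>.json``
    next to the image, else a shared ``wavelengths.json`` in the same
    directory.  A band-count mismatch between TIFF pages and sidecar is an
    error naming both counts.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    cube = np.moveaxis(pages, 0, -1)
    sidecar_path = _sidecar_path(path, sidecar)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"wavelength sidecar not found for {path} (looked at {sidecar_path})")
    wavelengths = json.loads(sidecar_path.read_text())["wavelengths_nm"]
    if len(wavelengths) != cube.shape[2]:
        raise ValueError(
            f"sidecar lists {len(wavelengths)} wavelengths but TIFF has {cube.shape[2]} pages"
        )
    return SpectralImage(cube=cube, wavelengths_nm=np.asarray(wavelengths, dtype=float))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Serialize a boolean mask as a single-page 8-bit TIFF (surface = 255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a sample table as comma-separated UTF-8 with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so write -> read -> write is byte-identical
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")


def pseudo_rgb(img: SpectralImage) -> np.ndarray:
    """Render a 3-channel visible preview from the bands nearest 630/525/450 nm.

    Each channel is contrast-stretched independently to [0, 1]; a constant
    channel is passed through unchanged (clipped), so a constant cube renders
    as constant grey.
    """
    if not np.any(img.wavelengths_nm < 500):
        raise ValueError("pseudo-RGB needs at least one band below 500 nm")
    out = np.empty(img.shape + (3,), dtype=float)
    for ch, target in enumerate((630.0, 525.0, 450.0)):
        band = img.cube[..., img.band_nearest(target)].astype(float)
        lo, hi = float(band.min()), float(band.max())
        if hi > lo:
            out[..., ch] = (band - lo) / (hi - lo)
        else:
            out[..., ch] = np.clip(band, 0.0, 1.0)
    return out
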