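"""Seed ROI segmentation and per-seed mean-spectrum extraction.

Seeds lie on a dark background, so a single gray band (700 nm for the
endosperm face, 500 nm for the embryo face) separates kernel from
background.  The pipeline is: pick the gray band, percentile contrast
stretch, Otsu threshold, connected-component labeling with a minimum-area
filter, then average the calibrated pixel spectra within each seed region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pathlib import Path
from skimage import measure
from skimage.filters import threshold_otsu

from .cube_io import HyperCube, WavelengthGrid
from .errors import DegenerateInputError, EmptyMaskError

__all__ = [
    "SeedMask",
    "SpectraTable",
    "to_gray",
    "enhance",
    "otsu_threshold",
    "label_seeds",
    "mean_spectra",
    "segment_cube",
]

CLASS_NAMES = {1: "normal", 2: "slight", 3: "severe"}


@dataclass
class SeedMask:
    """Labeled seed regions: 0 = background, k >= 1 = seed k (raster order)."""

    labels: np.ndarray
    areas: np.ndarray

    @property
    def seed_count(self) -> int:
        return int(self.areas.size)


@dataclass
class SpectraTable:
    """n x B matrix of per-seed mean reflectance spectra with metadata.

    ``labels`` holds the freeze-damage class per row (1 = normal,
    2 = slightly frozen, 3 = severely frozen); ``side`` records which seed
    face was imaged; ``preprocessing`` tracks what has been applied.
    """

    spectra: np.ndarray
    grid: WavelengthGrid
    labels: np.ndarray
    side: str = "endosperm"
    preprocessing: str = "none"

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (n_seeds, n_bands) matrix")
        if self.spectra.shape[1] != self.grid.count:
            raise ValueError("spectra band count does not match the grid")
        if self.labels.shape != (self.spectra.shape[0],):
            raise ValueError("one class label per spectrum is required")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain missing/non-finite values")

    @property
    def n(self) -> int:
        return self.spectra.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.spectra, columns=[f"{w:.6g}" for w in self.grid.centers])
        df["label"] = self.labels
        df["side"] = self.side
        df["preprocessing"] = self.preprocessing
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        meta = {"label", "side", "preprocessing"}
        wl_cols = [c for c in df.columns if c not in meta]
        return cls(
            spectra=df[wl_cols].to_numpy(float),
            grid=WavelengthGrid(np.array([float(c) for c in wl_cols])),
            labels=df["label"].to_numpy(),
            side=str(df["side"].iloc[0]) if "side" in df else "endosperm",
            preprocessing=(
                str(df["preprocessing"].iloc[0]) if "preprocessing" in df else "none"
            ),
        )


def to_gray(cube: HyperCube, wavelength_nm: float) -> np.ndarray:
    """Return the band image whose center is nearest to *wavelength_nm*."""
    band = cube.grid.nearest_band(wavelength_nm)
    return cube.values[:, :, band]


def enhance(
    image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Linear contrast stretch clipping at the given percentiles, into [0, 1].

    A constant image cannot be stretched and is returned unchanged with a
    warning.
    """
    if not low_pct < high_pct:
        raise ValueError("low_pct must be smaller than high_pct")
    lo, hi = np.percentile(image, [low_pct, high_pct])
    if hi == lo:
        warnings.warn("constant image: contrast stretch is a no-op", stacklevel=2)
        return image.copy()
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of *image*.

    Maximizes the between-class variance of the foreground/background split.
    """
    image = np.asarray(image)
    if np.all(image == image.flat[0]):
        raise DegenerateInputError("constant image has no Otsu threshold")
    return float(threshold_otsu(image, nbins=256))


def label_seeds(
    binary_mask: np.ndarray, min_area: int = 50, connectivity: int = 2
) -> SeedMask:
    """Connected components above *min_area* pixels, labeled in raster order.

    ``connectivity`` follows skimage: 1 = 4-connected, 2 = 8-connected.
    Components are renumbered by the raster position of their top-left pixel
    so labels are stable under relabeling of the input.
    """
    lab = measure.label(binary_mask.astype(bool), connectivity=connectivity)
    regions = [r for r in measure.regionprops(lab) if r.area >= min_area]
    if not regions:
        raise EmptyMaskError(f"no component with area >= {min_area} px")
    # raster order of each region's topmost-then-leftmost pixel
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    out = np.zeros_like(lab)
    areas = np.empty(len(regions), dtype=np.int64)
    for k, r in enumerate(regions, start=1):
        out[lab == r.label] = k
        areas[k - 1] = r.area
    return SeedMask(labels=out, areas=areas)


def mean_spectra(
    cube: HyperCube,
    mask: SeedMask,
    labels: np.ndarray,
    side: str = "endosperm",
) -> SpectraTable:
    """Average the pixel spectra inside each seed region.

    Row k of the result is the arithmetic mean over seed k's pixels at every
    band — one spectrum per seed, which is the unit of all downstream
    analysis.  ``labels`` gives the freeze-damage class of each seed in mask
    order.
    """
    if not cube.calibrated:
        raise ValueError("mean_spectra expects a calibrated (reflectance) cube")
    if mask.labels.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match the cube's spatial shape")
    labels = np.asarray(labels)
    if labels.shape != (mask.seed_count,):
        raise ValueError("need one class label per seed")
    flat = cube.values.reshape(-1, cube.grid.count)
    lab_flat = mask.labels.ravel()
    rows = np.empty((mask.seed_count, cube.grid.count))
    for k in range(1, mask.seed_count + 1):
        sel = lab_flat == k
        if not sel.any():
            raise RuntimeError(f"seed {k} has zero pixels")  # internal consistency
        rows[k - 1] = flat[sel].mean(axis=0)
    return SpectraTable(rows, cube.grid, labels, side=side)


def segment_cube(
    cube: HyperCube,
    gray_nm: float = 700.0,
    min_area: int = 50,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> SeedMask:
    """Full segmentation: gray band -> stretch -> Otsu -> labeled components."""
    gray = enhance(to_gray(cube, gray_nm), low_pct, high_pct)
    thr = otsu_threshold(gray)
    return label_seeds(gray > thr, min_area=min_area)


def mask_to_ascii(mask: SeedMask, path) -> None:
    """Export the label image as a whitespace-separated integer grid."""
    np.savetxt(Path(path), mask.labels, fmt="%d")
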