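"""Synthetic seed spectra and hyperspectral cubes with known ground truth.

No seed-image dataset is publicly deposited for this problem, so every
stage of the pipeline is exercised on synthetic data whose statistical
structure matches what is reported for freeze-damaged corn kernels:

* three severity classes (1 normal, 2 slight, 3 severe) whose mean
  reflectance is severity-ordered — unfrozen seeds darkest, severely
  frozen brightest;
* smooth class-dependent absorption features concentrated in the
  700–979 nm region, where the damage response of raw spectra lives;
* per-seed multiplicative scatter and additive baseline (so SNV has real
  work to do) plus per-band Gaussian noise;
* an "embryo" profile with roughly double the class separation of the
  "endosperm" profile, reflecting the embryo's greater sensitivity to
  freezing.

``gen_spectra`` draws per-seed mean spectra directly; ``gen_cube``
paints seed ellipses into a scene and synthesizes raw/dark/white count
cubes such that black-white calibration exactly inverts the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cube_io import HyperCube, WavelengthGrid
from .errors import ConfigError, LayoutError
from .segmentation import SeedMask, SpectraTable

__all__ = [
    "SynthConfig",
    "CubeLayout",
    "GroundTruth",
    "gen_spectra",
    "gen_cube",
    "default_config",
    "grid_layout",
]

#: class-dependent absorption features: (center_nm, width_nm)
_DEFAULT_FEATURES = ((730.0, 12.0), (810.0, 14.0), (880.0, 12.0), (950.0, 10.0))


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of the spectra/cube generator.

    Severity offsets are per class (index 0 = normal) and must strictly
    increase with severity.  Damage features are Gaussian bumps whose
    amplitude grows with severity (``feature_amp_step`` per class step),
    concentrating the class-dependent response at known bands on top of the
    overall severity brightening, so both the level and the local band
    shape separate the classes.
    """

    class_sizes: tuple[int, ...] = (800, 640, 480)
    grid_start_nm: float = 450.0
    grid_stop_nm: float = 979.0
    n_bands: int = 420
    severity_offsets: tuple[float, ...] = (0.0, 0.02, 0.04)
    feature_centers: tuple[tuple[float, float], ...] = _DEFAULT_FEATURES
    feature_amp_step: float = 0.012
    scatter_gain: tuple[float, float] = (0.85, 1.15)
    baseline_range: tuple[float, float] = (-0.03, 0.03)
    noise_sd: float = 0.008
    severity_jitter: float = 0.32
    side_profile: str = "endosperm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.severity_jitter < 0:
            raise ConfigError("severity_jitter must be >= 0")
        offs = np.asarray(self.severity_offsets)
        if offs.size != len(self.class_sizes):
            raise ConfigError("one severity offset per class is required")
        if not np.all(np.diff(offs) > 0):
            raise ConfigError(
                "severity offsets must strictly increase with damage severity"
            )

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.linspace(self.grid_start_nm, self.grid_stop_nm, self.n_bands)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    class_means: np.ndarray  # (K, B) noiseless class mean curves
    informative_centers_nm: np.ndarray
    informative_band_indices: np.ndarray


def default_config(
    side: str = "endosperm",
    seed: int = 0,
    class_sizes: tuple[int, ...] = (800, 640, 480),
    n_bands: int = 420,
) -> SynthConfig:
    """Study-condition defaults for either seed face.

    The embryo face carries roughly twice the endosperm's class separation
    (larger severity offsets and deeper damage features), which is what
    makes embryo-side classification the easier task.
    """
    if side == "embryo":
        return SynthConfig(
            class_sizes=class_sizes,
            n_bands=n_bands,
            severity_offsets=(0.0, 0.035, 0.07),
            feature_amp_step=0.022,
            severity_jitter=0.26,
            side_profile="embryo",
            seed=seed,
        )
    if side == "endosperm":
        return SynthConfig(
            class_sizes=class_sizes, n_bands=n_bands, side_profile="endosperm",
            seed=seed,
        )
    raise ConfigError(f"side must be 'endosperm' or 'embryo', got {side!r}")


def _base_curve(wl: np.ndarray, side: str) -> np.ndarray:
    """Smooth kernel-reflectance shape; the embryo face images brighter."""
    base = (
        0.18
        + 0.42 * np.exp(-(((wl - 780.0) / 190.0) ** 2))
        + 0.18 * np.exp(-(((wl - 560.0) / 110.0) ** 2))
    )
    if side == "embryo":
        base = base + 0.05
    return base


def class_mean_curves(cfg: SynthConfig) -> np.ndarray:
    """Noiseless (K, B) class mean spectra implied by the config."""
    wl = cfg.grid.centers
    base = _base_curve(wl, cfg.side_profile)
    K = len(cfg.class_sizes)
    means = np.empty((K, wl.size))
    for c in range(K):
        bumps = np.zeros_like(wl)
        for center, width in cfg.feature_centers:
            bumps += cfg.feature_amp_step * c * np.exp(
                -(((wl - center) / width) ** 2)
            )
        means[c] = base + cfg.severity_offsets[c] + bumps
    return means


def _severity_curves(cfg: SynthConfig, s: np.ndarray) -> np.ndarray:
    """Noiseless spectra for fractional severities *s* (0 = normal class)."""
    wl = cfg.grid.centers
    base = _base_curve(wl, cfg.side_profile)
    K = len(cfg.class_sizes)
    offsets = np.interp(s, np.arange(K), np.asarray(cfg.severity_offsets))
    bumps = np.zeros((s.size, wl.size))
    for center, width in cfg.feature_centers:
        bumps += np.exp(-(((wl - center) / width) ** 2))[None, :]
    return base[None, :] + offsets[:, None] + cfg.feature_amp_step * s[:, None] * bumps


def gen_spectra(cfg: SynthConfig) -> tuple[SpectraTable, GroundTruth]:
    """Draw per-seed mean spectra with scatter, baseline, noise and jitter.

    Each seed's true damage severity is its class index plus Gaussian
    jitter (``severity_jitter`` class units, truncated to the class range):
    freeze damage is a continuum that the three categories bin, so seeds
    near a category boundary genuinely overlap the neighboring class.  The
    observed spectrum is ``gain * curve(severity) + baseline + noise``.
    Deterministic under a fixed config (including its RNG seed); returns
    the table together with the planted ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    means = class_mean_curves(cfg)
    K = len(cfg.class_sizes)
    n_total = int(sum(cfg.class_sizes))
    spectra = np.empty((n_total, grid.count))
    labels = np.empty(n_total, dtype=np.int64)
    row = 0
    for c, n_c in enumerate(cfg.class_sizes):
        sev = np.clip(
            rng.normal(float(c), cfg.severity_jitter, size=n_c), 0.0, K - 1.0
        )
        gains = rng.uniform(*cfg.scatter_gain, size=n_c)
        bases = rng.uniform(*cfg.baseline_range, size=n_c)
        noise = rng.normal(0.0, cfg.noise_sd, size=(n_c, grid.count))
        spectra[row : row + n_c] = (
            gains[:, None] * _severity_curves(cfg, sev) + bases[:, None] + noise
        )
        labels[row : row + n_c] = c + 1
        row += n_c
    np.clip(spectra, 0.0, 1.2, out=spectra)
    centers = np.array([c for c, _ in cfg.feature_centers])
    truth = GroundTruth(
        class_means=means,
        informative_centers_nm=centers,
        informative_band_indices=np.array(
            [grid.nearest_band(c) for c in centers], dtype=np.int64
        ),
    )
    table = SpectraTable(spectra, grid, labels, side=cfg.side_profile)
    return table, truth


@dataclass(frozen=True)
class CubeLayout:
    """Seed-ellipse placement for a synthetic scene.

    ``ellipses`` is a sequence of (center_row, center_col, semi_axis_row,
    semi_axis_col); ``classes`` gives each seed's severity class (1-based).
    The background must stay darker than every seed at the segmentation
    band, which holds for the default levels.
    """

    shape: tuple[int, int] = (96, 96)
    ellipses: tuple[tuple[float, float, float, float], ...] = ()
    classes: tuple[int, ...] = ()
    background_reflectance: float = 0.04
    dark_level: float = 500.0
    white_level: float = 4000.0
    white_gradient: float = 0.0  # fractional left-to-right droop of the white field

    def __post_init__(self) -> None:
        if len(self.ellipses) != len(self.classes):
            raise LayoutError("one class per ellipse is required")


def grid_layout(
    n_rows: int,
    n_cols: int,
    classes: tuple[int, ...],
    cell: int = 32,
    radius: tuple[float, float] = (9.0, 7.0),
) -> CubeLayout:
    """Regular row-major grid of non-overlapping seed ellipses."""
    if len(classes) != n_rows * n_cols:
        raise LayoutError("need one class per grid cell")
    ellipses = tuple(
        (r * cell + cell / 2, c * cell + cell / 2, radius[0], radius[1])
        for r in range(n_rows)
        for c in range(n_cols)
    )
    return CubeLayout(
        shape=(n_rows * cell, n_cols * cell), ellipses=ellipses, classes=classes
    )


def _paint_masks(layout: CubeLayout) -> np.ndarray:
    """Rasterize ellipses into a label image; raise on any overlap."""
    H, W = layout.shape
    rr, cc = np.mgrid[0:H, 0:W]
    labels = np.zeros((H, W), dtype=np.int64)
    for k, (cy, cx, ay, ax) in enumerate(layout.ellipses, start=1):
        inside = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
        if (labels[inside] != 0).any():
            raise LayoutError(f"ellipse {k} overlaps an earlier ellipse")
        labels[inside] = k
    return labels


def gen_cube(
    cfg: SynthConfig, layout: CubeLayout
) -> tuple[HyperCube, HyperCube, HyperCube, SeedMask]:
    """Synthesize (raw, dark, white) count cubes plus the truth seed mask.

    A reflectance scene is painted (background + one generated spectrum per
    seed ellipse), then raw counts are built as
    ``raw = dark + reflectance * (white - dark)`` so that black/white
    calibration recovers the painted scene exactly.  The white field can
    carry a lateral gradient to emulate uneven illumination, which the
    calibration must (and does) cancel.
    """
    n_seeds = len(layout.ellipses)
    per_class = tuple(
        int(np.sum(np.asarray(layout.classes) == c + 1))
        for c in range(len(cfg.class_sizes))
    )
    spectra_cfg = replace(cfg, class_sizes=tuple(max(c, 1) for c in per_class))
    table, _ = gen_spectra(spectra_cfg)
    labels_img = _paint_masks(layout)
    grid = cfg.grid

    scene = np.full(
        (*layout.shape, grid.count), layout.background_reflectance, dtype=float
    )
    # consume generated rows class by class, in seed (raster) order
    cursor = {c + 1: np.nonzero(table.labels == c + 1)[0] for c in range(len(per_class))}
    used = {c: 0 for c in cursor}
    for k, cls in enumerate(layout.classes, start=1):
        row = cursor[cls][used[cls] % cursor[cls].size]
        used[cls] += 1
        scene[labels_img == k] = table.spectra[row]

    H, W = layout.shape
    dark = np.full((H, W, grid.count), layout.dark_level)
    droop = 1.0 - layout.white_gradient * (np.arange(W) / max(W - 1, 1))
    white = layout.white_level * droop[None, :, None] * np.ones((H, W, grid.count))
    raw = dark + scene * (white - dark)

    areas = np.array(
        [int(np.sum(labels_img == k)) for k in range(1, n_seeds + 1)], dtype=np.int64
    )
    mask = SeedMask(labels=labels_img, areas=areas)
    return (
        HyperCube(raw, grid, calibrated=False),
        HyperCube(dark, grid, calibrated=False),
        HyperCube(white, grid, calibrated=False),
        mask,
    )
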