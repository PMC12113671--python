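"""Hyperspectral cube I/O, reflectance calibration and waveband trimming.

Cubes are stored as ENVI-style pairs: an ASCII ``.hdr`` with ``key = value``
metadata and a raw little-endian binary file in BIL, BIP or BSQ interleave.
In memory a cube is a ``(line, sample, band)`` float array together with its
wavelength grid.

Reflectance calibration follows the standard black/white correction

    I = (I_o - I_B) / (I_W - I_B)

with ``I_o`` the raw scene, ``I_B`` the dark-current cube (lens capped,
light off) and ``I_W`` the white-reference cube (Teflon board).  The
division cancels both the dark current and any spatial non-uniformity of
the illumination field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import CalibrationError, CorruptFileError, FormatError

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "read_envi",
    "write_envi",
    "calibrate",
    "trim_bands",
    "trim_wavelengths",
]

_INTERLEAVES = ("bil", "bip", "bsq")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-center wavelengths in nm."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("wavelength grid needs at least 2 band centers")
        if not np.all(np.diff(c) > 0):
            raise ValueError("wavelength centers must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.centers.size)

    @classmethod
    def linspace(cls, start_nm: float, stop_nm: float, count: int) -> "WavelengthGrid":
        """Evenly spaced grid of *count* centers spanning [start, stop] nm."""
        return cls(np.linspace(start_nm, stop_nm, count))

    def nearest_band(self, wavelength_nm: float) -> int:
        """0-based index of the band center nearest to *wavelength_nm*."""
        lo, hi = self.centers[0], self.centers[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside grid range [{lo}, {hi}]"
            )
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))

    def to_csv(self, path: str | Path) -> None:
        """Write the per-band wavelength list as a one-column CSV."""
        lines = ["wavelength_nm"] + [f"{w:.6g}" for w in self.centers]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class HyperCube:
    """Reflectance (or raw-count) cube indexed ``(line, sample, band)``."""

    values: np.ndarray
    grid: WavelengthGrid
    calibrated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError("cube values must be 3-D (line, sample, band)")
        if v.shape[2] != self.grid.count:
            raise ValueError(
                f"band dimension {v.shape[2]} != grid count {self.grid.count}"
            )
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def _parse_header(text: str) -> dict[str, str]:
    """Parse ENVI ``key = value`` lines; ``{...}`` blocks may span lines."""
    text = re.sub(r"^ENVI\s*", "", text.strip())
    fields: dict[str, str] = {}
    # join multi-line { } blocks
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI header + raw cube pair.

    The raw file is located by dropping the ``.hdr`` suffix, or by trying
    ``.raw`` / ``.img`` / ``.dat`` next to the header.

    Raises
    ------
    FormatError
        if the header lacks wavelength metadata or uses an unknown layout.
    CorruptFileError
        if the raw file size disagrees with the declared dimensions.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())

    if "wavelength" not in fields:
        raise FormatError(f"{header_path}: header has no wavelength list")
    wl_text = fields["wavelength"].strip().strip("{}")
    centers = np.array([float(w) for w in wl_text.split(",") if w.strip()])
    grid = WavelengthGrid(centers)

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise FormatError(f"{header_path}: missing dimension field {exc}") from exc
    if bands != grid.count:
        raise FormatError(
            f"{header_path}: bands={bands} but wavelength list has {grid.count}"
        )
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"{header_path}: unknown interleave {interleave!r}")
    dtype = _ENVI_DTYPES.get(fields.get("data type", "5"))
    if dtype is None:
        raise FormatError(f"{header_path}: unsupported data type")

    raw_path = _find_raw(header_path)
    raw = np.fromfile(raw_path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise CorruptFileError(
            f"{raw_path}: {raw.size} values on disk, header implies {expected}"
        )
    if interleave == "bil":  # (line, band, sample)
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (line, sample, band)
        values = raw.reshape(lines, samples, bands)
    else:  # bsq: (band, line, sample)
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    return HyperCube(values.astype(np.float64), grid, calibrated=False)


# ENVI numeric codes for the types we read/write
_ENVI_DTYPES = {
    "4": np.dtype("<f4"),
    "5": np.dtype("<f8"),
    "12": np.dtype("<u2"),
}


def _find_raw(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for candidate in (stem, *(stem.with_suffix(s) for s in (".raw", ".img", ".dat"))):
        if candidate.exists() and candidate != header_path:
            return candidate
    raise FileNotFoundError(f"no raw file found for header {header_path}")


def write_envi(
    cube: HyperCube, header_path: str | Path, interleave: str = "bil"
) -> None:
    """Write *cube* as an ENVI header + ``.raw`` little-endian float64 pair."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}")
    header_path = Path(header_path)
    lines, samples, bands = cube.shape
    wl = ", ".join(repr(float(w)) for w in cube.grid.centers)
    header_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    if interleave == "bil":
        out = cube.values.transpose(0, 2, 1)
    elif interleave == "bip":
        out = cube.values
    else:
        out = cube.values.transpose(2, 0, 1)
    np.ascontiguousarray(out, dtype="<f8").tofile(header_path.with_suffix(".raw"))


def calibrate(
    raw: HyperCube,
    dark: HyperCube,
    white: HyperCube,
    zero_denominator: str = "raise",
) -> HyperCube:
    """Black/white reflectance correction ``(raw - dark) / (white - dark)``.

    Parameters
    ----------
    zero_denominator
        ``"raise"`` (default) aborts listing the offending voxel count;
        ``"mask"`` sets those voxels to NaN instead.
    """
    for other in (dark, white):
        if other.shape != raw.shape or not np.array_equal(
            other.grid.centers, raw.grid.centers
        ):
            raise ValueError("raw, dark and white cubes must share shape and grid")
    denom = white.values - dark.values
    bad = denom == 0
    n_bad = int(bad.sum())
    if n_bad and zero_denominator == "raise":
        raise CalibrationError(
            f"white - dark is zero at {n_bad} voxel(s); "
            "pass zero_denominator='mask' to NaN them instead"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (raw.values - dark.values) / denom
    if n_bad:
        values[bad] = np.nan
    return HyperCube(values, raw.grid, calibrated=True)


def _trim_grid(grid: WavelengthGrid, first_index: int, last_index: int):
    if not (1 <= first_index <= last_index <= grid.count):
        raise ValueError(
            f"band indices {first_index}..{last_index} invalid for "
            f"{grid.count}-band grid (1-based inclusive)"
        )
    sl = slice(first_index - 1, last_index)
    return WavelengthGrid(grid.centers[sl]), sl


def trim_bands(obj, first_index: int, last_index: int):
    """Keep bands ``first_index..last_index`` (1-based, inclusive).

    The instrument's extreme bands are noisy (low detector response), so the
    analysis waveband is cut down before modeling; with a 477-band grid the
    conventional cut 36..455 retains 420 bands.  Accepts a
    :class:`HyperCube` or a :class:`~seedfrost.segmentation.SpectraTable`.
    """
    grid, sl = _trim_grid(obj.grid, first_index, last_index)
    if isinstance(obj, HyperCube):
        return HyperCube(obj.values[:, :, sl], grid, calibrated=obj.calibrated)
    # SpectraTable (duck-typed to avoid a circular import)
    return replace(obj, spectra=obj.spectra[:, sl], grid=grid)


def trim_wavelengths(obj, low_nm: float, high_nm: float):
    """Keep bands whose centers satisfy ``low_nm <= center <= high_nm``."""
    centers = obj.grid.centers
    keep = np.nonzero((centers >= low_nm) & (centers <= high_nm))[0]
    if keep.size < 2:
        raise ValueError(f"fewer than 2 bands inside [{low_nm}, {high_nm}] nm")
    return trim_bands(obj, int(keep[0]) + 1, int(keep[-1]) + 1)
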