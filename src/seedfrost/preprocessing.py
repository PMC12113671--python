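"""Spectral preprocessing: standard normal variate and 5-3 smoothing.

Both operate row-locally (one seed spectrum at a time), so neither can leak
information between training and testing partitions.

SNV removes per-spectrum multiplicative scatter and additive baseline
effects (particle size, surface scattering, optical path) by centering each
spectrum to mean 0 and scaling to unit sample standard deviation.

5-3 smoothing is Savitzky–Golay least-squares smoothing with a 5-point
window and a 3rd-order polynomial: at interior points it is the convolution
kernel (-3, 12, 17, 12, -3)/35; at the two points on each boundary the
window polynomial is refit and evaluated at the boundary positions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateInputError
from .segmentation import SpectraTable

__all__ = ["snv", "sg53", "apply_preprocessing", "PREPROCESSORS"]


def snv(table: SpectraTable) -> SpectraTable:
    """Standard normal variate: per-row center to mean 0, scale to sd 1.

    Uses the sample standard deviation (denominator B - 1).  Idempotent, and
    invariant to any per-spectrum affine distortion a*x + b with a > 0.
    """
    X = table.spectra
    sd = X.std(axis=1, ddof=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise DegenerateInputError(
            f"constant spectrum in row(s) {flat.tolist()}: SNV undefined"
        )
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(table, spectra=out, preprocessing="snv")


def sg53(table: SpectraTable, passes: int = 1) -> SpectraTable:
    """5-point / 3rd-order Savitzky–Golay smoothing, *passes* times (default 1).

    Exact on cubic polynomials sampled on an even grid.  Boundary points use
    the fitted window polynomial evaluated at the edge positions
    (``mode='interp'``).
    """
    if table.grid.count < 5:
        raise ValueError("5-point smoothing needs at least 5 bands")
    out = table.spectra
    for _ in range(passes):
        out = savgol_filter(out, window_length=5, polyorder=3, axis=1, mode="interp")
    return replace(table, spectra=out, preprocessing="sg53")


PREPROCESSORS = {
    "none": lambda t: replace(t, preprocessing="none"),
    "snv": snv,
    "sg53": sg53,
}


def apply_preprocessing(table: SpectraTable, name: str) -> SpectraTable:
    """Apply a preprocessing arm by name: ``none``, ``snv`` or ``sg53``."""
    try:
        return PREPROCESSORS[name](table)
    except KeyError:
        raise ValueError(
            f"unknown preprocessing {name!r}; choose from {sorted(PREPROCESSORS)}"
        ) from None
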