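"""Feature-wavelength selection: SPA, 2DCOS autocorrelation peaks, fusion.

Three selectors are provided, mirroring the chemometric workflow for
freeze-damage discrimination:

* **SPA** (successive projections algorithm) — forward selection that, at
  each step, appends the band whose column has the largest norm after
  orthogonal projection onto the complement of the already-selected bands,
  minimizing collinearity of the chosen subset.  Candidate subsets (every
  start band, every chain length in a 1..20 range) are scored by stratified
  cross-validated misclassification of a linear discriminant on the
  *training* partition only.

* **2DCOS** — two-dimensional correlation spectroscopy, treating the
  freeze-damage severity (normal -> slight -> severe) as the external
  perturbation.  The synchronous spectrum is the covariance of the
  mean-removed (dynamic) class-mean spectra; the autocorrelation curve on
  its diagonal peaks at the wavelengths most responsive to the
  perturbation.

* **SPA+2DCOS fusion** — the sorted, de-duplicated union of the two
  wavelength sets, combining SPA's low-redundancy subsets with 2DCOS's
  sensitivity to weak responses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .cube_io import WavelengthGrid
from .errors import ConfigError, DegenerateInputError
from .segmentation import SpectraTable

__all__ = [
    "SelectionResult",
    "SyncSpectrum",
    "spa_chain",
    "spa_select",
    "sync_spectrum",
    "autocorr_peaks",
    "fuse",
    "twodcos_select",
]


@dataclass
class SelectionResult:
    """An ordered set of selected wavelengths with per-wavelength provenance."""

    method: str
    wavelengths_nm: np.ndarray
    band_indices: np.ndarray | None = None
    provenance: dict[float, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        order = np.argsort(wl)
        self.wavelengths_nm = wl[order]
        if self.band_indices is not None:
            idx = np.asarray(self.band_indices, dtype=np.int64)[order]
            if np.unique(idx).size != idx.size:
                raise ValueError("band indices must be unique")
            self.band_indices = idx
        if not self.provenance:
            self.provenance = {float(w): (self.method,) for w in self.wavelengths_nm}

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @classmethod
    def from_bands(
        cls, method: str, indices, grid: WavelengthGrid
    ) -> "SelectionResult":
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=np.int64)
        return cls(method, grid.centers[idx], idx)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "wavelengths_nm": self.wavelengths_nm.tolist(),
                "band_indices": (
                    None
                    if self.band_indices is None
                    else self.band_indices.tolist()
                ),
                "provenance": {
                    f"{w:g}": list(tags) for w, tags in self.provenance.items()
                },
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_csv_line(self) -> str:
        """One-line CSV for quick diffing: method, count, wavelength list."""
        wl = ", ".join(f"{w:g}" for w in self.wavelengths_nm)
        return f"{self.method},{len(self)},\"{wl}\""


@dataclass
class SyncSpectrum:
    """Synchronous 2D correlation spectrum over an ordered perturbation series."""

    phi: np.ndarray
    grid: WavelengthGrid
    series_length: int

    def __post_init__(self) -> None:
        if np.abs(self.phi - self.phi.T).max() > 1e-10:
            raise ValueError("synchronous spectrum must be symmetric")

    @property
    def diagonal(self) -> np.ndarray:
        """Autocorrelation curve phi(v, v)."""
        return np.diag(self.phi)


def spa_chain(X: np.ndarray, start_band: int, max_len: int) -> list[int]:
    """Classic SPA projection recursion from one start band.

    Columns of *X* are mean-centered, the chain begins at ``start_band``,
    and each step appends the unselected column with the largest norm after
    projecting all columns onto the orthogonal complement of the selected
    set (sequential Gram–Schmidt deflation).  Ties break toward the lowest
    band index.
    """
    X = np.asarray(X, dtype=float)
    n, B = X.shape
    if not 1 <= max_len <= B:
        raise ValueError(f"max_len must be in [1, {B}]")
    if not 0 <= start_band < B:
        raise ValueError(f"start_band {start_band} out of range [0, {B})")
    P = X - X.mean(axis=0, keepdims=True)
    chain = [int(start_band)]
    selected = np.zeros(B, dtype=bool)
    selected[start_band] = True
    for _ in range(max_len - 1):
        p = P[:, chain[-1]].copy()
        pp = p @ p
        if pp > 0:
            P = P - np.outer(p, (p @ P) / pp)
        norms = np.einsum("ij,ij->j", P, P)
        norms[selected] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 0:
            break  # remaining columns are in the span of the chain
        chain.append(nxt)
        selected[nxt] = True
    return chain


def _cv_misclassification(
    X: np.ndarray, y: np.ndarray, folds: list[tuple[np.ndarray, np.ndarray]]
) -> float:
    errors = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear subsets are expected
        for tr, te in folds:
            clf = LinearDiscriminantAnalysis()
            clf.fit(X[tr], y[tr])
            errors += int(np.sum(clf.predict(X[te]) != y[te]))
    return errors / len(y)


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    grid: WavelengthGrid,
    k_min: int = 1,
    k_max: int = 20,
    cv_folds: int = 5,
) -> SelectionResult:
    """SPA wavelength selection over chain lengths ``k_min..k_max``.

    For every start band and every chain length k, the candidate subset
    (the first k bands of that start's projection chain) is scored by
    stratified ``cv_folds``-fold cross-validated misclassification of a
    linear discriminant; the minimizing subset wins, with ties broken
    toward smaller k and then the smaller start index.  Fully
    deterministic: folds are unshuffled.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, B = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if n < classes.size:
        raise ValueError("need at least one sample per class")
    if not 1 <= k_min <= k_max <= B:
        raise ValueError(f"need 1 <= k_min <= k_max <= {B}")
    if counts.min() < cv_folds:
        raise ConfigError(
            f"smallest class has {counts.min()} samples < {cv_folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=False)
    folds = list(skf.split(X, y))

    best = (np.inf, -1, -1)  # (score, k, start)
    best_subset: list[int] | None = None
    for start in range(B):
        chain = spa_chain(X, start, k_max)
        for k in range(k_min, min(k_max, len(chain)) + 1):
            subset = chain[:k]
            score = _cv_misclassification(X[:, subset], y, folds)
            key = (score, k, start)
            if key < best:
                best = key
                best_subset = subset
    assert best_subset is not None
    return SelectionResult.from_bands("SPA", best_subset, grid)


def sync_spectrum(series: np.ndarray, grid: WavelengthGrid) -> SyncSpectrum:
    """Synchronous 2D correlation spectrum of an ordered perturbation series.

    ``series`` is an (m, B) stack of spectra ordered along the external
    perturbation.  Dynamic spectra are deviations from the series mean; the
    synchronous spectrum is ``phi = dynamic.T @ dynamic / (m - 1)`` (Noda's
    normalization — any positive constant leaves peak positions unchanged).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise DegenerateInputError("perturbation series needs at least 2 spectra")
    if series.shape[1] != grid.count:
        raise ValueError("series band count does not match the grid")
    m = series.shape[0]
    dyn = series - series.mean(axis=0, keepdims=True)
    phi = dyn.T @ dyn / (m - 1)
    phi = (phi + phi.T) / 2  # kill rounding asymmetry
    return SyncSpectrum(phi, grid, m)


def autocorr_peaks(
    sync: SyncSpectrum, min_rel_prominence: float = 0.05
) -> SelectionResult:
    """Local maxima of the diagonal autocorrelation curve.

    Keeps peaks whose prominence is at least ``min_rel_prominence`` times
    the curve's maximum; a flat diagonal yields an empty selection.
    """
    diag = sync.diagonal
    top = diag.max()
    if top <= 0 or np.allclose(diag, diag[0]):
        return SelectionResult("2DCOS", np.empty(0), np.empty(0, dtype=np.int64))
    idx, _ = find_peaks(diag, prominence=min_rel_prominence * top)
    return SelectionResult.from_bands("2DCOS", idx, sync.grid)


def twodcos_select(
    table: SpectraTable, min_rel_prominence: float = 0.05
) -> SelectionResult:
    """2DCOS selection with freeze severity as the external perturbation.

    The perturbation series is the per-class mean spectrum ordered by
    increasing severity (class label 1 -> 2 -> 3).
    """
    classes = np.unique(table.labels)
    if classes.size < 2:
        raise DegenerateInputError("need >= 2 severity classes for a series")
    series = np.stack(
        [table.spectra[table.labels == c].mean(axis=0) for c in classes]
    )
    return autocorr_peaks(sync_spectrum(series, table.grid), min_rel_prominence)


def fuse(a: SelectionResult, b: SelectionResult) -> SelectionResult:
    """Sorted, de-duplicated union of two selections on the same grid.

    Provenance tags are merged per wavelength, so a band found by both
    methods carries both tags.
    """
    if a.band_indices is not None and b.band_indices is not None:
        pairs = {
            (float(w), int(i))
            for w, i in zip(a.wavelengths_nm, a.band_indices)
        } | {(float(w), int(i)) for w, i in zip(b.wavelengths_nm, b.band_indices)}
        for w in set(w for w, _ in pairs):
            if sum(1 for ww, _ in pairs if ww == w) > 1:
                raise ValueError(f"grid mismatch: wavelength {w} maps to two bands")
        wl = np.array(sorted(w for w, _ in pairs))
        idx = np.array([i for _, i in sorted(pairs)], dtype=np.int64)
    else:
        wl = np.array(sorted(set(a.wavelengths_nm) | set(b.wavelengths_nm)))
        idx = None
    prov: dict[float, tuple[str, ...]] = {}
    for w in wl:
        tags = a.provenance.get(float(w), ()) + b.provenance.get(float(w), ())
        prov[float(w)] = tuple(dict.fromkeys(tags)) or ("fused",)
    method = f"{a.method}+{b.method}" if a.method and b.method else "SPA+2DCOS"
    return SelectionResult(method, wl, idx, prov)
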