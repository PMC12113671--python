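import numpy as np
import pytest

import seedfrost as sf
from seedfrost.errors import ConfigError, DegenerateInputError
from seedfrost.selection import _cv_misclassification

from oracles import spa_chain_gram_schmidt, sync_spectrum_loops
from reference_data import WAVELENGTH_SETS


def grid_of(n):
    return sf.WavelengthGrid(np.linspace(450, 979, n))


class TestSpaChain:
    def test_orthogonal_columns_by_descending_norm(self):
        # mutually orthogonal columns of norms 3 > 2 > 1 (already centered)
        X = np.zeros((6, 3))
        X[0:2, 0] = [3 / np.sqrt(2), -3 / np.sqrt(2)]
        X[2:4, 1] = [2 / np.sqrt(2), -2 / np.sqrt(2)]
        X[4:6, 2] = [1 / np.sqrt(2), -1 / np.sqrt(2)]
        assert sf.spa_chain(X, start_band=0, max_len=3) == [0, 1, 2]

    def test_duplicated_column_never_follows_its_twin(self, rng):
        X = rng.random((8, 4))
        X[:, 3] = X[:, 0]  # exact collinearity
        chain = sf.spa_chain(X, start_band=0, max_len=4)
        assert 3 not in chain[:2]
        # the duplicate has zero projected norm and is never selected
        assert 3 not in chain

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_gram_schmidt_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 5))
        for start in range(5):
            assert sf.spa_chain(X, start, 5) == spa_chain_gram_schmidt(X, start, 5)

    def test_invariant_to_common_positive_rescale(self, rng):
        X = rng.normal(size=(10, 6))
        assert sf.spa_chain(X, 2, 6) == sf.spa_chain(1000.0 * X, 2, 6)

    def test_max_len_out_of_range(self, rng):
        with pytest.raises(ValueError):
            sf.spa_chain(rng.random((4, 3)), 0, 4)


class TestSpaSelect:
    def test_single_band_equals_exhaustive_search(self, small_table):
        table, _ = small_table
        X, y = table.spectra, table.labels
        got = sf.spa_select(X, y, table.grid, k_min=1, k_max=1)
        from sklearn.model_selection import StratifiedKFold

        folds = list(StratifiedKFold(5, shuffle=False).split(X, y))
        scores = [
            _cv_misclassification(X[:, [j]], y, folds) for j in range(X.shape[1])
        ]
        assert got.band_indices.tolist() == [int(np.argmin(scores))]

    def test_selected_size_within_one_to_twenty(self, small_table):
        table, _ = small_table
        sel = sf.spa_select(table.spectra, table.labels, table.grid)
        assert 1 <= len(sel) <= 20

    def test_small_class_vs_folds_is_config_error(self, rng):
        X = rng.random((9, 6))
        y = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        with pytest.raises(ConfigError, match="folds"):
            sf.spa_select(X, y, grid_of(6), k_max=3, cv_folds=5)

    def test_recovers_planted_signal_bands(self):
        """3 signal bands among pure-noise bands are found nearly always."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 120
            y = np.repeat([1, 2, 3], n // 3)
            X = rng.normal(0, 1.0, size=(n, 15))
            # one-vs-rest contrast per signal band: each adds information
            for j, cls in zip((2, 7, 11), (1, 2, 3)):
                X[:, j] = 2.5 * (y == cls) + rng.normal(0, 1.2, n)
            sel = sf.spa_select(X, y, grid_of(15), k_min=1, k_max=6)
            if {2, 7, 11} <= set(sel.band_indices.tolist()):
                hits += 1
        assert hits >= 0.95 * n_rep


class TestSyncSpectrum:
    def test_hand_computed_two_by_two(self):
        series = np.array([[0.0, 0.0], [2.0, 4.0]])
        sync = sf.sync_spectrum(series, sf.WavelengthGrid(np.array([500.0, 600.0])))
        np.testing.assert_allclose(sync.phi, [[2.0, 4.0], [4.0, 8.0]])

    def test_symmetric_nonnegative_diagonal(self, rng):
        series = rng.random((5, 12))
        sync = sf.sync_spectrum(series, grid_of(12))
        np.testing.assert_allclose(sync.phi, sync.phi.T, atol=1e-12)
        assert (sync.diagonal >= 0).all()

    def test_identical_spectra_give_zero(self):
        series = np.tile(np.linspace(0, 1, 8), (4, 1))
        sync = sf.sync_spectrum(series, grid_of(8))
        np.testing.assert_allclose(sync.phi, 0.0, atol=1e-15)

    def test_single_spectrum_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sf.sync_spectrum(np.ones((1, 8)), grid_of(8))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_explicit_double_sum(self, seed):
        series = np.random.default_rng(seed).random((4, 9))
        sync = sf.sync_spectrum(series, grid_of(9))
        np.testing.assert_allclose(sync.phi, sync_spectrum_loops(series), atol=1e-12)


class TestAutocorrPeaks:
    def _sync_with_diag(self, diag):
        B = diag.size
        return sf.SyncSpectrum(
            np.diag(diag).astype(float), grid_of(B), series_length=3
        )

    def test_single_bump_single_peak(self):
        x = np.arange(200.0)
        diag = np.exp(-(((x - 100) / 10) ** 2))
        sync = self._sync_with_diag(diag)
        sel = sf.autocorr_peaks(sync)
        assert sel.band_indices.tolist() == [100]

    def test_two_bumps_two_peaks(self):
        x = np.arange(200.0)
        diag = np.exp(-(((x - 50) / 8) ** 2)) + 0.7 * np.exp(-(((x - 150) / 8) ** 2))
        sel = sf.autocorr_peaks(self._sync_with_diag(diag))
        assert sel.band_indices.tolist() == [50, 150]

    def test_flat_diagonal_empty(self):
        sel = sf.autocorr_peaks(self._sync_with_diag(np.full(50, 0.3)))
        assert len(sel) == 0

    def test_generator_class_means_peak_at_planted_features(self, small_table):
        table, truth = small_table
        sel = sf.twodcos_select(table)
        spacing = np.diff(table.grid.centers).mean()
        for center in truth.informative_centers_nm:
            assert np.min(np.abs(sel.wavelengths_nm - center)) <= 2 * spacing


class TestFuse:
    @pytest.mark.parametrize("key", sorted(WAVELENGTH_SETS))
    def test_published_fused_counts(self, key):
        sets = WAVELENGTH_SETS[key]
        a = sf.SelectionResult("SPA", np.array(sets["spa"], float))
        b = sf.SelectionResult("2DCOS", np.array(sets["2dcos"], float))
        fused = sf.fuse(a, b)
        assert len(fused) == sets["fused_count"]
        assert fused.method == "SPA+2DCOS"
        assert fused.wavelengths_nm.tolist() == sorted(
            set(sets["spa"]) | set(sets["2dcos"])
        )

    def test_dedup(self):
        a = sf.SelectionResult("SPA", np.array([500.0, 600.0]))
        b = sf.SelectionResult("2DCOS", np.array([600.0, 700.0]))
        fused = sf.fuse(a, b)
        assert fused.wavelengths_nm.tolist() == [500.0, 600.0, 700.0]
        assert fused.provenance[600.0] == ("SPA", "2DCOS")

    def test_empty_is_identity(self):
        a = sf.SelectionResult("SPA", np.array([500.0, 600.0]))
        e = sf.SelectionResult("2DCOS", np.empty(0))
        assert sf.fuse(a, e).wavelengths_nm.tolist() == [500.0, 600.0]

    def test_cardinality_bound(self, rng):
        """|a u b| <= |a| + |b|, equality iff the sets are disjoint."""
        for _ in range(10):
            wa = rng.choice(np.arange(450, 980, 10.0), 5, replace=False)
            wb = rng.choice(np.arange(450, 980, 10.0), 5, replace=False)
            fused = sf.fuse(
                sf.SelectionResult("SPA", wa), sf.SelectionResult("2DCOS", wb)
            )
            overlap = len(set(wa) & set(wb))
            assert len(fused) == 10 - overlap


def test_selection_result_json_round_trip(tmp_path, small_table):
    import json

    table, _ = small_table
    sel = sf.twodcos_select(table)
    path = tmp_path / "sel.json"
    sel.to_json(path)
    data = json.loads(path.read_text())
    assert data["method"] == "2DCOS"
    assert data["band_indices"] == sel.band_indices.tolist()
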