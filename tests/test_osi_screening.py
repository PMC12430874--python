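"""Correlation machinery: scalar Pearson, streaming pair/triad searches
against naive enumeration, significance filtering."""

import itertools

import numpy as np
import pytest

from osiscan import (
    SpectrumSet,
    TraitVector,
    WavelengthGrid,
    pearson_r,
    refine_triples,
    screen_pairs,
    screen_triples,
    select_significant,
)
from osiscan.errors import ConfigurationError, UndefinedCorrelationError
from osiscan.spectral_indices import PAIR_FORMS, TRIPLE_FORMS, eval_pair, eval_triple
from conftest import naive_pearson


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r2, _ = pearson_r(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_frozen_textbook_value(self):
        # value frozen from the covariance/SD formula:
        # x=(1..5), y=(2,1,4,3,5): cov=2, sd_x=sqrt(2.5), sd_y=sqrt(2.5) -> r=0.8
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        r, p = pearson_r(x, y)
        assert r == pytest.approx(0.8, abs=1e-12)
        assert 0 < p <= 1

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_nan_samples_dropped_before_correlation(self):
        x = np.array([1.0, 2, np.nan, 4, 5, 6])
        y = np.array([2.0, 4, 100.0, 8, 10, 12])
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(1.0)

    def test_too_few_defined_pairs(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, 3.0]))


def _naive_best_pair(spectra, trait, form):
    wl = spectra.grid.wavelengths
    pf = PAIR_FORMS[form]
    best = (-1.0, None, None)
    for i, j in itertools.product(wl, wl):
        if pf.antisymmetric and j < i:
            continue
        r = naive_pearson(eval_pair(spectra, form, i, j).values, trait.lnc)
        if np.isfinite(r) and (abs(r) > best[0] or (abs(r) == best[0] and (i, j) < best[1])):
            best = (abs(r), (i, j), r)
    return best


def _naive_best_triple(spectra, trait, form):
    wl = spectra.grid.wavelengths
    tf = TRIPLE_FORMS[form]
    best = (-1.0, None, None)
    for i, j, k in itertools.product(wl, repeat=3):
        if tf.symmetry == "jk" and k < j:
            continue
        if tf.symmetry == "full" and not (i <= j <= k):
            continue
        r = naive_pearson(eval_triple(spectra, form, i, j, k).values, trait.lnc)
        if np.isfinite(r) and (abs(r) > best[0] or (abs(r) == best[0] and (i, j, k) < best[1])):
            best = (abs(r), (i, j, k), r)
    return best


class TestOracleEquivalence:
    @pytest.mark.parametrize("form", sorted(PAIR_FORMS))
    def test_pair_screening_matches_naive_enumeration(self, toy_spectra, toy_trait, form):
        _, res = screen_pairs(toy_spectra, toy_trait, form, stride=19.0)
        absr, bands, r = _naive_best_pair(toy_spectra, toy_trait, form)
        assert tuple(res.best_bands) == bands
        assert res.best_r == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("form", sorted(TRIPLE_FORMS))
    @pytest.mark.parametrize("method", ["moments", "direct"])
    def test_triple_screening_matches_naive_enumeration(
        self, toy_spectra, toy_trait, form, method
    ):
        _, res = screen_triples(toy_spectra, toy_trait, form, stride=19.0, method=method)
        absr, bands, r = _naive_best_triple(toy_spectra, toy_trait, form)
        assert tuple(res.best_bands) == bands
        assert res.best_r == pytest.approx(r, abs=1e-12)

    def test_triple_chunk_size_does_not_change_result(self, toy_spectra, toy_trait):
        results = [
            screen_triples(toy_spectra, toy_trait, "DTSI", stride=19.0, method="direct", chunk=c)[1]
            for c in (1, 5, 64)
        ]
        for res in results[1:]:
            assert tuple(res.best_bands) == tuple(results[0].best_bands)
            assert res.best_r == results[0].best_r

    def test_top_k_set_matches_naive(self, toy_spectra, toy_trait):
        wl = toy_spectra.grid.wavelengths
        _, res = screen_pairs(toy_spectra, toy_trait, "NDSI", stride=19.0, top_k=10)
        ranked = []
        for i, j in itertools.product(wl, wl):
            if j < i:
                continue
            r = naive_pearson(eval_pair(toy_spectra, "NDSI", i, j).values, toy_trait.lnc)
            if np.isfinite(r):
                ranked.append((abs(r), (i, j), r))
        ranked.sort(key=lambda e: (-e[0], e[1]))
        expect = {e[1] for e in ranked[:10]}
        got = {tuple(e["bands"]) for e in res.top_k}
        assert got == expect


class TestScreeningContracts:
    def test_constant_trait_rejected(self, toy_spectra):
        flat = TraitVector(toy_spectra.sample_ids, np.full(toy_spectra.n_samples, 30.0))
        with pytest.raises(UndefinedCorrelationError):
            screen_triples(toy_spectra, flat, "DTSI", stride=19.0)

    def test_negating_trait_flips_sign_keeps_bands(self, toy_spectra, toy_trait):
        _, res = screen_pairs(toy_spectra, toy_trait, "NDSI", stride=19.0)
        flipped = TraitVector(toy_spectra.sample_ids, 80.0 - toy_trait.lnc)
        _, res2 = screen_pairs(toy_spectra, flipped, "NDSI", stride=19.0)
        assert tuple(res2.best_bands) == tuple(res.best_bands)
        assert res2.best_r == pytest.approx(-res.best_r, abs=1e-10)

    def test_coarser_stride_never_beats_stride_one(self, toy_spectra, toy_trait):
        _, fine = screen_pairs(toy_spectra, toy_trait, "NDSI", stride=19.0)
        _, coarse = screen_pairs(toy_spectra, toy_trait, "NDSI", stride=38.0)
        assert abs(coarse.best_r) <= abs(fine.best_r) + 1e-15

    def test_stride_must_divide_grid(self, toy_spectra, toy_trait):
        with pytest.raises(ConfigurationError):
            screen_pairs(toy_spectra, toy_trait, "NDSI", stride=7.0)

    def test_dense_matrix_shape_and_bounds(self, toy_spectra, toy_trait):
        cmap, _ = screen_pairs(toy_spectra, toy_trait, "NDSI", stride=19.0)
        m = len(toy_spectra.grid)
        assert cmap.matrix.shape == (m, m)
        finite = cmap.matrix[np.isfinite(cmap.matrix)]
        assert np.all(np.abs(finite) <= 1 + 1e-12)

    def test_refine_matches_naive_box_search_and_never_degrades(self, canopy):
        from osiscan import PlantedSignal, plant_index_signal

        spectra, _ = canopy
        y = plant_index_signal(spectra, PlantedSignal("DTSI", (833.0, 756.0, 802.0)), seed=3)
        _, coarse = screen_triples(
            spectra, y, "DTSI", stride=5.0, search_range=(740.0, 860.0)
        )
        refined = refine_triples(spectra, y, coarse, radius=5.0)
        assert abs(refined.best_r) >= abs(coarse.best_r) - 1e-12
        # stride-1 naive enumeration of the +/-5 nm box around the coarse bands
        g = spectra.grid.wavelengths
        windows = [g[(g >= b - 5) & (g <= b + 5)] for b in coarse.best_bands]
        best = (-1.0, None, None)
        for i in windows[0]:
            for j in windows[1]:
                for k in windows[2]:
                    if k < j:
                        continue
                    r = naive_pearson(
                        eval_triple(spectra, "DTSI", i, j, k).values, y.lnc
                    )
                    if np.isfinite(r) and (
                        abs(r) > best[0] or (abs(r) == best[0] and (i, j, k) < best[1])
                    ):
                        best = (abs(r), (i, j, k), r)
        assert tuple(refined.best_bands) == best[1]
        assert refined.best_r == pytest.approx(best[2], abs=1e-12)


class TestSelectSignificant:
    def test_threshold_semantics(self):
        entries = [("A", 0.5, 0.049), ("B", 0.4, 0.051)]
        assert select_significant(entries, alpha=0.05) == [("A", 0.5, 0.049)]

    def test_order_preserved_and_empty_ok(self):
        entries = [("C", 0.2, 0.01), ("A", 0.9, 0.001), ("B", 0.1, 0.2)]
        kept = select_significant(entries, alpha=0.05)
        assert [e[0] for e in kept] == ["C", "A"]
        assert select_significant([], 0.05) == []
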