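"""Index formula arithmetic, algebraic identities, and undefined-value flags."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osiscan import SpectrumSet, WavelengthGrid, eval_empirical, eval_pair, eval_triple
from osiscan.spectral_indices import EMPIRICAL_FORMS, registry_to_json
import json


def _spectrum_with(values: dict, fill=0.4, n_extra=0):
    """Single-sample SpectrumSet over the full 1 nm grid with chosen band values."""
    grid = WavelengthGrid.regular(350, 1830, 1)
    R = np.full((1 + n_extra, len(grid)), fill)
    for wl, v in values.items():
        R[0, int(wl) - 350] = v
    return SpectrumSet([f"s{i}" for i in range(1 + n_extra)], grid, R)


class TestEmpirical:
    def test_flat_spectrum_cancellations(self):
        spectra = _spectrum_with({}, fill=0.4)
        assert eval_empirical(spectra, "DDn").values[0] == pytest.approx(0.0)
        assert eval_empirical(spectra, "DDI").values[0] == pytest.approx(0.0)
        assert eval_empirical(spectra, "RDVI").values[0] == pytest.approx(0.0)
        assert eval_empirical(spectra, "CI").values[0] == pytest.approx(1.0)
        # flat spectrum makes the MNDSI denominator (R800+R680-2*R445) vanish
        # exactly as well, so the value is flagged undefined rather than 0
        assert np.isnan(eval_empirical(spectra, "MNDSI").values[0])

    def test_mndsi_numerator_cancellation(self):
        spectra = _spectrum_with({800: 0.4, 680: 0.4, 445: 0.3})
        assert eval_empirical(spectra, "MNDSI").values[0] == pytest.approx(0.0, abs=1e-12)

    def test_mtci_hand_value(self):
        spectra = _spectrum_with({754: 0.5, 709: 0.3, 681: 0.2})
        assert eval_empirical(spectra, "MTCI").values[0] == pytest.approx(2.0, abs=1e-12)

    def test_ddn_follows_canonical_definition(self):
        spectra = _spectrum_with({710: 0.30, 660: 0.10, 760: 0.45})
        expected = 2 * 0.30 - 0.10 - 0.45
        assert eval_empirical(spectra, "DDn").values[0] == pytest.approx(expected, abs=1e-12)

    def test_gitelson2_hand_value(self):
        spectra = _spectrum_with({687: 0.25, 500: 0.10, 750: 0.50})
        assert eval_empirical(spectra, "Gitelson2").values[0] == pytest.approx(0.3, abs=1e-12)

    def test_all_seven_forms_registered(self):
        assert set(EMPIRICAL_FORMS) == {"DDI", "MNDSI", "DDn", "RDVI", "CI", "MTCI", "Gitelson2"}


class TestPairForms:
    def test_identity_band_values(self):
        spectra = _spectrum_with({}, fill=0.4)
        assert eval_pair(spectra, "NDSI", 700, 700).values[0] == 0.0
        assert eval_pair(spectra, "DSI", 700, 700).values[0] == 0.0
        assert eval_pair(spectra, "SASI", 700, 700).values[0] == 0.0
        assert eval_pair(spectra, "RSI", 700, 700).values[0] == 1.0

    def test_hand_values(self):
        spectra = _spectrum_with({600: 0.6, 640: 0.2, 680: 0.3})
        assert eval_pair(spectra, "NDSI", 600, 640).values[0] == pytest.approx(0.5, abs=1e-12)
        assert eval_pair(spectra, "RSI", 600, 640).values[0] == pytest.approx(3.0, abs=1e-12)
        assert eval_triple(spectra, "DTSI", 600, 640, 680).values[0] == pytest.approx(0.1, abs=1e-12)
        assert eval_triple(spectra, "RTSI", 600, 640, 680).values[0] == pytest.approx(10.0, abs=1e-12)

    def test_tsi_anchored_cancellation(self):
        # Ri = Rj = R550 makes both triangle legs vanish
        spectra = _spectrum_with({}, fill=0.33)
        assert eval_pair(spectra, "TSI", 800, 900).values[0] == pytest.approx(0.0, abs=1e-12)

    def test_sasi_soil_adjustment_constant(self):
        spectra = _spectrum_with({700: 0.5, 710: 0.1})
        expected = 1.16 * (0.5 - 0.1) / (0.5 + 0.1 + 0.16)
        assert eval_pair(spectra, "SASI", 700, 710).values[0] == pytest.approx(expected, abs=1e-12)

    def test_near_zero_denominator_flags_sample_not_inf(self):
        spectra = _spectrum_with({709: 0.3, 681: 0.3})  # MTCI denominator 0
        vals = eval_empirical(spectra, "MTCI").values
        assert np.isnan(vals[0])
        spectra2 = _spectrum_with({600: 0.0, 640: 0.0})
        assert np.isnan(eval_pair(spectra2, "NDSI", 600, 640).values[0])
        assert np.isnan(eval_triple(spectra2, "RATSI", 600, 640, 680).values[0])


class TestTripleForms:
    def test_unit_reflectance_values(self):
        spectra = _spectrum_with({}, fill=1.0)
        assert eval_triple(spectra, "RATSI", 700, 800, 900).values[0] == pytest.approx(3.0)
        assert eval_triple(spectra, "RDTSI", 700, 800, 900).values[0] == pytest.approx(-1.0)
        assert eval_triple(spectra, "RTSI", 700, 800, 900).values[0] == pytest.approx(1.0)
        assert eval_triple(spectra, "DTSI", 700, 800, 900).values[0] == pytest.approx(-1.0)

    def test_equal_band_dtsi_identity(self):
        spectra = _spectrum_with({}, fill=0.27)
        assert eval_triple(spectra, "DTSI", 700, 700, 700).values[0] == pytest.approx(-0.27)


@st.composite
def reflectance_rows(draw, m=8):
    vals = draw(
        st.lists(st.floats(0.02, 1.0), min_size=2 * m, max_size=2 * m)
    )
    return np.array(vals).reshape(2, m)


@settings(deadline=None, max_examples=50)
@given(R=reflectance_rows())
def test_algebraic_symmetries(R):
    grid = WavelengthGrid(500.0 + 10.0 * np.arange(R.shape[1]))
    spectra = SpectrumSet(["a", "b"], grid, R)
    i, j, k = 500.0, 530.0, 570.0
    rsi_ij = eval_pair(spectra, "RSI", i, j).values
    rsi_ji = eval_pair(spectra, "RSI", j, i).values
    assert np.allclose(rsi_ij * rsi_ji, 1.0, atol=1e-10)
    ndsi_ij = eval_pair(spectra, "NDSI", i, j).values
    ndsi_ji = eval_pair(spectra, "NDSI", j, i).values
    assert np.allclose(ndsi_ij, -ndsi_ji, atol=1e-12)
    assert np.all(np.abs(ndsi_ij) <= 1.0 + 1e-12)
    dsi = eval_pair(spectra, "DSI", i, j).values
    assert np.allclose(dsi, -eval_pair(spectra, "DSI", j, i).values, atol=1e-12)
    # DTSI(i, j, k) = DSI(i, j) - Rk
    dtsi = eval_triple(spectra, "DTSI", i, j, k).values
    assert np.allclose(dtsi, dsi - spectra.band(k), atol=1e-12)
    # RATSI invariant under any permutation
    base = eval_triple(spectra, "RATSI", i, j, k).values
    for perm in [(j, i, k), (k, j, i), (j, k, i)]:
        assert np.allclose(base, eval_triple(spectra, "RATSI", *perm).values, atol=1e-12)


def test_vectorized_matches_per_sample(toy_spectra):
    whole = eval_triple(toy_spectra, "RTSI", 474.0, 512.0, 588.0).values
    for s in range(toy_spectra.n_samples):
        single = toy_spectra.select_samples([toy_spectra.sample_ids[s]])
        one = eval_triple(single, "RTSI", 474.0, 512.0, 588.0).values[0]
        assert one == pytest.approx(whole[s], abs=1e-14)


def test_registry_serializes_to_json():
    entries = json.loads(registry_to_json())
    assert {e["name"] for e in entries if e["arity"] == 3} == {"RTSI", "DTSI", "RDTSI", "RATSI"}
    assert all("arity" in e for e in entries)
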