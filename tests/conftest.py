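import numpy as np
import pytest

from osiscan import SpectrumSet, SynthConfig, TraitVector, WavelengthGrid, generate_canopy_dataset

#: 12-band uniform toy grid (step 19 nm) that contains both anchor bands
#: 455 nm (mSR/mNDI) and 550 nm (TSI): 455 + 19k for k = 0..11.
TOY_WAVELENGTHS = 455.0 + 19.0 * np.arange(12)


@pytest.fixture
def toy_spectra():
    rng = np.random.default_rng(42)
    n = 20
    return SpectrumSet(
        [f"s{i}" for i in range(n)],
        WavelengthGrid(TOY_WAVELENGTHS),
        rng.uniform(0.05, 0.9, (n, TOY_WAVELENGTHS.size)),
    )


@pytest.fixture
def toy_trait(toy_spectra):
    rng = np.random.default_rng(7)
    return TraitVector(toy_spectra.sample_ids, rng.uniform(15.0, 50.0, toy_spectra.n_samples))


@pytest.fixture(scope="session")
def canopy():
    """One 66-sample synthetic campaign at the default field-like noise level."""
    return generate_canopy_dataset(SynthConfig(n_samples=66, seed=11))


@pytest.fixture(scope="session")
def canopy_noiseless():
    return generate_canopy_dataset(SynthConfig(n_samples=66, seed=11, noise_sd=0.0))


def naive_pearson(x, t):
    """Independent textbook two-pass Pearson r; NaN if undefined."""
    x = np.asarray(x, float)
    t = np.asarray(t, float)
    ok = np.isfinite(x) & np.isfinite(t)
    x, t = x[ok], t[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(t) == 0:
        return np.nan
    xc, tc = x - x.mean(), t - t.mean()
    return float((xc * tc).sum() / np.sqrt((xc * xc).sum() * (tc * tc).sum()))
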