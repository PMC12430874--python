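"""Synthetic canopy reflectance with nitrogen-coupled spectral features.

Real winter-wheat canopy spectra tie leaf nitrogen to chlorophyll, so three
couplings are built into the generator exactly: as leaf nitrogen
concentration (LNC) rises, the chlorophyll absorption well around 680 nm
deepens, the red-edge inflection shifts to longer wavelengths, and the NIR
plateau (760-900 nm) level rises.  The curve is a cheap smooth parametric
model -- visible baseline with pigment absorption, a logistic red edge, an
NIR plateau with Gaussian water dips -- not a radiative-transfer code; see
docs/methods.md for what it does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .spectra_io import SpectrumSet, TraitVector, WavelengthGrid
from . import spectral_indices as si

#: LNC value (mg g^-1) at which the nitrogen effect terms saturate to 1.
_LNC_SCALE = 50.0


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for one synthetic acquisition campaign.

    noise_sd is additive i.i.d. Gaussian reflectance noise per band,
    clipped back into [0, 1]; 0.005 is of the order of a well-calibrated
    field spectroradiometer's band-to-band scatter.
    """

    n_samples: int = 66
    seed: int = 0
    lnc_range: tuple[float, float] = (15.0, 50.0)
    noise_sd: float = 0.005
    grid: tuple[float, float, float] = (350.0, 1830.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigurationError("n_samples must be >= 4")
        lo, hi = self.lnc_range
        if not (0 < lo < hi):
            raise ConfigurationError(f"lnc_range must satisfy 0 < min < max, got {self.lnc_range}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        WavelengthGrid.regular(*self.grid)  # validates


@dataclass(frozen=True)
class PlantedSignal:
    """A known band-combination signal to bury in a trait vector."""

    form: str
    bands: tuple[float, ...]
    noise_sd: float = 0.0  # trait units (mg g^-1)

    def __post_init__(self) -> None:
        arity = si.form_arity(self.form)
        if arity not in (2, 3):
            raise ConfigurationError(f"{self.form}: planted signals need a 2- or 3-band form")
        if len(self.bands) != arity:
            raise ConfigurationError(
                f"{self.form} takes {arity} bands, got {len(self.bands)}"
            )


def _reflectance_curve(wl: np.ndarray, lnc: np.ndarray) -> np.ndarray:
    """Noise-free canopy reflectance, shape (n_samples, n_bands).

    u = LNC / 50 drives every nitrogen-coupled term monotonically.
    """
    u = (lnc / _LNC_SCALE)[:, None]
    lam = wl[None, :]

    # pigment absorption profile: red (chlorophyll a, ~670 nm) + blue bands
    absorb = np.exp(-(((lam - 670.0) / 45.0) ** 2)) + 0.9 * np.exp(-(((lam - 450.0) / 60.0) ** 2))
    absorb = np.clip(absorb, 0.0, 1.0)
    # visible baseline with a green bump at 560 nm, darkened by pigment content
    vis = (0.16 + 0.10 * np.exp(-(((lam - 560.0) / 50.0) ** 2))) * (1.0 - 0.55 * u * absorb)

    # red-edge logistic: inflection shifts 700 -> 725 nm as u goes 0 -> 1
    edge_center = 700.0 + 25.0 * u
    s = 1.0 / (1.0 + np.exp(-(lam - edge_center) / 12.0))

    # NIR plateau rises with nitrogen; water absorption dips carve the SWIR
    water = (
        1.0
        - 0.35 * np.exp(-(((lam - 1450.0) / 55.0) ** 2))
        - 0.12 * np.exp(-(((lam - 1200.0) / 60.0) ** 2))
        - 0.06 * np.exp(-(((lam - 970.0) / 45.0) ** 2))
    )
    plateau = (0.40 + 0.10 * u) * water

    return (1.0 - s) * vis + s * plateau


def generate_canopy_dataset(config: SynthConfig) -> tuple[SpectrumSet, TraitVector]:
    """Draw LNC uniformly over ``lnc_range`` and synthesize matching spectra.

    Identical configs give bitwise-identical output.  At ``noise_sd = 0``
    the nitrogen couplings (680 nm well, red-edge position, NIR level) hold
    exactly and monotonically.
    """
    grid = WavelengthGrid.regular(*config.grid)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lnc_range
    lnc = rng.uniform(lo, hi, size=config.n_samples)
    R = _reflectance_curve(grid.wavelengths, lnc)
    if config.noise_sd > 0:
        R = R + rng.normal(0.0, config.noise_sd, size=R.shape)
    R = np.clip(R, 1e-4, 1.0)
    ids = [f"S{i:03d}" for i in range(config.n_samples)]
    return SpectrumSet(ids, grid, R), TraitVector(ids, lnc)


def chlorophyll_well_depth(spectra: SpectrumSet) -> np.ndarray:
    """Depth of the 680 nm absorption well below the 640-760 nm continuum line."""
    r640, r680, r760 = (spectra.band(w) for w in (640.0, 680.0, 760.0))
    continuum = r640 + (r760 - r640) * (680.0 - 640.0) / (760.0 - 640.0)
    return continuum - r680


def red_edge_position(spectra: SpectrumSet) -> np.ndarray:
    """Wavelength of the steepest reflectance rise between 680 and 780 nm."""
    g = spectra.grid.wavelengths
    mask = (g >= 680.0) & (g <= 780.0)
    wl = g[mask]
    deriv = np.gradient(spectra.reflectance[:, mask], wl, axis=1)
    return wl[np.argmax(deriv, axis=1)]


def plant_index_signal(spectra: SpectrumSet, signal: PlantedSignal, seed: int = 0) -> TraitVector:
    """Build a trait whose only structure is one index at known bands.

    The index is evaluated per sample, mapped affinely (positive slope)
    onto the 15-50 mg g^-1 LNC scale -- Pearson correlation is invariant
    under that map, so at ``noise_sd = 0`` the correlation between the
    returned trait and the planted index is exactly 1 -- then Gaussian
    trait noise of sd ``noise_sd`` is added.
    """
    values = si.evaluate_form(spectra, signal.form, signal.bands).values
    if not np.all(np.isfinite(values)):
        raise DegenerateInputError("planted index undefined for some samples")
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0:
        raise DegenerateInputError("planted index is constant over the dataset")
    y = 15.0 + 35.0 * (values - lo) / (hi - lo)
    if signal.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, signal.noise_sd, size=y.size)
    return TraitVector(spectra.sample_ids, y)
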