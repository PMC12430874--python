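"""Spectra and trait containers, CSV I/O, replicate-scan reduction and Savitzky-Golay smoothing.

The on-disk dialect is a wide CSV: first column ``sample_id``, remaining
column headers integer wavelengths in nm, cells unitless reflectance
fractions.  Traits travel in a two-column CSV (``sample_id``, ``lnc_mg_g``).
Both are RFC-4180 output with '.' as the decimal separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

from .errors import (
    BandLookupError,
    ConfigurationError,
    DegenerateInputError,
    FormatError,
    SpectrumValidationError,
)

#: Calibration overshoot tolerated on ingestion (unitless reflectance).
REFLECTANCE_MAX = 1.2


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm (integers by default)."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ConfigurationError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise FormatError("wavelength grid must be strictly increasing with no duplicates")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def step(self) -> float:
        """Uniform grid step in nm; raises if the grid is non-uniform."""
        d = np.diff(self.wavelengths)
        if d.size == 0:
            raise ConfigurationError("single-band grid has no step")
        if not np.allclose(d, d[0]):
            raise ConfigurationError("grid is not uniformly spaced")
        return float(d[0])

    def index_of(self, nm: float, snap_tol: float = 1.0) -> int:
        """Index of the band at ``nm``, snapping to the nearest band within ``snap_tol`` nm."""
        idx = int(np.argmin(np.abs(self.wavelengths - nm)))
        if abs(self.wavelengths[idx] - nm) > snap_tol:
            raise BandLookupError(f"wavelength {nm} nm not on grid (nearest {self.wavelengths[idx]:.0f} nm)")
        return idx

    @classmethod
    def regular(cls, start: float = 350.0, stop: float = 1830.0, step: float = 1.0) -> "WavelengthGrid":
        if step <= 0 or stop <= start:
            raise ConfigurationError(f"invalid grid spec start={start} stop={stop} step={step}")
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


@dataclass
class SpectrumSet:
    """n samples x m bands of unitless canopy reflectance on a shared grid."""

    sample_ids: list
    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.reflectance, dtype=float)
        if R.ndim != 2:
            raise FormatError("reflectance must be a 2-D (samples x bands) matrix")
        if R.shape[0] != len(self.sample_ids):
            raise FormatError(
                f"{len(self.sample_ids)} sample ids but {R.shape[0]} reflectance rows"
            )
        if R.shape[1] != len(self.grid):
            raise FormatError(f"{len(self.grid)} grid bands but {R.shape[1]} reflectance columns")
        bad = ~np.isfinite(R)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite reflectance for sample {self.sample_ids[r]!r} "
                f"at {self.grid.wavelengths[c]:.0f} nm"
            )
        out = (R < 0) | (R > REFLECTANCE_MAX)
        if out.any():
            r, c = np.argwhere(out)[0]
            raise SpectrumValidationError(
                f"reflectance {R[r, c]:.4g} out of [0, {REFLECTANCE_MAX}] for sample "
                f"{self.sample_ids[r]!r} at {self.grid.wavelengths[c]:.0f} nm"
            )
        self.reflectance = R
        self.sample_ids = list(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    def band(self, nm: float, snap_tol: float = 1.0) -> np.ndarray:
        """Reflectance column at wavelength ``nm`` (nearest-band snap within ``snap_tol``)."""
        return self.reflectance[:, self.grid.index_of(nm, snap_tol)]

    def select_bands(self, wavelengths: Iterable[float]) -> "SpectrumSet":
        """Restrict to the given wavelengths (each must be on the grid)."""
        idx = [self.grid.index_of(w, snap_tol=0.0) for w in wavelengths]
        return SpectrumSet(self.sample_ids, WavelengthGrid(self.grid.wavelengths[idx]),
                           self.reflectance[:, idx])

    def select_samples(self, sample_ids: Sequence) -> "SpectrumSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SpectrumSet(list(sample_ids), self.grid, self.reflectance[idx])

    def to_dataframe(self) -> pd.DataFrame:
        cols = [_fmt_wavelength(w) for w in self.grid.wavelengths]
        df = pd.DataFrame(self.reflectance, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class TraitVector:
    """Per-sample leaf nitrogen concentration (mg N per g dry mass)."""

    sample_ids: list
    lnc: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.lnc, dtype=float)
        if y.ndim != 1 or y.size != len(self.sample_ids):
            raise FormatError("trait vector must align 1:1 with sample ids")
        if not np.all(np.isfinite(y)):
            raise FormatError("trait vector contains non-finite values")
        if np.any(y <= 0):
            raise FormatError("LNC values must be strictly positive (mg g^-1)")
        self.lnc = y
        self.sample_ids = list(self.sample_ids)

    def __len__(self) -> int:
        return self.lnc.size

    def select_samples(self, sample_ids: Sequence) -> "TraitVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return TraitVector(list(sample_ids), self.lnc[[pos[s] for s in sample_ids]])


@dataclass
class ScanStack:
    """Replicate scans (nominally 9) collected over one quadrat."""

    quadrat_id: str
    grid: WavelengthGrid
    scans: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.scans, dtype=float)
        if S.ndim != 2 or S.shape[0] < 1:
            raise FormatError("scan stack must be a 2-D (scans x bands) matrix with >= 1 scan")
        if S.shape[1] != len(self.grid):
            raise FormatError("scan stack does not match grid length")
        self.scans = S


@dataclass(frozen=True)
class PreprocessConfig:
    """Savitzky-Golay and scan-filter settings.

    sg_window / sg_polyorder: a second-order polynomial fitted in a
    nine-band moving window is the default smoother.  scan_sd_threshold is
    the +/- k*SD replicate-scan outlier multiplier; a scan is dropped
    wholesale once it is flagged at more than ``scan_flag_fraction`` of bands.
    """

    sg_window: int = 9
    sg_polyorder: int = 2
    scan_sd_threshold: float = 3.0
    scan_flag_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigurationError(
                f"sg_window must be odd and > sg_polyorder (got {self.sg_window}, {self.sg_polyorder})"
            )
        if self.scan_sd_threshold <= 0:
            raise ConfigurationError("scan_sd_threshold must be > 0")
        if not 0 < self.scan_flag_fraction <= 1:
            raise ConfigurationError("scan_flag_fraction must be in (0, 1]")


def _fmt_wavelength(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


# ---------------------------------------------------------------------------
# CSV I/O


def write_spectra(spectra: SpectrumSet, path) -> None:
    spectra.to_dataframe().to_csv(path, index=False)


def read_spectra(path) -> SpectrumSet:
    """Read a wide-CSV spectrum file and validate it into a SpectrumSet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if len(header) < 2 or header[0] != "sample_id":
        raise FormatError(f"{path}: expected a 'sample_id' first column followed by wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header: {exc}") from exc
    df = pd.read_csv(path, header=0, names=["sample_id"] + list(range(len(wavelengths))))
    if np.unique(wavelengths).size != wavelengths.size:
        raise FormatError(f"{path}: duplicated wavelength in header")
    if not np.all(np.diff(wavelengths) > 0):
        raise FormatError(f"{path}: wavelength header is not strictly increasing")
    values = df.iloc[:, 1:]
    if values.isna().any().any():
        row, col = next(
            (i, c) for c in values.columns for i in values.index[values[c].isna()]
        )
        raise FormatError(f"{path}: missing/non-numeric reflectance at row {row}, column {col}")
    R = values.to_numpy(dtype=float)
    return SpectrumSet(df["sample_id"].tolist(), WavelengthGrid(wavelengths), R)


def write_trait(trait: TraitVector, path) -> None:
    pd.DataFrame({"sample_id": trait.sample_ids, "lnc_mg_g": trait.lnc}).to_csv(path, index=False)


def read_trait(path) -> TraitVector:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("sample_id", "lnc_mg_g"):
        if col not in df.columns:
            raise FormatError(f"{path}: trait CSV must have columns sample_id, lnc_mg_g")
    return TraitVector(df["sample_id"].tolist(), df["lnc_mg_g"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Replicate-scan reduction


def filter_and_average_scans(stack: ScanStack, config: PreprocessConfig | None = None) -> np.ndarray:
    """Drop outlying replicate scans and average the rest into one spectrum.

    Per band, each scan's value is compared against the mean and standard
    deviation of the *other* scans (leave-one-out); a deviation beyond
    ``scan_sd_threshold`` standard deviations flags the scan at that band.
    A scan flagged at more than ``scan_flag_fraction`` of bands is excluded
    wholesale, and the surviving scans are averaged.  A single scan passes
    through unchanged.
    """
    config = config or PreprocessConfig()
    S = stack.scans
    s, m = S.shape
    if s == 1:
        return S[0].copy()
    total = S.sum(axis=0)
    sumsq = (S * S).sum(axis=0)
    # leave-one-out mean/SD per (scan, band)
    loo_mean = (total[None, :] - S) / (s - 1)
    loo_var = (sumsq[None, :] - S * S) / (s - 1) - loo_mean**2
    loo_sd = np.sqrt(np.clip(loo_var, 0.0, None))
    dev = np.abs(S - loo_mean)
    # zero spread among the others: any real deviation is an outlier (atol
    # absorbs rounding in the running sums for exactly-identical scans)
    atol = 1e-12
    flagged = np.where(loo_sd > atol, dev > config.scan_sd_threshold * loo_sd, dev > atol)
    keep = flagged.mean(axis=1) <= config.scan_flag_fraction
    if not keep.any():
        raise DegenerateInputError(
            f"quadrat {stack.quadrat_id!r}: every replicate scan was excluded as an outlier"
        )
    return S[keep].mean(axis=0)


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing


def _edge_rows(window: int, polyorder: int) -> list[np.ndarray]:
    """Least-squares fit weights for the shrunken left-edge windows.

    Position p (0-based, p < window//2) is smoothed by fitting a degree-
    ``polyorder`` polynomial to bands 0..p+half and evaluating it at p.
    """
    half = window // 2
    rows = []
    for p in range(half):
        x = np.arange(0, p + half + 1, dtype=float) - p
        A = np.vander(x, polyorder + 1, increasing=True)
        # value at offset 0 => first row of the pseudoinverse projection
        rows.append(np.linalg.pinv(A)[0])
    return rows


def sg_smooth(spectra: SpectrumSet, config: PreprocessConfig | None = None) -> SpectrumSet:
    """Savitzky-Golay smoothing of every spectrum (window 9, order 2 by default).

    Interior bands use the standard least-squares convolution kernel; the
    first and last ``window//2`` bands are fitted on the shrunken one-sided
    window (no padding).  The grid and sample count are unchanged.
    """
    config = config or PreprocessConfig()
    m = len(spectra.grid)
    w, order = config.sg_window, config.sg_polyorder
    if w > m:
        raise ConfigurationError(f"sg_window {w} exceeds the {m}-band grid")
    spectra.grid.step  # raises if non-uniform
    R = spectra.reflectance
    kernel = savgol_coeffs(w, order)
    half = w // 2
    out = np.empty_like(R)
    # interior: valid convolution (kernel is symmetric for smoothing)
    windows = np.lib.stride_tricks.sliding_window_view(R, w, axis=1)
    out[:, half:m - half] = windows @ kernel[::-1]
    for p, row in enumerate(_edge_rows(w, order)):
        k = row.size
        out[:, p] = R[:, :k] @ row
        out[:, m - 1 - p] = R[:, m - k:] @ row[::-1]
    out = np.clip(out, 0.0, REFLECTANCE_MAX)
    return SpectrumSet(spectra.sample_ids, spectra.grid, out)
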