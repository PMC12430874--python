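"""Spectral index formulas: seven fixed-band empirical indices, seven
two-band parametric forms and four three-band parametric forms.

Two-band forms take arbitrary wavelengths i, j (three-band forms add k);
TSI additionally anchors on R550 and mSR/mNDI on R455.  All formulas
assume reflectance as unitless fractions.  Division by a near-zero
denominator (|den| < 1e-12) yields NaN for that sample -- an "undefined"
flag that downstream correlation screening excludes rather than propagates.

Every form lives in an overridable registry, so an alternative reading of
a formula is a one-line ``register_*`` call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import json
import numpy as np

from .errors import ConfigurationError
from .spectra_io import SpectrumSet

#: denominators smaller than this in magnitude are treated as undefined
DENOM_EPS = 1e-12


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    ok = np.abs(den) >= DENOM_EPS
    return np.divide(num, np.where(ok, den, 1.0), out=None) * np.where(ok, 1.0, np.nan)


def _safe_recip(r):
    r = np.asarray(r, dtype=float)
    ok = r >= DENOM_EPS
    return np.where(ok, 1.0 / np.where(ok, r, 1.0), np.nan)


@dataclass(frozen=True)
class IndexValue:
    """One index evaluated over a SpectrumSet; NaN marks undefined samples."""

    form: str
    bands: tuple
    values: np.ndarray


# ---------------------------------------------------------------------------
# Empirical (fixed-band) indices


@dataclass(frozen=True)
class EmpiricalForm:
    name: str
    wavelengths: tuple[float, ...]
    func: Callable[..., np.ndarray]  # called with one reflectance vector per wavelength


EMPIRICAL_FORMS: dict[str, EmpiricalForm] = {}


def register_empirical(name: str, wavelengths: Sequence[float], func: Callable) -> None:
    EMPIRICAL_FORMS[name] = EmpiricalForm(name, tuple(wavelengths), func)


register_empirical("DDI", (749, 720, 701, 672), lambda a, b, c, d: (a - b) - (c - d))
register_empirical(
    "MNDSI", (800, 680, 445), lambda a, b, c: _safe_div(a - b, a + b - 2.0 * c)
)
register_empirical("DDn", (710, 660, 760), lambda a, b, c: 2.0 * a - b - c)
register_empirical(
    "RDVI", (800, 670), lambda a, b: _safe_div(a - b, np.sqrt(np.clip(a + b, 0.0, None)))
)
register_empirical("CI", (675, 690, 683), lambda a, b, c: _safe_div(a * b, c * c))
register_empirical("MTCI", (754, 709, 681), lambda a, b, c: _safe_div(a - b, b - c))
register_empirical("Gitelson2", (687, 500, 750), lambda a, b, c: _safe_div(a - b, c))


# ---------------------------------------------------------------------------
# Two-band parametric forms
#
# Functions broadcast over leading axes, so screening can evaluate whole
# band blocks at once.  ``aux`` carries the per-sample anchor reflectances
# (R550, R455) already shaped for broadcasting.


@dataclass(frozen=True)
class PairForm:
    name: str
    func: Callable[..., np.ndarray]  # (Ri, Rj, *, r550, r455)
    fixed_refs: tuple[float, ...] = ()
    #: swapping (i, j) flips the sign but not |r|; screening then only needs i <= j
    antisymmetric: bool = False


PAIR_FORMS: dict[str, PairForm] = {}


def register_pair(
    name: str, func: Callable, fixed_refs: Sequence[float] = (), antisymmetric: bool = False
) -> None:
    PAIR_FORMS[name] = PairForm(name, func, tuple(fixed_refs), antisymmetric)


register_pair(
    "SASI",
    lambda ri, rj, r550=None, r455=None: 1.16 * _safe_div(ri - rj, ri + rj + 0.16),
    antisymmetric=True,
)
register_pair(
    "NDSI", lambda ri, rj, r550=None, r455=None: _safe_div(ri - rj, ri + rj), antisymmetric=True
)
register_pair(
    "TSI",
    lambda ri, rj, r550=None, r455=None: 0.5 * (120.0 * (ri - r550) - 200.0 * (rj - r550)),
    fixed_refs=(550,),
)
register_pair(
    "mSR",
    lambda ri, rj, r550=None, r455=None: _safe_div(ri - r455, rj - r455),
    fixed_refs=(455,),
)
register_pair(
    "mNDI",
    lambda ri, rj, r550=None, r455=None: _safe_div(ri - rj, ri + rj - 2.0 * r455),
    fixed_refs=(455,),
    antisymmetric=True,
)
register_pair("RSI", lambda ri, rj, r550=None, r455=None: _safe_div(ri, rj))
register_pair("DSI", lambda ri, rj, r550=None, r455=None: ri - rj, antisymmetric=True)


# ---------------------------------------------------------------------------
# Three-band parametric forms
#
# Each form also declares a separable structure used by the streaming
# screener: "additive" forms are s1*f(Ri) + s2*f(Rj) + s3*f(Rk) and
# "multiplicative" forms are f1(Ri)*f2(Rj)*f3(Rk), with f the identity or
# the (guarded) reciprocal.


@dataclass(frozen=True)
class TripleForm:
    name: str
    func: Callable[..., np.ndarray]  # (Ri, Rj, Rk)
    structure: str  # "additive" | "multiplicative"
    transforms: tuple[str, str, str]  # "id" | "recip"
    signs: tuple[int, int, int] = (1, 1, 1)  # used by additive forms
    #: "jk" = value unchanged when j and k swap; "full" = any permutation
    symmetry: str | None = None


TRIPLE_FORMS: dict[str, TripleForm] = {}


def register_triple(name, func, structure, transforms, signs=(1, 1, 1), symmetry=None) -> None:
    TRIPLE_FORMS[name] = TripleForm(
        name, func, structure, tuple(transforms), tuple(signs), symmetry
    )


register_triple(
    "RTSI",
    lambda ri, rj, rk: _safe_div(ri, rj * rk),  # Ri/Rj/Rk, left-associative
    "multiplicative",
    ("id", "recip", "recip"),
    symmetry="jk",
)
register_triple(
    "DTSI", lambda ri, rj, rk: ri - rj - rk, "additive", ("id", "id", "id"), (1, -1, -1),
    symmetry="jk",
)
register_triple(
    "RDTSI",
    lambda ri, rj, rk: _safe_recip(ri) - _safe_recip(rj) - _safe_recip(rk),
    "additive",
    ("recip", "recip", "recip"),
    (1, -1, -1),
    symmetry="jk",
)
register_triple(
    "RATSI",
    lambda ri, rj, rk: _safe_recip(ri) + _safe_recip(rj) + _safe_recip(rk),
    "additive",
    ("recip", "recip", "recip"),
    (1, 1, 1),
    symmetry="full",
)

FACTOR_TRANSFORMS = {"id": lambda r: np.asarray(r, dtype=float), "recip": _safe_recip}


# ---------------------------------------------------------------------------
# Evaluation entry points


def form_arity(name: str) -> int:
    if name in EMPIRICAL_FORMS:
        return 0
    if name in PAIR_FORMS:
        return 2
    if name in TRIPLE_FORMS:
        return 3
    raise ConfigurationError(f"unknown index form {name!r}")


def _aux(spectra: SpectrumSet, form: PairForm) -> dict:
    aux = {}
    if 550 in form.fixed_refs:
        aux["r550"] = spectra.band(550.0)
    if 455 in form.fixed_refs:
        aux["r455"] = spectra.band(455.0)
    return aux


def eval_empirical(spectra: SpectrumSet, name: str) -> IndexValue:
    """Evaluate a fixed-band empirical index (snapping bands within 1 nm)."""
    form = EMPIRICAL_FORMS[name]
    cols = [spectra.band(w) for w in form.wavelengths]
    return IndexValue(name, (), np.asarray(form.func(*cols), dtype=float))


def eval_pair(spectra: SpectrumSet, name: str, i: float, j: float) -> IndexValue:
    form = PAIR_FORMS[name]
    ri, rj = spectra.band(i, snap_tol=0.0), spectra.band(j, snap_tol=0.0)
    vals = form.func(ri, rj, **_aux(spectra, form))
    return IndexValue(name, (i, j), np.asarray(vals, dtype=float))


def eval_triple(spectra: SpectrumSet, name: str, i: float, j: float, k: float) -> IndexValue:
    form = TRIPLE_FORMS[name]
    cols = [spectra.band(w, snap_tol=0.0) for w in (i, j, k)]
    return IndexValue(name, (i, j, k), np.asarray(form.func(*cols), dtype=float))


def evaluate_form(spectra: SpectrumSet, name: str, bands: Sequence[float] = ()) -> IndexValue:
    """Dispatch on arity: empirical (no bands), pair (i, j) or triple (i, j, k)."""
    arity = form_arity(name)
    if arity == 0:
        return eval_empirical(spectra, name)
    if len(bands) != arity:
        raise ConfigurationError(f"{name} takes {arity} bands, got {len(bands)}")
    if arity == 2:
        return eval_pair(spectra, name, *bands)
    return eval_triple(spectra, name, *bands)


def registry_to_json() -> str:
    """Serializable summary of the registered forms (names, arity, anchors)."""
    entries = (
        [{"name": f.name, "arity": 0, "fixed_bands": list(f.wavelengths)} for f in EMPIRICAL_FORMS.values()]
        + [{"name": f.name, "arity": 2, "fixed_refs": list(f.fixed_refs)} for f in PAIR_FORMS.values()]
        + [
            {"name": f.name, "arity": 3, "structure": f.structure, "transforms": list(f.transforms)}
            for f in TRIPLE_FORMS.values()
        ]
    )
    return json.dumps(entries, indent=2)
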