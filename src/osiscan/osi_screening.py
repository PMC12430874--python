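"""Exhaustive correlation-matrix screening of optimal spectral indices.

For a chosen index form, every ordered wavelength pair (2D-OSI) or triad
(3D-OSI) on a strided grid is evaluated against the trait and its Pearson
r recorded; the winner is the combination maximizing |r| (ties broken by
the lexicographically smallest band tuple).  Pair searches return the
dense r matrix; triad searches stream in band blocks and never hold the
full m^3 cube, keeping only the global argmax, a top-k list and per-slice
maxima for visualization.

Samples whose index value is undefined (NaN flag from the formula guards)
are dropped per combination; a combination is itself undefined when fewer
than 3 samples remain or the index is constant over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    ScreeningFailureError,
    UndefinedCorrelationError,
)
from .spectra_io import SpectrumSet, TraitVector
from .spectral_indices import (
    FACTOR_TRANSFORMS,
    PAIR_FORMS,
    TRIPLE_FORMS,
    form_arity,
)

_MEM_BUDGET = 8_000_000  # floats per streamed value block


@dataclass
class CorrelationMap:
    """The r-R matrix of one screening run (dense for pairs, sparse for triads)."""

    form: str
    stride: float
    wavelengths: np.ndarray
    matrix: np.ndarray | None = None  # (m', m') signed r, NaN = undefined (arity 2)
    slice_max: np.ndarray | None = None  # per-i max |r| over (j, k) (arity 3)
    top_k: list = field(default_factory=list)


@dataclass
class ScreeningResult:
    form: str
    best_bands: tuple
    best_r: float
    p_value: float
    n_used: int
    top_k: list  # [{"bands": (...), "r": float}, ...] sorted by |r| desc

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "bands": [float(b) for b in self.best_bands],
            "r": self.best_r,
            "p": self.p_value,
            "n_used": self.n_used,
            "top_k": [
                {"bands": [float(b) for b in e["bands"]], "r": e["r"]} for e in self.top_k
            ],
        }


# ---------------------------------------------------------------------------
# Pearson correlation


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n-2 df), NaN pairs dropped.

    Raises UndefinedCorrelationError for constant vectors or fewer than
    3 defined pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("pearson_r expects two equal-length 1-D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise UndefinedCorrelationError(f"only {x.size} defined pairs (need >= 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), max(float(res.pvalue), np.finfo(float).tiny)


def _p_from_r(r: float, n: int) -> float:
    """Two-sided p via the t transform with n-2 degrees of freedom."""
    if n < 3:
        return np.nan
    rr = min(abs(r), 1.0)
    if rr >= 1.0:
        return float(np.finfo(float).tiny)
    t = rr * np.sqrt((n - 2) / (1.0 - rr * rr))
    return max(float(2.0 * stats.t.sf(t, n - 2)), np.finfo(float).tiny)


def _masked_pearson_block(vals: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NaN-aware Pearson r of ``vals[:, ...]`` columns against y.

    Returns (r, n_used) with r = NaN where fewer than 3 samples remain or
    the index is constant over them.
    """
    shape_tail = (1,) * (vals.ndim - 1)
    yb = y.reshape((-1,) + shape_tail)
    mask = np.isfinite(vals)
    nu = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = np.where(mask, vals, 0.0).sum(axis=0) / nu
        mean_y = np.where(mask, yb, 0.0).sum(axis=0) / nu
        vc = np.where(mask, vals - mean_x, 0.0)
        yc = np.where(mask, yb - mean_y, 0.0)
        sxy = (vc * yc).sum(axis=0)
        sxx = (vc * vc).sum(axis=0)
        syy = (yc * yc).sum(axis=0)
        r = sxy / np.sqrt(sxx * syy)
    r = np.where((nu >= 3) & (sxx > 0) & (syy > 0), r, np.nan)
    return r, nu


# ---------------------------------------------------------------------------
# Shared reduction helpers


def _aligned_trait(spectra: SpectrumSet, trait: TraitVector) -> np.ndarray:
    if list(trait.sample_ids) == list(spectra.sample_ids):
        return trait.lnc
    return trait.select_samples(spectra.sample_ids).lnc


def _strided_indices(
    spectra: SpectrumSet, stride: float, search_range: tuple[float, float] | None = None
) -> np.ndarray:
    step = spectra.grid.step
    ratio = stride / step
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ConfigurationError(f"stride {stride} nm is not a multiple of the {step} nm grid step")
    idx = np.arange(0, len(spectra.grid), int(round(ratio)))
    if search_range is not None:
        lo, hi = search_range
        wl = spectra.grid.wavelengths[idx]
        idx = idx[(wl >= lo) & (wl <= hi)]
        if idx.size == 0:
            raise ConfigurationError(f"search range {search_range} contains no strided bands")
    return idx


class _BestTracker:
    """Running |r| argmax with lexicographic tie-break, plus a top-k heap."""

    def __init__(self, k: int):
        self.k = k
        self.best_bands: tuple | None = None
        self.best_r = np.nan
        self.best_n = 0
        self.entries: list = []  # (absr, bands, r, nu)

    def update(self, r_block: np.ndarray, nu_block: np.ndarray, bands_of) -> None:
        absr = np.abs(r_block)
        if not np.any(np.isfinite(absr)):
            return
        flat = np.where(np.isfinite(absr), absr, -1.0).ravel()
        k = min(self.k, flat.size)
        cand = np.argpartition(flat, -k)[-k:]
        cand = cand[flat[cand] >= 0]
        for idx in cand:
            multi = np.unravel_index(idx, absr.shape)
            self.entries.append(
                (flat[idx], bands_of(multi), float(r_block[multi]), int(nu_block[multi]))
            )
        # chunk-local argmax candidates, including exact ties for the tie-break
        m = flat.max()
        if m < 0:
            return
        for idx in np.flatnonzero(flat == m):
            multi = np.unravel_index(idx, absr.shape)
            bands = bands_of(multi)
            better = (
                self.best_bands is None
                or m > abs(self.best_r)
                or (m == abs(self.best_r) and bands < self.best_bands)
            )
            if better:
                self.best_bands = bands
                self.best_r = float(r_block[multi])
                self.best_n = int(nu_block[multi])

    def top_k(self) -> list:
        self.entries.sort(key=lambda e: (-e[0], e[1]))
        return [{"bands": b, "r": r} for _, b, r, _ in self.entries[: self.k]]

    def result(self, form: str) -> ScreeningResult:
        if self.best_bands is None:
            raise ScreeningFailureError(
                f"{form}: every band combination had an undefined correlation"
            )
        return ScreeningResult(
            form=form,
            best_bands=self.best_bands,
            best_r=self.best_r,
            p_value=_p_from_r(self.best_r, self.best_n),
            n_used=self.best_n,
            top_k=self.top_k(),
        )


# ---------------------------------------------------------------------------
# 2D-OSI


def screen_pairs(
    spectra: SpectrumSet,
    trait: TraitVector,
    form: str,
    stride: float = 1.0,
    top_k: int = 20,
    search_range: tuple[float, float] | None = None,
) -> tuple[CorrelationMap, ScreeningResult]:
    """Exhaustive ordered-pair search for a two-band form."""
    if form_arity(form) != 2:
        raise ConfigurationError(f"{form} is not a two-band form")
    pf = PAIR_FORMS[form]
    y = _aligned_trait(spectra, trait)
    idx = _strided_indices(spectra, stride, search_range)
    Rs = spectra.reflectance[:, idx]
    wl = spectra.grid.wavelengths[idx]
    n, mp = Rs.shape
    aux = {}
    if 550 in pf.fixed_refs:
        aux["r550"] = spectra.band(550.0)[:, None, None]
    if 455 in pf.fixed_refs:
        aux["r455"] = spectra.band(455.0)[:, None, None]

    rmat = np.full((mp, mp), np.nan)
    tracker = _BestTracker(top_k)
    chunk = max(1, _MEM_BUDGET // (n * mp))
    cols = np.arange(mp)
    for start in range(0, mp, chunk):
        ch = slice(start, min(start + chunk, mp))
        vals = pf.func(Rs[:, ch, None], Rs[:, None, :], **aux)
        r_block, nu_block = _masked_pearson_block(vals, y)
        rmat[ch] = r_block
        if pf.antisymmetric:
            # sign-symmetric under (i, j) swap: select only the canonical i <= j
            # representative, realizing the lexicographic tie-break exactly
            keep = cols[None, :] >= np.arange(start, ch.stop)[:, None]
            r_block = np.where(keep, r_block, np.nan)
        tracker.update(
            r_block, nu_block, lambda multi, s=start: (wl[s + multi[0]], wl[multi[1]])
        )
    result = tracker.result(form)
    cmap = CorrelationMap(form, stride, wl, matrix=rmat, top_k=tracker.top_k())
    return cmap, result


# ---------------------------------------------------------------------------
# 3D-OSI


def _triple_factors(form_name: str, Rs: np.ndarray):
    tf = TRIPLE_FORMS[form_name]
    return [FACTOR_TRANSFORMS[t](Rs) for t in tf.transforms]


def screen_triples(
    spectra: SpectrumSet,
    trait: TraitVector,
    form: str,
    stride: float = 5.0,
    chunk: int = 8,
    top_k: int = 20,
    method: str = "auto",
    search_range: tuple[float, float] | None = None,
) -> tuple[CorrelationMap, ScreeningResult]:
    """Streaming exhaustive ordered-triad search for a three-band form.

    ``method`` selects the evaluation route: "moments" exploits the form's
    additive/multiplicative separability through per-band Gram matrices and
    BLAS contractions, "direct" materializes value blocks and uses the
    NaN-aware correlation (the only route when some factor is undefined),
    and "auto" picks "moments" whenever all factors are finite.  All routes
    produce the same screening result; ``chunk`` only sizes the i-band
    slabs of the "direct" route.
    """
    if form_arity(form) != 3:
        raise ConfigurationError(f"{form} is not a three-band form")
    tf = TRIPLE_FORMS[form]
    y = _aligned_trait(spectra, trait)
    idx = _strided_indices(spectra, stride, search_range)
    Rs = spectra.reflectance[:, idx]
    wl = spectra.grid.wavelengths[idx]
    n, mp = Rs.shape

    factors = _triple_factors(form, Rs)
    finite = all(np.all(np.isfinite(F)) for F in factors)
    if method == "auto":
        method = "moments" if finite else "direct"
    if method == "moments" and not finite:
        raise ConfigurationError("moments route requires all factor values defined")

    tracker = _BestTracker(top_k)
    slice_max = np.full(mp, np.nan)
    canon = _canonical_keep(tf.symmetry, mp)
    if method == "moments":
        if np.ptp(y) == 0:
            raise UndefinedCorrelationError("correlation undefined for a constant trait")
        if tf.structure == "additive":
            _triples_additive(factors, tf.signs, y, wl, tracker, slice_max, canon)
        else:
            _triples_multiplicative(factors, y, wl, tracker, slice_max, canon)
    elif method == "direct":
        _triples_direct(tf, Rs, y, wl, tracker, slice_max, max(1, chunk), canon)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    result = tracker.result(form)
    cmap = CorrelationMap(form, stride, wl, slice_max=slice_max, top_k=tracker.top_k())
    return cmap, result


def _canonical_keep(symmetry, mp):
    """Boolean keep-mask builder selecting one representative per symmetry orbit.

    Symmetric permutations of a triad have identical index values, so the
    |r| argmax is restricted to the lexicographically smallest member:
    k >= j for j/k-symmetric forms, i <= j <= k for fully symmetric ones.
    """
    idx = np.arange(mp)
    jk = idx[None, :, None] <= idx[None, None, :]  # j <= k

    def keep(i_lo, i_hi):
        if symmetry is None:
            return True
        if symmetry == "jk":
            return jk
        ii = idx[i_lo:i_hi, None, None]
        return (ii <= idx[None, :, None]) & jk

    return keep


def _slab_update(tracker, slice_max, r_slab, nu_slab, wl, i0, canon):
    with np.errstate(all="ignore"):
        sm = np.nanmax(np.abs(r_slab), axis=(1, 2))
    c = r_slab.shape[0]
    slice_max[i0 : i0 + c] = np.where(
        np.isfinite(sm), sm, slice_max[i0 : i0 + c]
    )
    keep = canon(i0, i0 + c)
    if keep is not True:
        r_slab = np.where(keep, r_slab, np.nan)
    tracker.update(
        r_slab, nu_slab, lambda multi, s=i0: (wl[s + multi[0]], wl[multi[1]], wl[multi[2]])
    )


def _triples_additive(factors, signs, y, wl, tracker, slice_max, canon):
    """Pearson r for X = s1*A_i + s2*B_j + s3*C_k from column means and Gram matrices."""
    n = y.size
    A, B, C = (s * F for s, F in zip(signs, factors))
    yc = y - y.mean()
    syy = float(yc @ yc)
    Ac, Bc, Cc = (F - F.mean(axis=0, keepdims=True) for F in (A, B, C))
    ay, by, cy = (F.T @ yc for F in (Ac, Bc, Cc))
    va, vb, vc = ((F * F).sum(axis=0) for F in (Ac, Bc, Cc))
    gab, gac, gbc = Ac.T @ Bc, Ac.T @ Cc, Bc.T @ Cc
    mp = wl.size
    c = max(1, _MEM_BUDGET // (mp * mp))
    vscale = max(va.max(), vb.max(), vc.max())
    for i0 in range(0, mp, c):
        ch = slice(i0, min(i0 + c, mp))
        num = ay[ch, None, None] + by[None, :, None] + cy[None, None, :]
        varx = (
            va[ch, None, None]
            + vb[None, :, None]
            + vc[None, None, :]
            + 2.0 * (gab[ch, :, None] + gac[ch, None, :] + gbc[None, :, :])
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / np.sqrt(varx * syy)
        r = np.where(varx > vscale * 1e-13, r, np.nan)
        nu = np.full(r.shape, n, dtype=int)
        _slab_update(tracker, slice_max, r, nu, wl, i0, canon)


def _triples_multiplicative(factors, y, wl, tracker, slice_max, canon):
    """Pearson r for X = A_i * B_j * C_k from three BLAS tensor contractions."""
    A, B, C = factors
    n, mp = A.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    Ay = A * yc[:, None]
    A2 = A * A
    cj = max(1, _MEM_BUDGET // (mp * mp))  # j-block width; fixed by grid size only
    for j0 in range(0, mp, cj):
        Bb = B[:, j0 : j0 + cj]
        w = Bb.shape[1]
        P = (Bb[:, :, None] * C[:, None, :]).reshape(n, w * mp)
        P2 = ((Bb * Bb)[:, :, None] * (C * C)[:, None, :]).reshape(n, w * mp)
        s1 = (A.T @ P).reshape(mp, w, mp)
        sy = (Ay.T @ P).reshape(mp, w, mp)
        s2 = (A2.T @ P2).reshape(mp, w, mp)
        varx = s2 - s1 * s1 / n
        with np.errstate(invalid="ignore", divide="ignore"):
            r = sy / np.sqrt(varx * syy)
        r = np.where(varx > np.abs(s2) * 1e-13, r, np.nan)
        nu = np.full(r.shape, n, dtype=int)
        # block covers all i, columns j0..j0+w
        with np.errstate(all="ignore"):
            sm = np.nanmax(np.abs(r), axis=(1, 2))
        np.fmax(slice_max, sm, out=slice_max)
        keep = canon(0, mp)
        if keep is not True:
            r = np.where(keep[:, j0 : j0 + w, :], r, np.nan)
        tracker.update(
            r, nu, lambda multi, s=j0: (wl[multi[0]], wl[s + multi[1]], wl[multi[2]])
        )


def _triples_direct(tf, Rs, y, wl, tracker, slice_max, chunk, canon):
    """Materialize (n, chunk, m', m') value blocks; NaN-aware correlation."""
    n, mp = Rs.shape
    for i0 in range(0, mp, chunk):
        ch = slice(i0, min(i0 + chunk, mp))
        vals = tf.func(Rs[:, ch, None, None], Rs[:, None, :, None], Rs[:, None, None, :])
        r_slab, nu_slab = _masked_pearson_block(vals, y)
        _slab_update(tracker, slice_max, r_slab, nu_slab, wl, i0, canon)


def refine_triples(
    spectra: SpectrumSet,
    trait: TraitVector,
    coarse: ScreeningResult,
    radius: float = 5.0,
) -> ScreeningResult:
    """Stride-1 re-search in a +/- ``radius`` nm box around a coarse optimum."""
    g = spectra.grid.wavelengths
    windows = []
    for b in coarse.best_bands:
        sel = g[(g >= b - radius) & (g <= b + radius)]
        windows.append(sel)
    mask = np.zeros(g.size, dtype=bool)
    for w in windows:
        mask |= np.isin(g, w)
    sub = spectra.select_bands(g[mask])
    y = _aligned_trait(sub, trait)
    tf = TRIPLE_FORMS[coarse.form]
    tracker = _BestTracker(len(coarse.top_k) or 1)
    swl = sub.grid.wavelengths
    pos = {w: i for i, w in enumerate(swl)}
    ii = np.array([pos[w] for w in windows[0]])
    jj = np.array([pos[w] for w in windows[1]])
    kk = np.array([pos[w] for w in windows[2]])
    R = sub.reflectance
    vals = tf.func(
        R[:, ii][:, :, None, None], R[:, jj][:, None, :, None], R[:, kk][:, None, None, :]
    )
    r_block, nu_block = _masked_pearson_block(vals, y)
    if tf.symmetry is not None:
        wj = windows[1][None, :, None]
        wk = windows[2][None, None, :]
        keep = wj <= wk
        if tf.symmetry == "full":
            keep = keep & (windows[0][:, None, None] <= wj)
        r_block = np.where(keep, r_block, np.nan)
    tracker.update(
        r_block,
        nu_block,
        lambda multi: (windows[0][multi[0]], windows[1][multi[1]], windows[2][multi[2]]),
    )
    return tracker.result(coarse.form)


def screen(
    spectra: SpectrumSet,
    trait: TraitVector,
    form: str,
    stride: float | None = None,
    **kw,
) -> tuple[CorrelationMap, ScreeningResult]:
    """Arity dispatch: pairs default to stride 1 nm, triads to stride 5 nm."""
    arity = form_arity(form)
    if arity == 2:
        return screen_pairs(spectra, trait, form, stride=stride or 1.0, **kw)
    if arity == 3:
        return screen_triples(spectra, trait, form, stride=stride or 5.0, **kw)
    raise ConfigurationError(f"{form} is not a screenable parametric form")


def select_significant(entries: Sequence, alpha: float = 0.05) -> list:
    """Keep (name, r, p) entries with p < alpha, preserving order."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    return [e for e in entries if e[2] < alpha]
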