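"""Trait outlier removal, stratified modeling/validation split, and
Combine 1-7 feature-matrix assembly.

The seven Combines are unions of the three significance-filtered index
families: 1 = empirical, 2 = two-band optimal, 3 = three-band optimal,
4 = 1 u 2, 5 = 1 u 3, 6 = 2 u 3, 7 = 1 u 2 u 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError
from .spectra_io import SpectrumSet, TraitVector
from . import spectral_indices as si

__all__ = [
    "TraitVector",
    "GrubbsResult",
    "grubbs_filter",
    "SplitResult",
    "stratified_split",
    "CombineSpec",
    "FeatureDescriptor",
    "FeatureMatrix",
    "COMBINE_MEMBERS",
    "build_combine",
    "combine_spec_from_screening",
]


# ---------------------------------------------------------------------------
# Grubbs outlier test


@dataclass
class GrubbsResult:
    kept_ids: list
    removed_ids: list
    statistics: list  # (G, G_critical, iteration) per iteration performed


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile,
    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2}."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(trait: TraitVector, alpha: float = 0.05) -> GrubbsResult:
    """Iterative two-sided Grubbs test: remove the most extreme sample while
    G = max|y_i - ybar|/s exceeds the critical value, then stop."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    ids = list(trait.sample_ids)
    y = trait.lnc.copy()
    if y.size < 3:
        raise DegenerateInputError(f"Grubbs test needs n >= 3, got {y.size}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("Grubbs test undefined for zero-variance trait")
    removed: list = []
    statistics: list = []
    iteration = 0
    while y.size >= 3 and np.ptp(y) > 0:
        iteration += 1
        s = y.std(ddof=1)
        dev = np.abs(y - y.mean())
        i = int(np.argmax(dev))
        G = float(dev[i] / s)
        G_crit = float(grubbs_critical(y.size, alpha))
        statistics.append((G, G_crit, iteration))
        if G <= G_crit:
            break
        removed.append(ids.pop(i))
        y = np.delete(y, i)
    return GrubbsResult(kept_ids=ids, removed_ids=removed, statistics=statistics)


# ---------------------------------------------------------------------------
# Stratified split


@dataclass
class SplitResult:
    modeling_ids: list
    validation_ids: list
    seed: int
    strata: list  # bin edges on LNC

    def to_dict(self) -> dict:
        return {
            "modeling_ids": list(self.modeling_ids),
            "validation_ids": list(self.validation_ids),
            "seed": self.seed,
            "strata": [float(e) for e in self.strata],
        }


def stratified_split(
    trait: TraitVector,
    train_fraction: float = 2.0 / 3.0,
    n_strata: int = 3,
    seed: int = 0,
) -> SplitResult:
    """Quantile-stratified random split into modeling and validation sets.

    Samples are binned into ``n_strata`` LNC quantile bins; a seeded shuffle
    within each bin allocates samples to the modeling set, with per-bin
    quotas rounded by the largest-remainder method so the global modeling
    count is exactly floor(n * train_fraction).
    """
    n = len(trait)
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    if not 1 <= n_strata <= n:
        raise ConfigurationError(f"need 1 <= n_strata <= n, got {n_strata} with n={n}")
    y = trait.lnc
    edges = np.quantile(y, np.linspace(0, 1, n_strata + 1))
    # interior edges only; duplicates collapse bins for ties
    interior = np.unique(edges[1:-1])
    bins = np.searchsorted(interior, y, side="left")
    rng = np.random.default_rng(seed)
    target_total = int(np.floor(n * train_fraction))
    bin_labels = np.unique(bins)
    sizes = np.array([(bins == b).sum() for b in bin_labels])
    quotas_f = sizes * train_fraction
    base = np.floor(quotas_f).astype(int)
    short = target_total - base.sum()
    # distribute the remainder to the largest fractional parts, ties by bin order
    order = np.argsort(-(quotas_f - base), kind="stable")
    quotas = base.copy()
    for b in order[:short]:
        quotas[b] += 1
    modeling, validation = [], []
    ids = np.asarray(trait.sample_ids, dtype=object)
    for b, q in zip(bin_labels, quotas):
        members = np.flatnonzero(bins == b)
        perm = rng.permutation(members.size)
        chosen = members[perm]
        modeling.extend(ids[chosen[:q]])
        validation.extend(ids[chosen[q:]])
    return SplitResult(
        modeling_ids=modeling,
        validation_ids=validation,
        seed=seed,
        strata=list(edges),
    )


# ---------------------------------------------------------------------------
# Combines


COMBINE_MEMBERS: dict[int, tuple[str, ...]] = {
    1: ("empirical",),
    2: ("pair",),
    3: ("triple",),
    4: ("empirical", "pair"),
    5: ("empirical", "triple"),
    6: ("pair", "triple"),
    7: ("empirical", "pair", "triple"),
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """One index feature: family, form name, and (for parametric forms) bands."""

    family: str  # "empirical" | "pair" | "triple"
    form: str
    bands: tuple = ()

    @property
    def label(self) -> str:
        if not self.bands:
            return self.form
        return f"{self.form}({','.join(str(int(b)) for b in self.bands)})"


@dataclass
class CombineSpec:
    combine_id: int
    members: list  # FeatureDescriptor, in family order empirical -> pair -> triple

    def to_json(self) -> str:
        return json.dumps(
            {
                "combine_id": self.combine_id,
                "members": [
                    {"family": m.family, "form": m.form, "bands": [float(b) for b in m.bands]}
                    for m in self.members
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CombineSpec":
        d = json.loads(text)
        return cls(
            combine_id=d["combine_id"],
            members=[
                FeatureDescriptor(m["family"], m["form"], tuple(m["bands"]))
                for m in d["members"]
            ],
        )


@dataclass
class FeatureMatrix:
    sample_ids: list
    names: list
    values: np.ndarray  # n x p

    def select_samples(self, sample_ids: Sequence) -> "FeatureMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return FeatureMatrix(list(sample_ids), self.names, self.values[idx])


def combine_spec_from_screening(
    combine_id: int,
    empirical: Sequence[str] = (),
    osi2: Sequence = (),
    osi3: Sequence = (),
) -> CombineSpec:
    """Assemble a CombineSpec from significance-filtered family members.

    ``empirical`` is a list of empirical form names; ``osi2``/``osi3`` are
    ScreeningResult objects (or (form, bands) tuples) for the optimal
    two-/three-band indices.
    """
    if combine_id not in COMBINE_MEMBERS:
        raise ConfigurationError(f"combine_id must be 1..7, got {combine_id}")
    members = []
    fams = COMBINE_MEMBERS[combine_id]

    def _bands(entry):
        return tuple(entry.best_bands) if hasattr(entry, "best_bands") else tuple(entry[1])

    def _form(entry):
        return entry.form if hasattr(entry, "form") else entry[0]

    if "empirical" in fams:
        members += [FeatureDescriptor("empirical", name) for name in empirical]
    if "pair" in fams:
        members += [FeatureDescriptor("pair", _form(e), _bands(e)) for e in osi2]
    if "triple" in fams:
        members += [FeatureDescriptor("triple", _form(e), _bands(e)) for e in osi3]
    return CombineSpec(combine_id, members)


def build_feature_matrix(spec: CombineSpec, spectra: SpectrumSet) -> FeatureMatrix:
    """Evaluate every member index of a CombineSpec on the given spectra."""
    cols, names = [], []
    for m in spec.members:
        iv = si.evaluate_form(spectra, m.form, m.bands)
        cols.append(iv.values)
        names.append(m.label)
    if not cols:
        raise ConfigurationError(f"Combine {spec.combine_id} has no member features")
    return FeatureMatrix(list(spectra.sample_ids), names, np.column_stack(cols))


def build_combine(
    combine_id: int,
    empirical: Sequence[str],
    osi2: Sequence,
    osi3: Sequence,
    spectra: SpectrumSet,
) -> FeatureMatrix:
    """One-call assembly: family membership -> CombineSpec -> FeatureMatrix."""
    spec = combine_spec_from_screening(combine_id, empirical, osi2, osi3)
    return build_feature_matrix(spec, spectra)
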