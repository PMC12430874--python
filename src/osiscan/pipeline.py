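"""End-to-end orchestration: simulate -> preprocess -> screen -> prepare -> fit.

A RunConfig is a single serializable document sufficient to reproduce a
run bit-for-bit (given deterministic settings).  Every stage writes its
artifacts under the run directory and nothing mutates an input file; a
manifest records the config hash, package version and per-stage wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .spectra_io import (
    PreprocessConfig,
    SpectrumSet,
    TraitVector,
    read_spectra,
    read_trait,
    sg_smooth,
    write_spectra,
    write_trait,
)
from .synthetic_data import SynthConfig, generate_canopy_dataset
from .spectral_indices import EMPIRICAL_FORMS, PAIR_FORMS, TRIPLE_FORMS, eval_empirical
from .osi_screening import pearson_r, screen_pairs, screen_triples, select_significant
from .dataset_prep import (
    COMBINE_MEMBERS,
    FeatureMatrix,
    build_feature_matrix,
    combine_spec_from_screening,
    grubbs_filter,
    stratified_split,
)
from .regressors import default_configs, run_grid

log = logging.getLogger("osiscan")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; flags override file values in the CLI."""

    out_dir: str = "osiscan_run"
    spectra_path: str | None = None  # None => simulate
    trait_path: str | None = None
    seed: int = 7
    # simulation (used when spectra_path is None)
    n_samples: int = 66
    noise_sd: float = 0.005
    lnc_range: tuple[float, float] = (15.0, 50.0)
    # preprocessing
    sg_window: int = 9
    sg_polyorder: int = 2
    # screening
    pair_stride: float = 1.0
    triple_stride: float = 5.0
    alpha: float = 0.05
    top_k: int = 20
    screen_on: str = "modeling"  # or "all"
    search_range: tuple[float, float] | None = None
    write_rmatrix: bool = False
    # split
    train_fraction: float = 2.0 / 3.0
    n_strata: int = 3

    def validate(self) -> None:
        if (self.spectra_path is None) != (self.trait_path is None):
            raise ConfigurationError("spectra_path and trait_path must be given together")
        if self.screen_on not in ("modeling", "all"):
            raise ConfigurationError("screen_on must be 'modeling' or 'all'")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        PreprocessConfig(sg_window=self.sg_window, sg_polyorder=self.sg_polyorder)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("lnc_range", "search_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        stages[name] = time.perf_counter()
        return name

    def done(name):
        stages[name] = time.perf_counter() - stages[name]

    # --- data -------------------------------------------------------------
    s = stage("data")
    if config.spectra_path is None:
        synth = SynthConfig(
            n_samples=config.n_samples,
            seed=config.seed,
            lnc_range=config.lnc_range,
            noise_sd=config.noise_sd,
        )
        spectra, trait = generate_canopy_dataset(synth)
    else:
        spectra = read_spectra(config.spectra_path)
        trait = read_trait(config.trait_path)
    done(s)

    # --- preprocess -------------------------------------------------------
    s = stage("preprocess")
    prep = PreprocessConfig(sg_window=config.sg_window, sg_polyorder=config.sg_polyorder)
    spectra = sg_smooth(spectra, prep)
    write_spectra(spectra, out / "spectra_smoothed.csv")
    done(s)

    # --- trait outliers + split -------------------------------------------
    s = stage("prepare")
    gr = grubbs_filter(trait, alpha=config.alpha)
    trait = trait.select_samples(gr.kept_ids)
    spectra = spectra.select_samples(gr.kept_ids)
    split = stratified_split(
        trait,
        train_fraction=config.train_fraction,
        n_strata=config.n_strata,
        seed=config.seed,
    )
    (out / "split.json").write_text(
        json.dumps({"grubbs_removed": gr.removed_ids, **split.to_dict()}, indent=2)
    )
    done(s)

    # --- screening ----------------------------------------------------------
    s = stage("screen")
    if config.screen_on == "modeling":
        scr_spectra = spectra.select_samples(split.modeling_ids)
        scr_trait = trait.select_samples(split.modeling_ids)
    else:
        scr_spectra, scr_trait = spectra, trait
    y = scr_trait.lnc

    empirical_entries = []
    for name in EMPIRICAL_FORMS:
        r, p = pearson_r(eval_empirical(scr_spectra, name).values, y)
        empirical_entries.append((name, r, p))
    pair_results = []
    for name in PAIR_FORMS:
        cmap, res = screen_pairs(
            scr_spectra,
            scr_trait,
            name,
            stride=config.pair_stride,
            top_k=config.top_k,
            search_range=config.search_range,
        )
        if config.write_rmatrix:
            np.savetxt(out / f"rmatrix_{name}.csv", cmap.matrix, delimiter=",")
        pair_results.append(res)
    triple_results = []
    for name in TRIPLE_FORMS:
        _, res = screen_triples(
            scr_spectra,
            scr_trait,
            name,
            stride=config.triple_stride,
            top_k=config.top_k,
            search_range=config.search_range,
        )
        triple_results.append(res)
    screening_doc = {
        "empirical": [{"form": n, "r": r, "p": p} for n, r, p in empirical_entries],
        "pairs": [r.to_dict() for r in pair_results],
        "triples": [r.to_dict() for r in triple_results],
    }
    (out / "screening.json").write_text(json.dumps(screening_doc, indent=2))
    done(s)

    # --- combines -----------------------------------------------------------
    s = stage("combine")
    sig_empirical = [n for n, _, _ in select_significant(empirical_entries, config.alpha)]
    sig_pairs = [
        r for r in pair_results if select_significant([(r.form, r.best_r, r.p_value)], config.alpha)
    ]
    sig_triples = [
        r for r in triple_results if select_significant([(r.form, r.best_r, r.p_value)], config.alpha)
    ]
    specs = {
        cid: combine_spec_from_screening(cid, sig_empirical, sig_pairs, sig_triples)
        for cid in COMBINE_MEMBERS
    }
    (out / "combines.json").write_text(
        json.dumps({cid: json.loads(sp.to_json()) for cid, sp in specs.items()}, indent=2)
    )
    feature_matrices = {cid: build_feature_matrix(sp, spectra) for cid, sp in specs.items()}
    done(s)

    # --- models ---------------------------------------------------------------
    s = stage("fit")
    grid = run_grid(feature_matrices, trait, split, default_configs(seed=config.seed))
    grid.to_csv(out / "metrics.csv", index=False)
    done(s)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "osiscan_version": __version__,
        "numpy_version": np.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stage_seconds": {k: round(v, 3) for k, v in stages.items()},
        "n_samples_after_grubbs": len(trait),
        "n_modeling": len(split.modeling_ids),
        "n_validation": len(split.validation_ids),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
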