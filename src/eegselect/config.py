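"""Flat run-configuration schema shared by the CLI and the experiment driver.

All numeric defaults of the pipeline live here, in one place:

    n_nests=30, max_iter=100, p_a=0.25, beta=1.5, alpha=1.0    (optimizer)
    w1=0.8, w2=0.2, k_neighbors=1, n_folds=10                  (fitness)
    n_runs=25                                                  (experiments)

A config file is a flat JSON object overriding any subset of these keys;
unknown keys are rejected at load.
"""

from __future__ import annotations

import json
from pathlib import Path

from .cuckoo import CSConfig
from .objective import ObjectiveConfig

__all__ = ["DEFAULTS", "load_config", "objective_config", "cs_config"]

DEFAULTS: dict = {
    # optimizer
    "n_nests": 30,
    "max_iter": 100,
    "p_a": 0.25,
    "beta": 1.5,
    "alpha": 1.0,
    "printed_transfer_rule": False,
    "replacement": "random",
    # fitness
    "w1": 0.8,
    "w2": 0.2,
    "k_neighbors": 1,
    "n_folds": 10,
    "fold_seed": 0,
    "stratified": True,
    "standardize": False,
    # features
    "ar_order": 5,
    "ar_method": "burg",
    "aggregate": "per_recording",
    # experiments
    "n_runs": 25,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Merge DEFAULTS <- file <- keyword overrides, validating keys."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = json.load(fh)
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    unknown = set(overrides) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(overrides)
    # fail fast on invalid values
    objective_config(cfg)
    cs_config(cfg)
    return cfg


def objective_config(cfg: dict, fold_seed: int | None = None) -> ObjectiveConfig:
    return ObjectiveConfig(
        w1=cfg["w1"],
        w2=cfg["w2"],
        k_neighbors=cfg["k_neighbors"],
        n_folds=cfg["n_folds"],
        fold_seed=cfg["fold_seed"] if fold_seed is None else fold_seed,
        stratified=cfg["stratified"],
        standardize=cfg["standardize"],
    )


def cs_config(cfg: dict, seed: int = 0) -> CSConfig:
    return CSConfig(
        n_nests=cfg["n_nests"],
        max_iter=cfg["max_iter"],
        p_a=cfg["p_a"],
        beta=cfg["beta"],
        alpha=cfg["alpha"],
        seed=seed,
        printed_transfer_rule=cfg["printed_transfer_rule"],
        replacement=cfg["replacement"],
    )
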