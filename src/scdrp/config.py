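"""Configuration loading/validation and deterministic seed fan-out."""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "stage_seed"]

# Real-data defaults; the DAE/predictor widths follow the published
# hyperparameter table for the primary cisplatin dataset.
DEFAULT_CONFIG: dict = {
    "io": {"orientation": "samples_by_genes", "label_column": "response"},
    "qc": {"min_genes": 200, "min_cells": 3, "max_mito_frac": 0.10, "mito_prefix": "MT-"},
    "normalize": {"target_sum": 1.0e4},
    "balance": {"method": "oversample", "k_neighbors": 5},
    "split": {"test_frac": 0.20, "seed": 0},
    "dae": {
        "bottleneck": 512,
        "encoder_dims": [256, 128],
        "noise_rate": 0.2,
        "dropout": 0.3,
        "epochs": 500,
        "learning_rate": 1.0e-3,
    },
    "model": {
        "n_heads": 8,
        "n_tokens": 8,
        "predictor_dims": [128, 64],
        "dropout": 0.3,
    },
    "dann": {
        "omega": 0.25,
        "theta": 0.1,
        "epochs": 30,
        "batch_size": 128,
        "learning_rate": 1.0e-3,
        "cluster_resolution": 1.0,
    },
    "sim": {
        "n_genes": 300,
        "n_bulk": 400,
        "n_cells": 400,
        "n_latent": 10,
        "effect_size": 3.0,
        "domain_shift": 1.0,
        "imbalance": 0.5,
        "n_markers_per_class": 10,
        "dropout_rate": 0.3,
    },
    "seed": 0,
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def _validate(cfg: dict) -> None:
    qc = cfg["qc"]
    if not (0.0 <= qc["max_mito_frac"] <= 1.0):
        raise ConfigError("qc.max_mito_frac must lie in [0,1]")
    if not (0.0 < cfg["split"]["test_frac"] < 1.0):
        raise ConfigError("split.test_frac must lie in (0,1)")
    if cfg["balance"]["method"] not in ("smote", "oversample", "none"):
        raise ConfigError("balance.method must be smote | oversample | none")
    bottleneck = cfg["dae"]["bottleneck"]
    n_tokens = cfg["model"]["n_tokens"]
    if bottleneck % n_tokens != 0:
        raise ConfigError(
            f"dae.bottleneck ({bottleneck}) must be divisible by model.n_tokens ({n_tokens})"
        )
    token_dim = bottleneck // n_tokens
    n_heads = cfg["model"]["n_heads"]
    if n_heads < 0:
        raise ConfigError("model.n_heads must be ≥ 0")
    if n_heads > 0 and token_dim % n_heads != 0:
        raise ConfigError(
            f"token_dim ({token_dim}) must be divisible by model.n_heads ({n_heads})"
        )
    for key in ("omega", "theta"):
        if cfg["dann"][key] < 0:
            raise ConfigError(f"dann.{key} must be ≥ 0")


def load_config(path: str | None = None) -> dict:
    """Load a YAML/JSON config, apply defaults, reject unknown keys, and run
    cross-field checks. ``None`` or an empty file yields the full defaults."""
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        if text.strip():
            loaded = yaml.safe_load(text)
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise ConfigError("config root must be a mapping")
            user = loaded
    cfg = _merge(DEFAULT_CONFIG, user)
    _validate(cfg)
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_checksum(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
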