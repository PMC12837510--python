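"""YAML configuration with documented defaults.

The default values mirror the reference training recipe (mask ratio 0.75,
α = 0.01, β = 0.05, γ = 2.0, ω = 0.5, batch 64/32, warm-up then cosine);
the ``tiny`` profile used by the bundled pipeline command scales epochs and
dataset sizes to desk scale.  Any key can be overridden from a YAML file.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "model": {
        "image_size": 64,
        "patch_size": 8,
        "embed_dim": 64,
        "encoder_depth": 2,
        "encoder_heads": 4,
        "decoder_dim": 48,
        "decoder_depth": 1,
        "decoder_heads": 4,
        "mask_ratio": 0.75,
    },
    "data": {
        "n_pretrain": 200,
        "n_per_class": 50,
        "classes": [0, 1],
        "lesion_contrast": 300.0,
        "domain1_preset": "jmid_mediastinal",
        "domain2_preset": "jmid_lung",
        "task_preset": "jmid_mediastinal",
    },
    "stage1": {
        "epochs": 30,
        "batch_size": 64,
        "warmup_epochs": 4,
        "peak_lr": 1.5e-3,
        "weight_decay": 0.01,
    },
    "stage3": {
        "epochs": 30,
        "batch_size": 32,
        "warmup_epochs": 4,
        "peak_lr": 1.5e-3,
        "weight_decay": 0.01,
    },
    "buffer": {"alpha": 0.01, "beta": 0.05, "mode": "latent"},
    "distill": {"mode": "wkd_bke", "gamma": 2.0, "omega": 0.5, "lambda_fd": 1.0},
    "finetune": {"epochs": 80, "batch_size": 32, "lr": 3e-3, "weight_decay": 0.01},
    "eval": {"seeds": [0, 10, 100]},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise ConfigurationError(f"unknown config key {path + key!r}")
        if isinstance(out[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(out[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    text = Path(path).read_text()
    override = yaml.safe_load(text) or {}
    if not isinstance(override, dict):
        raise ConfigurationError("config file must contain a YAML mapping")
    return _merge(DEFAULTS, override)
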