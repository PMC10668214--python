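"""YAML run configuration with defaults and reproducibility metadata."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "preprocess": {
        "highpass_hz": 0.5,
        "lowpass_hz": 45.0,
        "notch_hz": 50.0,
        "order": 4,
        "zero_phase": True,
        "target_rate_hz": 256.0,
    },
    "montage": {
        "reference": "earlobe",  # or "common_average"
    },
    "model": {
        "architecture": "tcn",
        "hyperparameters": {},
        "epochs": 20,
        "max_learning_rate": 1e-2,
        "batch_size": 64,
    },
    "decision": {
        "mode": "TMDM",
        "threshold": 0.5,
        "spatial_rule": "overlap",
    },
    "evaluation": {
        "thresholds": None,  # default grid
        "target_sensitivity": 0.8,
        "bootstrap_iterations": 0,
    },
    "simulation": {
        "duration_s": 600.0,
        "ied_rate_per_min": 2.0,
        "ied_amplitude_uv": 120.0,
        "alpha_amplitude_uv": 30.0,
        "pink_noise_scale": 10.0,
        "n_segments_per_class": 200,
    },
    "train": {
        "recordings": [],  # list of {edf: path, annotations: path}
        "synthetic_segments": None,  # or {n_per_class: N}
    },
    "detect": {
        "recordings": [],  # list of edf paths
        "checkpoint": None,
        "threshold_file": None,
    },
    "evaluate": {
        "recordings": [],  # list of {edf: path, events: path}
        "checkpoint": None,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults merged with an optional YAML file."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return _merge(json.loads(json.dumps(DEFAULT_CONFIG)), user)


def write_run_metadata(out_dir, command: str, config: dict, seed: int) -> None:
    """Resolved-config snapshot + manifest beside every run's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    manifest = {
        "command": command,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": __import__("iedscan").__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
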