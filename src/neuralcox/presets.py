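"""Shipped hyper-parameter presets, one YAML file per benchmark experiment.

The simulated-experiment presets (``sim_linear``, ``sim_nonlinear``,
``sim_treatment``) drive the reproduction pipeline; the clinical-cohort
presets (``whas``, ``support``, ``metabric``, ``gbsg``) are provided for
users with access to those datasets.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .network import NetworkConfig

__all__ = ["available_presets", "load_preset"]


def available_presets() -> list[str]:
    """Names of the shipped presets."""
    pkg = resources.files(__package__) / "presets"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str, **overrides) -> NetworkConfig:
    """Load a named preset, optionally overriding fields (e.g. seed, n_epochs)."""
    path = resources.files(__package__) / "presets" / f"{name}.yaml"
    if not path.is_file():
        raise ValueError(f"unknown preset {name!r}; available: {available_presets()}")
    cfg = yaml.safe_load(path.read_text())
    cfg.update(overrides)
    return NetworkConfig.from_dict(cfg)


def load_config(path, **overrides) -> NetworkConfig:
    """Load a NetworkConfig from an arbitrary YAML/JSON file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg.update(overrides)
    return NetworkConfig.from_dict(cfg)
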