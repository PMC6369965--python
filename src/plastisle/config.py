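"""Flat config-file loading (YAML or JSON) with CLI override semantics.

A config file is a flat mapping whose keys are exactly the parameter field
names (``sigma2_DI`` ... ``alpha_T``, ``Gaa`` ... ``omega_b``, ``m``).  An
empty file yields the defaults; unknown keys are rejected by name.  Overrides
(typically CLI flags) are merged on top of the file, and the fully resolved
set is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import fields
from pathlib import Path

import yaml

from .params import (
    DispersalParams,
    EnvironmentParams,
    GeneticSelectionParams,
    ParameterBundle,
    ParameterError,
)

__all__ = ["load_config", "bundle_from_mapping", "KNOWN_KEYS"]

logger = logging.getLogger(__name__)

KNOWN_KEYS = (
    tuple(f.name for f in fields(EnvironmentParams))
    + tuple(f.name for f in fields(GeneticSelectionParams))
    + tuple(f.name for f in fields(DispersalParams))
)


def bundle_from_mapping(mapping: dict) -> ParameterBundle:
    """Build a validated bundle from a flat key->value mapping."""
    unknown = sorted(set(mapping) - set(KNOWN_KEYS))
    if unknown:
        raise ParameterError(f"unknown configuration keys: {', '.join(unknown)}")
    env_names = {f.name for f in fields(EnvironmentParams)}
    gen_names = {f.name for f in fields(GeneticSelectionParams)}
    env = EnvironmentParams(**{k: v for k, v in mapping.items() if k in env_names})
    gen = GeneticSelectionParams(**{k: v for k, v in mapping.items() if k in gen_names})
    disp = DispersalParams(**{k: v for k, v in mapping.items() if k in {"m"}})
    return ParameterBundle(env, gen, disp).validate()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ParameterBundle:
    """Load defaults + config file + overrides into a validated bundle.

    ``overrides`` entries with value ``None`` are ignored (unset CLI flags).
    """
    mapping: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            loaded = json.loads(text) if text.strip() else {}
        else:
            loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must contain a flat mapping")
        mapping.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            mapping[key] = value
    bundle = bundle_from_mapping(mapping)
    logger.info("resolved parameters: %s", bundle.to_dict())
    return bundle
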