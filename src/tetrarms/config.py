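"""YAML configuration: strength-table overrides, policy and design knobs.

Schema (all sections optional)::

    strength_overrides:          # list of [primer_base, template_base, strength]
      - [G, G, medium]
    policy:                      # PcrPolicy field overrides
      annealing_temp_c: 61.0
    constraints:                 # DesignConstraints field overrides
      product_max: 500
    scoring:                     # candidate-ranking weights
      tm_uniformity: 0.5
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path
from typing import Any

import yaml

from .errors import ParseError
from .mismatch import StrengthTable
from .model import DesignConstraints, PcrPolicy


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data


def strength_table_from_config(config: dict[str, Any]) -> StrengthTable:
    table = StrengthTable.default()
    overrides = config.get("strength_overrides") or []
    if overrides:
        table = table.override([tuple(t) for t in overrides])
    return table


def _apply(obj, section: dict[str, Any] | None, what: str):
    if not section:
        return obj
    valid = {f.name for f in fields(obj)}
    unknown = set(section) - valid
    if unknown:
        raise ParseError(f"unknown {what} option(s): {sorted(unknown)}")
    return replace(obj, **section)


def policy_from_config(config: dict[str, Any], **kwargs) -> PcrPolicy:
    policy = _apply(PcrPolicy(), config.get("policy"), "policy")
    return replace(policy, **kwargs) if kwargs else policy


def constraints_from_config(config: dict[str, Any]) -> DesignConstraints:
    constraints = _apply(
        DesignConstraints(), config.get("constraints"), "constraints"
    )
    if config.get("scoring"):
        scoring = dict(constraints.scoring)
        scoring.update(config["scoring"])
        constraints = replace(constraints, scoring=scoring)
    return constraints
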