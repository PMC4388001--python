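"""Scenario configuration loading (YAML/JSON) and the Table-style grid."""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .errors import ConfigError, InvalidArgumentError
from .experiment import ScenarioConfig

_FIELD_NAMES = {f.name for f in fields(ScenarioConfig)}

GRID_POPULATION_SIZES = (10, 30, 50)
GRID_HERITABILITIES = (0.10, 0.25, 0.50)
GRID_MARKER_DENSITIES = (2525, 5050, 10100)


def _make_config(overrides: dict) -> ScenarioConfig:
    unknown = set(overrides) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        cfg = ScenarioConfig(**overrides)
        cfg.validate()
    except (InvalidArgumentError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def table_grid(defaults: dict | None = None) -> list[ScenarioConfig]:
    """The 9 study scenarios: one-at-a-time sweeps of N, h2 and marker
    density around the default (N=50, h2=0.25, 10100 markers/chromosome)."""
    defaults = dict(defaults or {})
    grid = []
    for n in GRID_POPULATION_SIZES:
        grid.append(_make_config({**defaults, "N": n}))
    for h2 in GRID_HERITABILITIES:
        grid.append(_make_config({**defaults, "h2": h2}))
    for snps in GRID_MARKER_DENSITIES:
        grid.append(_make_config({**defaults, "markers_per_chromosome": snps}))
    return grid


def load_config(path: str | Path) -> list[ScenarioConfig]:
    """Load scenarios from a YAML/JSON file.

    Accepted shapes:

    * empty file -> the single default scenario;
    * a flat mapping of ScenarioConfig keys -> one scenario;
    * ``{"defaults": {...}, "scenarios": [{...}, ...]}``;
    * ``{"grid": "table1", ...defaults...}`` -> the 9-scenario grid.

    Unknown keys or out-of-range values raise :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return [_make_config({})]
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    if "grid" in raw:
        grid_name = raw.pop("grid")
        if grid_name != "table1":
            raise ConfigError(f"unknown grid {grid_name!r}")
        return table_grid(raw)
    if "scenarios" in raw:
        defaults = raw.pop("defaults", {})
        scenarios = raw.pop("scenarios")
        if raw:
            raise ConfigError(f"unknown config key(s): {sorted(raw)}")
        if not isinstance(defaults, dict) or not isinstance(scenarios, list):
            raise ConfigError("defaults must be a mapping, scenarios a list")
        return [_make_config({**defaults, **s}) for s in scenarios]
    return [_make_config(raw)]


def apply_overrides(cfg: ScenarioConfig, **overrides) -> ScenarioConfig:
    unknown = set(overrides) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    out = replace(cfg, **overrides)
    out.validate()
    return out
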