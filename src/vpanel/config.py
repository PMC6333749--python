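"""Run configuration: defaults, YAML config file, CLI flag precedence.

Precedence is flags > config file > built-in defaults. The config file is a
flat key-value YAML document whose keys mirror the CLI flags.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .variants import FilterConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "setup_logging"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    obo: Optional[Path] = None
    annotations: Optional[Path] = None
    aliases: Optional[Path] = None
    vcf: Optional[Path] = None
    sidecar: Optional[Path] = None
    trio: Optional[Path] = None
    cohort: Optional[Path] = None
    sample: str = "proband"
    min_count: int = 1
    min_tier: int = 1
    bidirectional: bool = False
    strict: bool = False
    seed: int = 0
    verbosity: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)

    _PATH_FIELDS = ("obo", "annotations", "aliases", "vcf", "sidecar", "trio", "cohort")

    def validate(self, required: tuple[str, ...] = ()) -> "RunConfig":
        for name in self._PATH_FIELDS:
            p = getattr(self, name)
            if name in required and p is None:
                raise ConfigError(f"missing required input: --{name}")
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        return self


_FILTER_KEYS = {"max_af_dominant", "max_af_recessive", "min_panel_tier"}


def load_config(path: str | Path, overrides: Optional[dict] = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus flag overrides."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}")
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a key-value mapping")
    merged = {**raw, **{k: v for k, v in (overrides or {}).items() if v is not None}}
    filter_kwargs = {k: merged.pop(k) for k in list(merged) if k in _FILTER_KEYS}
    known = {f.name for f in fields(RunConfig)} - {"filters"}
    unknown = set(merged) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for name in RunConfig._PATH_FIELDS:
        if merged.get(name) is not None:
            merged[name] = Path(merged[name])
    cfg = RunConfig(**merged)
    if filter_kwargs:
        cfg = replace(cfg, filters=replace(cfg.filters, **filter_kwargs))
    return cfg


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING
    if verbosity == 1:
        level = logging.INFO
    elif verbosity >= 2:
        level = logging.DEBUG
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )
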