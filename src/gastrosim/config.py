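"""Configuration loading, validation and packaged fixtures.

Protocols and drugs are described in YAML; validation is strict (unknown
fields are rejected with a field-level message).  A handful of fixture
scenarios and compounds ship with the package and can be referenced by
name anywhere a path is accepted.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path
from typing import Any

import yaml
from pydantic import ValidationError

from .drug import DrugProperties
from .protocol import Protocol

__all__ = [
    "ConfigError",
    "list_fixtures",
    "load_protocol",
    "load_drug",
    "dump_protocol",
    "dump_drug",
    "apply_overrides",
    "reference_auc_table",
]

_FIXTURES = files("gastrosim") / "fixtures"
_DATA = files("gastrosim") / "data"


class ConfigError(ValueError):
    """Invalid or unresolvable configuration."""


def _format_validation_error(err: ValidationError, source: str) -> str:
    lines = [f"invalid configuration in {source}:"]
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  field '{loc}': {e['msg']}")
    return "\n".join(lines)


def list_fixtures() -> dict[str, list[str]]:
    """Names of the packaged protocol and drug fixtures."""
    protocols, drugs = [], []
    for entry in sorted(_FIXTURES.iterdir(), key=lambda e: e.name):
        if not entry.name.endswith(".yaml"):
            continue
        raw = yaml.safe_load(entry.read_text())
        (protocols if "prandial_state" in raw else drugs).append(
            entry.name.removesuffix(".yaml")
        )
    return {"protocols": protocols, "drugs": drugs}


def _resolve(name_or_path: str | Path) -> tuple[str, str]:
    """Return (yaml text, source label) for a path or fixture name."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") or p.exists():
        if not p.exists():
            raise ConfigError(f"no such file: {p}")
        return p.read_text(), str(p)
    fixture = _FIXTURES / f"{name_or_path}.yaml"
    try:
        return fixture.read_text(), f"fixture '{name_or_path}'"
    except FileNotFoundError:
        raise ConfigError(
            f"'{name_or_path}' is neither a file nor a packaged fixture; "
            f"known fixtures: {list_fixtures()}"
        ) from None


def _coerce(value: str) -> Any:
    """Parse an override value with YAML semantics (numbers, lists, bools)."""
    return yaml.safe_load(value)


def apply_overrides(raw: dict, overrides: dict[str, str] | None) -> dict:
    """Apply dotted ``key=value`` overrides onto a raw config mapping."""
    if not overrides:
        return raw
    out = dict(raw)
    for key, value in overrides.items():
        target = out
        parts = key.split(".")
        for part in parts[:-1]:
            if part not in target or not isinstance(target[part], dict):
                target[part] = {}
            target = target[part]
        target[parts[-1]] = _coerce(value) if isinstance(value, str) else value
    return out


def load_protocol(
    name_or_path: str | Path, overrides: dict[str, str] | None = None
) -> Protocol:
    text, source = _resolve(name_or_path)
    raw = apply_overrides(yaml.safe_load(text), overrides)
    try:
        return Protocol.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err, source)) from None


def load_drug(
    name_or_path: str | Path, overrides: dict[str, str] | None = None
) -> DrugProperties:
    text, source = _resolve(name_or_path)
    raw = apply_overrides(yaml.safe_load(text), overrides)
    try:
        return DrugProperties.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err, source)) from None


def dump_protocol(protocol: Protocol) -> str:
    return yaml.safe_dump(protocol.model_dump(mode="json"), sort_keys=False)


def dump_drug(drug: DrugProperties) -> str:
    return yaml.safe_dump(drug.model_dump(mode="json"), sort_keys=False)


def reference_auc_table(name: str):
    """Packaged reference AUC summary tables for scenario comparisons.

    ``name`` is ``itraconazole_water_effect`` or ``indinavir_food_effect``.
    """
    import pandas as pd

    path = _DATA / f"{name}_aucs.csv"
    try:
        with path.open("rb") as fh:
            return pd.read_csv(fh)
    except FileNotFoundError:
        raise ConfigError(f"no packaged AUC table named '{name}'") from None
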