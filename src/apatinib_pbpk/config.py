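"""Packaged fixture access and YAML loading.

All physiological constants, tissue compositions, gut geometry, impairment
multipliers and perpetrator files live as editable YAML under
``apatinib_pbpk/data``; they are the declared calibration surface of the
model and can be overridden by passing explicit paths or dicts to the
constructors that consume them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

_DATA = resources.files("apatinib_pbpk") / "data"


def data_path(name: str) -> Path:
    """Return the path of a packaged data file."""
    p = _DATA / name
    if not p.is_file():
        raise ConfigurationError(f"no packaged data file named {name!r}")
    return Path(str(p))


def load_yaml(source: str | Path | dict) -> dict:
    """Load a YAML mapping from a packaged name, a path, or pass a dict through."""
    if isinstance(source, dict):
        return source
    p = Path(source)
    if not p.is_file():
        p = data_path(str(source))
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{p} did not parse to a mapping")
    return doc


def list_perpetrators() -> list[str]:
    """Names of all packaged perpetrator fixtures."""
    folder = _DATA / "perpetrators"
    return sorted(f.name.removesuffix(".yaml") for f in folder.iterdir() if f.name.endswith(".yaml"))


def perpetrator_path(name: str) -> Path:
    p = _DATA / "perpetrators" / f"{name}.yaml"
    if not p.is_file():
        raise ConfigurationError(f"no packaged perpetrator fixture {name!r}")
    return Path(str(p))
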