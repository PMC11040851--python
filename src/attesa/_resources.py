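"""Loaders for the YAML resources shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any

import yaml


def _read_resource(name: str) -> dict[str, Any]:
    ref = resources.files("attesa.resources").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def default_lexicon() -> dict[str, Any]:
    return _read_resource("lexicon.yaml")


@lru_cache(maxsize=None)
def default_numbers() -> dict[str, Any]:
    return _read_resource("numbers.yaml")


@lru_cache(maxsize=None)
def default_grammar_config() -> dict[str, Any]:
    return _read_resource("grammar.yaml")


def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
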