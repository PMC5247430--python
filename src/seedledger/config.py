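"""Configuration file and the customizable lab-guidelines document.

A small YAML file names the database location, the active login and the
path of the laboratory's own guidelines document (naming conventions,
storage rules, accepted file formats).  The guidelines hook mirrors an
always-visible "our lab" entry point: unset on first use, configurable and
re-configurable thereafter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .errors import GuidelinesNotConfiguredError, NotFoundError, ValidationError

DEFAULT_CONFIG_PATH = os.path.join(
    os.path.expanduser("~"), ".config", "seedledger", "config.yaml")


@dataclass
class Config:
    database: str = "seedledger.db"
    login: str = "admin"
    guidelines: str | None = None
    path: str = field(default=DEFAULT_CONFIG_PATH, compare=False)


def load_config(path: str | None = None) -> Config:
    path = path or DEFAULT_CONFIG_PATH
    if not os.path.exists(path):
        return Config(path=path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path!r} must be a YAML mapping")
    return Config(database=data.get("database", "seedledger.db"),
                  login=data.get("login", "admin"),
                  guidelines=data.get("guidelines"), path=path)


def save_config(cfg: Config) -> None:
    os.makedirs(os.path.dirname(cfg.path) or ".", exist_ok=True)
    with open(cfg.path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"database": cfg.database, "login": cfg.login,
                        "guidelines": cfg.guidelines}, fh)


def set_guidelines(cfg: Config, document_path: str) -> Config:
    """Configure (or replace) the lab-guidelines document."""
    if not os.path.exists(document_path):
        raise NotFoundError(f"no such document: {document_path!r}")
    cfg.guidelines = document_path
    save_config(cfg)
    return cfg


def show_lab_guidelines(cfg: Config) -> bytes:
    """Return the configured guidelines document content.

    Raises :class:`GuidelinesNotConfiguredError` when no document has been
    configured yet (the caller should prompt for one), and
    :class:`NotFoundError` when the configured file has gone missing.
    """
    if not cfg.guidelines:
        raise GuidelinesNotConfiguredError(
            "no lab-guidelines document configured yet; set one first")
    if not os.path.exists(cfg.guidelines):
        raise NotFoundError(
            f"configured guidelines document {cfg.guidelines!r} not found")
    with open(cfg.guidelines, "rb") as fh:
        return fh.read()
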