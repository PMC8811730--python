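"""Run manifests: a structured key-value record of every pipeline run."""

from __future__ import annotations

import datetime
import hashlib
from pathlib import Path

import yaml

from . import __version__

__all__ = ["write_manifest", "read_manifest", "file_digest"]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    parameters: dict,
    seed: int | None = None,
    inputs: dict[str, str | Path] | None = None,
) -> dict:
    """Write a YAML manifest recording command, parameters, seed and input
    digests; returns the manifest dict."""
    manifest = {
        "command": command,
        "parameters": {k: _plain(v) for k, v in parameters.items()},
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in (inputs or {}).items()
        },
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (list, tuple)):
        return [_plain(x) for x in v]
    if hasattr(v, "item"):  # numpy scalar
        return v.item()
    return v
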