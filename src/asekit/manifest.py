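"""Run manifests for reproducible pipeline invocations."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__

MANIFEST_NAME = "manifest.json"


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    config: dict,
    inputs: dict[str, str] | None = None,
    record_counts: dict[str, int] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a JSON manifest (config, input digests, seed, version, counts).

    Input digests are taken before the stage runs so the manifest pins the
    exact bytes consumed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digests = {
        name: file_digest(path) for name, path in (inputs or {}).items()
    }
    doc = {
        "tool": "ase-diff",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "input_digests": digests,
        "record_counts": record_counts or {},
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")
    return path
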