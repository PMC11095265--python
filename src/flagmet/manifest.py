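"""Run provenance: one manifest per output directory."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir,
    subcommand: str,
    config: dict,
    seed: int | None,
    inputs: list | None = None,
) -> Path:
    """Write ``manifest.json`` (tool version, resolved config, seeds,
    input checksums, timestamp) into ``outdir``."""
    from flagmet import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "flagmet",
        "version": __version__,
        "subcommand": subcommand,
        "config": config,
        "seed": seed,
        "inputs": {
            str(p): _checksum(Path(p)) for p in (inputs or []) if Path(p).is_file()
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
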