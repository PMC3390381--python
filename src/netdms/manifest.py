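"""Run manifests: reproducibility metadata written next to every output."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir, command: str, params: dict, inputs: list) -> Path:
    """Write <out_dir>/manifest.json recording inputs, parameters and seeds."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "netdms_version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "parameters": params,
        "inputs": {
            str(p): _checksum(p) for p in inputs if p and Path(p).is_file()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
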