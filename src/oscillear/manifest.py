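"""Run manifests: resolved configuration plus output digests.

A manifest records everything needed to reproduce a run bitwise: the
command, the fully resolved parameter set, every seed, the package version
and unit system, and a SHA-256 digest of each output file.  Re-executing
from the manifest must reproduce the digests exactly — the integrators are
fixed-step and every random input is seeded.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    params: dict,
    outputs: list[str | Path],
    seed: int | None = None,
    unit: str | None = None,
) -> dict:
    """Write the manifest JSON atomically; returns the manifest dict."""
    from . import __version__

    manifest = {
        "command": command,
        "params": params,
        "seed": seed,
        "unit": unit,
        "version": __version__,
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    tmp.replace(path)
    return manifest


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def verify_manifest(path: str | Path) -> dict[str, bool]:
    """Compare each recorded output digest against the file on disk."""
    man = load_manifest(path)
    return {
        out: Path(out).exists() and file_digest(out) == digest
        for out, digest in man["outputs"].items()
    }
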