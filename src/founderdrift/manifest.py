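"""Run manifests: enough provenance to re-run a command bit-identically."""
from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

__all__ = ["write_manifest", "sha256_file"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_manifest(outdir, command: str, config, seed, outputs) -> Path:
    """Write ``manifest.json`` listing config, seed and output digests."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "seed": seed,
        "config": _jsonable(config),
        "outputs": {
            str(Path(p).name): sha256_file(p) for p in outputs
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
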