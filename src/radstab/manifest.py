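"""Run manifest: config snapshots, seeds and artifact hashes per stage."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

__all__ = ["sha256_file", "append_stage", "read_manifest"]

MANIFEST_NAME = "run_manifest.json"


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_manifest(outdir: str | Path) -> list[dict[str, Any]]:
    path = Path(outdir) / MANIFEST_NAME
    if not path.exists():
        return []
    return json.loads(path.read_text())


def append_stage(
    outdir: str | Path,
    stage: str,
    config: dict[str, Any],
    outputs: Iterable[str | Path],
) -> None:
    """Append one stage record (config snapshot + hashed outputs)."""
    outdir = Path(outdir)
    entries = read_manifest(outdir)
    entries.append(
        {
            "stage": stage,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "config": config,
            "outputs": {
                str(Path(p).relative_to(outdir)): sha256_file(p) for p in outputs
            },
        }
    )
    (outdir / MANIFEST_NAME).write_text(json.dumps(entries, indent=2, default=str))
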