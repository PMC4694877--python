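"""Run manifests and the aggregate summary report."""
from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, subcommand: str, config: dict,
                   inputs: list[Path], seed: int | None) -> Path:
    """Write the single manifest.json for an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config": config,
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "seed": seed,
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def output_digests(outdir: Path) -> dict[str, str]:
    """Digest of every output file except the manifest itself."""
    outdir = Path(outdir)
    skip = {"manifest.json", "run.log"}  # both carry timestamps
    return {p.name: _digest(p) for p in sorted(outdir.iterdir())
            if p.is_file() and p.name not in skip}


def summarize(tables: dict[str, pd.DataFrame], outdir: Path) -> Path:
    """Aggregate per-pair metric tables into one TSV plus a text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for name, df in tables.items():
        d = df.copy()
        d.insert(0, "source", name)
        frames.append(d)
    combined = pd.concat(frames, ignore_index=True)
    tsv = outdir / "summary.tsv"
    combined.to_csv(tsv, sep="\t", index=False)
    lines = ["ffpe-concord summary", "====================", ""]
    for name, df in tables.items():
        lines.append(f"[{name}]")
        for r in df.itertuples(index=False):
            vals = "\t".join(str(v) for v in r)
            lines.append(f"  {vals}")
        lines.append("")
    (outdir / "summary.txt").write_text("\n".join(lines))
    return tsv
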