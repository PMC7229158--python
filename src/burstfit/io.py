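"""Reading and writing count tables, chains and run manifests.

Counts travel as long/tidy CSV or TSV with header columns
``cell_id, condition, count``; generated datasets get a JSON provenance
sidecar (seed, parameters, generator); pipeline runs write a manifest
recording seeds and SHA-256 digests of every output file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountData, REQUIRED_COLUMNS

__all__ = ["read_counts", "write_counts", "file_digest", "write_manifest"]


def read_counts(path: str | Path) -> CountData:
    """Parse a counts CSV/TSV, rejecting malformed rows with row numbers.

    Row numbers in error messages are 1-based file lines (header = line 1).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype={"cell_id": str, "condition": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    counts = pd.to_numeric(frame["count"], errors="coerce")
    bad = counts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: non-numeric count at row {row}")
    nonint = counts != np.floor(counts)
    if nonint.any():
        row = int(np.flatnonzero(nonint)[0]) + 2
        raise ValueError(f"{path}: non-integer count {counts.iloc[row - 2]} at row {row}")
    neg = counts < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0]) + 2
        raise ValueError(f"{path}: negative count at row {row}")
    frame = frame.assign(count=counts.astype(np.int64))

    prov = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
    return CountData(frame=frame[list(REQUIRED_COLUMNS)], provenance=prov)


def write_counts(data: CountData, path: str | Path, sidecar: bool = True) -> Path:
    """Write canonical CSV (and a JSON provenance sidecar)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    data.frame[list(REQUIRED_COLUMNS)].to_csv(path, sep=sep, index=False, lineterminator="\n")
    if sidecar and data.provenance:
        side = path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps(_jsonable(data.provenance), indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, entries: dict) -> Path:
    """Persist a run manifest (config echo, seeds, output digests)."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(entries), indent=2, sort_keys=True) + "\n")
    return path
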