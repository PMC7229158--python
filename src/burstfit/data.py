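"""Labelled per-cell mRNA count tables.

The canonical on-disk format is a long/tidy CSV with columns
``cell_id, condition, count`` (one row per cell), optionally accompanied
by a JSON provenance sidecar recording seeds and generator parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["CountData"]

REQUIRED_COLUMNS = ("cell_id", "condition", "count")


@dataclass
class CountData:
    """Per-cell mRNA copy numbers for one or more experimental conditions."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        counts = self.frame["count"]
        if not pd.api.types.is_integer_dtype(counts):
            as_float = counts.astype(float)
            if not np.all(as_float == np.floor(as_float)):
                raise ValueError("counts must be integers")
            self.frame = self.frame.assign(count=as_float.astype(np.int64))
        if (self.frame["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        for cond, grp in self.frame.groupby("condition", sort=False):
            if grp["cell_id"].duplicated().any():
                raise ValueError(f"duplicate cell_id within condition {cond!r}")

    @classmethod
    def from_counts(
        cls,
        counts: Iterable[int],
        condition: str = "cond",
        provenance: dict | None = None,
        cell_prefix: str = "cell",
    ) -> "CountData":
        counts = np.asarray(list(counts), dtype=np.int64)
        frame = pd.DataFrame(
            {
                "cell_id": [f"{cell_prefix}_{i:06d}" for i in range(len(counts))],
                "condition": condition,
                "count": counts,
            }
        )
        return cls(frame=frame, provenance=provenance or {})

    @classmethod
    def concat(cls, parts: Iterable["CountData"]) -> "CountData":
        parts = list(parts)
        frame = pd.concat([p.frame for p in parts], ignore_index=True)
        provenance = {"parts": [p.provenance for p in parts]}
        return cls(frame=frame, provenance=provenance)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    @property
    def n_cells(self) -> int:
        return len(self.frame)

    def counts(self, condition: str | None = None) -> np.ndarray:
        """Count vector for one condition (or all cells if None)."""
        if condition is None:
            return self.frame["count"].to_numpy()
        sel = self.frame.loc[self.frame["condition"] == condition, "count"]
        if sel.empty and condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return sel.to_numpy()

    def subset(self, mask: np.ndarray, note: str | None = None) -> "CountData":
        prov = dict(self.provenance)
        if note:
            prov["notes"] = list(prov.get("notes", [])) + [note]
        return CountData(frame=self.frame.loc[mask].reset_index(drop=True), provenance=prov)
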