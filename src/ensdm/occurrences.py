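"""Species point records with presence / pseudo-absence labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OccurrenceSet", "PRESENCE", "PSEUDO_ABSENCE"]

PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"
_LABELS = {PRESENCE, PSEUDO_ABSENCE}
COLUMNS = ["species", "x", "y", "label", "source"]


@dataclass
class OccurrenceSet:
    """Point records for one or more species.

    ``records`` is a DataFrame with columns species, x, y, label
    ("presence" or "pseudo_absence") and source (free-text provenance tag).
    Coordinates are continuous map coordinates, not cell indices.
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        if "label" not in df.columns:
            df["label"] = PRESENCE
        if "source" not in df.columns:
            df["source"] = ""
        missing = [c for c in ("species", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence records missing required columns: {missing}")
        bad = set(df["label"]) - _LABELS
        if bad:
            raise ValueError(f"invalid occurrence labels: {sorted(bad)}")
        if len(df) and not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError("occurrence coordinates must be finite")
        if len(df) and (df["species"].astype(str) == "").any():
            raise ValueError("species names must be non-empty")
        self.records = df.reset_index(drop=True)[COLUMNS]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_presence(self) -> int:
        return int((self.records["label"] == PRESENCE).sum())

    @property
    def n_pseudo_absence(self) -> int:
        return int((self.records["label"] == PSEUDO_ABSENCE).sum())

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        if not len(self.records):
            return (np.nan, np.nan, np.nan, np.nan)
        x = self.records["x"]
        y = self.records["y"]
        return (float(x.min()), float(y.min()), float(x.max()), float(y.max()))

    def presences(self) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["label"] == PRESENCE])

    def for_species(self, species: str) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["species"] == species])

    @property
    def species_names(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(pd.concat([self.records, other.records], ignore_index=True))
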