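"""Core in-memory containers shared across the pipeline.

Everything is a thin wrapper around pandas objects so that standard
DataFrame operations remain available; wrappers only enforce the invariants
that the pipeline depends on (unique peak ids, non-negative intensities,
metadata alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_META_COLUMNS = (
    "species",
    "tissue",
    "individual_id",
    "sex",
    "age",
    "rin",
    "condition",
    "postmortem_delay",
    "is_pooled",
)


@dataclass
class PeakTable:
    """Peaks x samples intensity matrix plus per-peak metadata.

    ``intensities``: DataFrame, index = peak ids, columns = sample ids,
    values in arbitrary units (AU, >= 0; 0 means "not detected").
    ``peak_meta``: DataFrame indexed like ``intensities`` with columns
    ``mz`` (Da, LC datasets), ``mass`` (nominal mass, GC), ``rt`` (minutes)
    and ``dataset`` in {posLC, negLC, GC}.
    ``log_scale``: True once values have been log2 transformed (zeros then
    stored as NaN).
    """

    intensities: pd.DataFrame
    peak_meta: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.intensities.index.is_unique:
            raise ValueError("peak ids must be unique")
        if not self.log_scale:
            vals = self.intensities.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("intensities must be non-negative")
        if not self.peak_meta.index.equals(self.intensities.index):
            self.peak_meta = self.peak_meta.reindex(self.intensities.index)

    @property
    def peak_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_peaks(self) -> int:
        return len(self.intensities.index)

    def subset_peaks(self, peak_ids) -> "PeakTable":
        return PeakTable(
            self.intensities.loc[peak_ids],
            self.peak_meta.loc[peak_ids],
            log_scale=self.log_scale,
        )

    def subset_samples(self, sample_ids) -> "PeakTable":
        return PeakTable(
            self.intensities[list(sample_ids)],
            self.peak_meta,
            log_scale=self.log_scale,
        )


def check_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame (index = sample ids)."""
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    if not meta.index.is_unique:
        raise ValueError("sample ids must be unique")
    pooled = meta["is_pooled"].astype(bool)
    if meta.loc[pooled, "individual_id"].notna().any():
        raise ValueError("pooled samples must not carry an individual_id")
    nonstd = meta["condition"] != "standard"
    if (meta.loc[nonstd & ~pooled, "species"] != "macaque").any():
        raise ValueError("non-standard conditions are defined for macaques only")
    return meta


@dataclass
class PathwayDB:
    """Pathway -> metabolite/enzyme sets plus direct enzyme-metabolite links."""

    metabolites: dict[str, set[str]] = field(default_factory=dict)
    enzymes: dict[str, set[str]] = field(default_factory=dict)
    links: set[tuple[str, str]] = field(default_factory=set)  # (enzyme, metabolite)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, mets in self.metabolites.items():
            if not mets:
                raise ValueError(f"pathway {pid!r} has no metabolites")

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.metabolites)

    def metabolite_universe(self) -> set[str]:
        out: set[str] = set()
        for mets in self.metabolites.values():
            out |= mets
        return out

    def enzyme_universe(self) -> set[str]:
        out: set[str] = set()
        for enz in self.enzymes.values():
            out |= enz
        return out

    def linked_enzymes(self, metabolite: str) -> set[str]:
        return {e for e, m in self.links if m == metabolite}

    def linked_metabolites(self, enzyme: str) -> set[str]:
        return {m for e, m in self.links if e == enzyme}
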