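"""Gene-panel definitions and the core expression/Ct containers.

The panel models a targeted qPCR expression panel: ~90 bladder-cancer
target genes plus two housekeeping (reference) genes used for delta-Ct
normalization.  Targets may carry pathway tags (development/EMT,
FGFR/RTK/MAPK/PI3K, TP53/genome-stability/cell-cycle); tags are inert
metadata and never influence computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("blpanel")

#: allowed scale flags for an ExpressionMatrix
SCALES = ("log2", "relative", "ct", "zscore")

#: subtype label vocabulary
BASAL = "basal"
LUMINAL = "luminal"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered target and housekeeping gene symbols with optional pathway tags."""

    target_genes: tuple[str, ...]
    housekeeping_genes: tuple[str, ...]
    pathway_tags: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        targets = list(self.target_genes)
        hk = list(self.housekeeping_genes)
        object.__setattr__(self, "target_genes", tuple(targets))
        object.__setattr__(self, "housekeeping_genes", tuple(hk))
        if len(set(targets)) != len(targets):
            dup = _first_duplicate(targets)
            raise ValueError(f"duplicate target gene symbol: {dup!r}")
        if len(set(hk)) != len(hk):
            dup = _first_duplicate(hk)
            raise ValueError(f"duplicate housekeeping gene symbol: {dup!r}")
        overlap = set(targets) & set(hk)
        if overlap:
            raise ValueError(
                f"genes listed as both target and housekeeping: {sorted(overlap)}"
            )
        stray = set(self.pathway_tags) - set(targets)
        if stray:
            raise ValueError(f"pathway tags for non-target genes: {sorted(stray)}")

    @property
    def all_genes(self) -> tuple[str, ...]:
        """Targets followed by housekeeping genes, in panel order."""
        return self.target_genes + self.housekeeping_genes

    @property
    def n_targets(self) -> int:
        return len(self.target_genes)


def _first_duplicate(items) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an explicit scale flag.

    ``data`` is a float DataFrame (rows = genes, columns = samples);
    NaN encodes a missing measurement.  ``scale`` is one of
    ``log2 | relative | ct | zscore`` and is set exactly once.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale flag {self.scale!r}; expected one of {SCALES}")
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene symbol: {dup!r}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        self.data = self.data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing(self) -> pd.DataFrame:
        return self.data.isna()

    def copy_with(self, values: np.ndarray | pd.DataFrame, scale: str) -> "ExpressionMatrix":
        df = pd.DataFrame(np.asarray(values, dtype=float),
                          index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, scale)


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold records.

    One row per (sample, assay, replicate); ``ct`` is NaN where the
    reaction failed to produce signal above background (``failed`` True).
    """

    records: pd.DataFrame  # columns: sample, assay, replicate, ct, failed

    COLUMNS = ("sample", "assay", "replicate", "ct", "failed")

    def __post_init__(self) -> None:
        df = self.records
        missing_cols = set(self.COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"CtTable records missing columns: {sorted(missing_cols)}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if len(df):
            rep = df["replicate"].to_numpy()
            if (rep < 1).any():
                bad = int(rep[rep < 1][0])
                raise ValueError(f"replicate index must be >= 1, got {bad}")
            ct = df["ct"].to_numpy(dtype=float)
            ok = ~df["failed"].to_numpy(dtype=bool)
            if np.any(ok & ~np.isfinite(ct)):
                raise ValueError("non-failed Ct values must be finite")
            if np.any(ok & (ct <= 0)):
                raise ValueError("Ct values must be > 0")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.records["sample"]))

    @property
    def assays(self) -> list[str]:
        return list(pd.unique(self.records["assay"]))


def as_labels(labels, samples=None) -> pd.Series:
    """Coerce a mapping / Series of subtype labels to a canonical Series.

    Values must be in {basal, luminal, unlabeled}.  If ``samples`` is given,
    label keys must be a subset of it and missing samples default to
    ``unlabeled``.
    """
    s = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels,
                  dtype=object)
    bad = set(s.unique()) - {BASAL, LUMINAL, UNLABELED}
    if bad:
        raise ValueError(f"unknown subtype labels: {sorted(bad)}")
    if samples is not None:
        extra = set(s.index) - set(samples)
        if extra:
            raise ValueError(f"labels for unknown samples: {sorted(extra)[:5]}")
        s = s.reindex(list(samples), fill_value=UNLABELED)
    return s
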