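"""Basal/luminal reference profiles and the B/L similarity score.

A sample's B/L score is half the difference between its Pearson
correlation with the basal reference profile and its correlation with the
luminal reference profile:

    score = (r_basal - r_luminal) / 2

The score lies in [-1, +1]; positive scores call the sample basal-like,
negative scores luminal-like, an exact zero is indeterminate.  Reference
profiles are per-gene mean standardized (z-scored) expression over the
labeled basal and luminal samples of a reference cohort.  Correlations are
pairwise-complete over jointly observed genes, so panel genes absent from
a dataset simply drop out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .normalize import standardize_genes
from .panel import BASAL, ExpressionMatrix, LUMINAL, as_labels

logger = logging.getLogger("blpanel")

BASAL_LIKE = "basal-like"
LUMINAL_LIKE = "luminal-like"
INDETERMINATE = "indeterminate"

#: minimum jointly observed genes for a correlation to be reported
MIN_OVERLAP = 3


@dataclass
class ReferenceProfiles:
    """Gene-aligned mean z-score vectors for the basal and luminal groups."""

    genes: list[str]
    basal_profile: pd.Series
    luminal_profile: pd.Series
    provenance: dict

    def __post_init__(self) -> None:
        self.basal_profile = self.basal_profile.reindex(self.genes)
        self.luminal_profile = self.luminal_profile.reindex(self.genes)

    def to_yaml(self, path) -> None:
        obj = {
            "genes": list(self.genes),
            "basal_profile": [None if np.isnan(v) else float(v) for v in self.basal_profile],
            "luminal_profile": [None if np.isnan(v) else float(v) for v in self.luminal_profile],
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(obj, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReferenceProfiles":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        genes = list(obj["genes"])
        to_series = lambda v: pd.Series(
            [np.nan if x is None else float(x) for x in v], index=genes
        )
        return cls(
            genes=genes,
            basal_profile=to_series(obj["basal_profile"]),
            luminal_profile=to_series(obj["luminal_profile"]),
            provenance=obj.get("provenance", {}),
        )


def derive_reference_profiles(
    matrix: ExpressionMatrix, labels, source: str = "reference-cohort"
) -> ReferenceProfiles:
    """Mean standardized expression per gene for each labeled group.

    Genes are z-scored across all samples of the reference cohort
    (unlabeled samples participate in the standardization, only labeled
    ones in the group means), then averaged gene-wise within the basal and
    the luminal group.  Genes unobserved in a group get a missing entry.
    """
    lab = as_labels(labels, matrix.samples)
    groups = {g: lab.index[lab == g] for g in (BASAL, LUMINAL)}
    for g, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"no samples labeled {g!r}")
    z = standardize_genes(matrix).data
    basal = z[list(groups[BASAL])].mean(axis=1, skipna=True)
    luminal = z[list(groups[LUMINAL])].mean(axis=1, skipna=True)
    return ReferenceProfiles(
        genes=matrix.genes,
        basal_profile=basal,
        luminal_profile=luminal,
        provenance={
            "source": source,
            "n_basal": int(len(groups[BASAL])),
            "n_luminal": int(len(groups[LUMINAL])),
        },
    )


def pearson_correlation(x, y) -> float:
    """Pairwise-complete Pearson correlation of two gene-aligned vectors.

    Returns NaN (with a warning) when fewer than MIN_OVERLAP genes are
    jointly observed, or when either vector has zero variance over the
    overlap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be gene-aligned (equal length)")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < MIN_OVERLAP:
        logger.warning(
            "only %d jointly observed genes (< %d); correlation undefined",
            int(ok.sum()), MIN_OVERLAP,
        )
        return float("nan")
    xs, ys = x[ok], y[ok]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def bl_similarity_score(sample_profile, refs: ReferenceProfiles) -> dict:
    """B/L score of one standardized sample vector against the references.

    Returns a dict with keys r_basal, r_luminal, score, call.
    """
    v = np.asarray(sample_profile, dtype=float)
    if v.shape[0] != len(refs.genes):
        raise ValueError("sample vector not gene-aligned with reference profiles")
    r_b = pearson_correlation(v, refs.basal_profile.to_numpy())
    r_l = pearson_correlation(v, refs.luminal_profile.to_numpy())
    if np.isnan(r_b) or np.isnan(r_l):
        return {"r_basal": r_b, "r_luminal": r_l, "score": float("nan"),
                "call": INDETERMINATE}
    score = (r_b - r_l) / 2.0
    if score > 0:
        call = BASAL_LIKE
    elif score < 0:
        call = LUMINAL_LIKE
    else:
        call = INDETERMINATE
    return {"r_basal": r_b, "r_luminal": r_l, "score": score, "call": call}


def score_cohort(matrix: ExpressionMatrix, refs: ReferenceProfiles) -> pd.DataFrame:
    """Score every sample of a cohort against the reference profiles.

    The cohort is z-scored per gene internally (cross-platform transfer
    relies on Pearson's scale invariance), aligned to the reference gene
    order, and scored sample by sample.  Returns a DataFrame indexed by
    sample with columns r_basal, r_luminal, score, call, in input order.
    """
    if matrix.scale == "relative":
        matrix = matrix.copy_with(np.log2(matrix.values), "log2")
    z = standardize_genes(matrix).data.reindex(refs.genes)
    rows = {s: bl_similarity_score(z[s].to_numpy(), refs) for s in z.columns}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out
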