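"""Technical validation of panel assays: failures, replicate CV, concordance.

Degraded FFPE template makes qPCR reactions fail outright (no signal above
background); per-assay failure accounting and replicate coefficients of
variation identify assays that should be dropped before analysis (the
canonical example being an assay failing ~96% of reactions).  Run-to-run
concordance (squared Pearson R of paired measurements) quantifies
chip-to-chip reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CtTable, ExpressionMatrix, PanelDefinition

logger = logging.getLogger("blpanel")

PASS = "pass"
HIGH_FAILURE = "high-failure"
HIGH_CV = "high-cv"
DROP = "drop"

#: default thresholds: acceptable assays fail <15% of reactions with CV <5%
MAX_FAILURE_RATE = 0.15
MAX_CV = 0.05


@dataclass
class QCReport:
    """Per-assay QC metrics; flags filled in by flag_assays."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # index assay; columns: attempts, failures, failure_rate, success_rate,
    # mean_cv, flag


def failure_summary(ct: CtTable, panel: PanelDefinition) -> QCReport:
    """Count attempted and failed reactions per assay.

    Attempts are all replicate records for the assay; the failure rate is
    failures/attempts.  Panel assays absent from the table get zero
    attempts and an undefined (missing) rate, with a warning.
    """
    rec = ct.records
    attempts = rec.groupby("assay").size()
    failures = rec.groupby("assay")["failed"].sum()
    assays = list(panel.all_genes)
    out = pd.DataFrame(index=assays)
    out["attempts"] = attempts.reindex(assays).fillna(0).astype(int)
    out["failures"] = failures.reindex(assays).fillna(0).astype(int)
    with np.errstate(invalid="ignore"):
        out["failure_rate"] = np.where(
            out["attempts"] > 0, out["failures"] / out["attempts"], np.nan
        )
    out["success_rate"] = 1.0 - out["failure_rate"]
    absent = out.index[out["attempts"] == 0]
    for a in absent:
        logger.warning("assay %r absent from Ct table; failure rate undefined", a)
    out["mean_cv"] = np.nan
    out["flag"] = PASS
    return QCReport(out)


def replicate_cv(
    ct: CtTable, base: float = 2.0, on: str = "expression"
) -> tuple[pd.DataFrame, pd.Series]:
    """Coefficient of variation over replicates per (sample, assay).

    CV = sample SD / mean of the replicate measurements, computed on the
    linear relative-expression scale ``base**(-Ct)`` by default
    (``on="ct"`` computes it on raw Ct values instead).  Cells with fewer
    than 2 non-failed replicates are missing; a zero mean yields a missing
    CV with a warning.  Returns (per-cell CV table, per-assay mean CV).
    """
    rec = ct.records
    ok = rec.loc[~rec["failed"]].copy()
    if on == "expression":
        ok["value"] = np.power(float(base), -ok["ct"])
    elif on == "ct":
        ok["value"] = ok["ct"]
    else:
        raise ValueError(f"unknown CV scale {on!r}")
    grouped = ok.groupby(["sample", "assay"])["value"]
    n = grouped.size()
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    cv = sd / mean
    cv[n < 2] = np.nan
    zero_mean = (mean == 0) & (n >= 2)
    if zero_mean.any():
        logger.warning("%d replicate groups have zero mean; CV undefined",
                       int(zero_mean.sum()))
        cv[zero_mean] = np.nan
    cell = cv.unstack("assay")
    per_assay = cell.mean(axis=0, skipna=True)
    return cell, per_assay


def run_concordance(
    run_a: ExpressionMatrix, run_b: ExpressionMatrix
) -> tuple[pd.Series, float]:
    """Squared Pearson correlation of paired measurements between two runs.

    Per gene across shared samples, plus a pooled overall R^2; genes with
    fewer than 3 shared observed pairs are missing.
    """
    genes = [g for g in run_a.genes if g in set(run_b.genes)]
    samples = [s for s in run_a.samples if s in set(run_b.samples)]
    if not genes or not samples:
        raise ValueError("runs share no genes or no samples")
    a = run_a.data.loc[genes, samples].to_numpy()
    b = run_b.data.loc[genes, samples].to_numpy()
    per_gene = {}
    for i, g in enumerate(genes):
        ok = np.isfinite(a[i]) & np.isfinite(b[i])
        if ok.sum() < 3:
            per_gene[g] = np.nan
            continue
        r = np.corrcoef(a[i, ok], b[i, ok])[0, 1]
        per_gene[g] = r * r
    ok = np.isfinite(a) & np.isfinite(b)
    overall = float(np.corrcoef(a[ok], b[ok])[0, 1] ** 2) if ok.sum() >= 3 else np.nan
    return pd.Series(per_gene), overall


def flag_assays(
    report: QCReport,
    max_failure_rate: float = MAX_FAILURE_RATE,
    max_cv: float = MAX_CV,
    drop_on: str = "both",
) -> QCReport:
    """Flag assays exceeding failure-rate or CV thresholds.

    Strict inequality: an assay exactly at a threshold passes.  ``drop_on``
    selects whether both limits (default) or either alone must be exceeded
    for the drop flag; singly exceeding assays are otherwise flagged
    high-failure or high-cv.  The default mirrors common panel-QC practice:
    an assay that both fails often and is noisy is removed, while an assay
    exceeding a single limit is flagged for review.
    """
    if not 0 < max_failure_rate <= 1:
        raise ValueError("max_failure_rate must be in (0, 1]")
    if max_cv <= 0:
        raise ValueError("max_cv must be > 0")
    if drop_on not in ("either", "both"):
        raise ValueError("drop_on must be 'either' or 'both'")
    t = report.table.copy()
    hf = t["failure_rate"] > max_failure_rate
    hc = t["mean_cv"] > max_cv
    drop = (hf | hc) if drop_on == "either" else (hf & hc)
    flags = np.select(
        [drop.to_numpy(), hf.to_numpy(), hc.to_numpy()],
        [DROP, HIGH_FAILURE, HIGH_CV],
        default=PASS,
    )
    t["flag"] = flags
    return QCReport(t)
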