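"""Expression preprocessing: median polish, delta-Ct, centering, z-scoring.

Median polish is Tukey's iterative row/column median sweep, decomposing a
matrix into overall + row + column effects + residuals; the "normalized"
matrix removes column (sample) effects, i.e. overall + row effects +
residuals.  Delta-Ct converts replicate qPCR Ct values to relative
expression against the geometric mean of the housekeeping-gene Cts of the
same sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CtTable, ExpressionMatrix, PanelDefinition

logger = logging.getLogger("blpanel")


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    iterations: int
    converged: bool

    def reconstruct(self) -> pd.DataFrame:
        """overall + row + column + residual; equals the input where observed."""
        return (
            self.residuals
            + self.overall
            + np.add.outer(self.row_effects.to_numpy(), self.col_effects.to_numpy())
        )

    def normalized(self) -> pd.DataFrame:
        """Input with column (sample) effects removed."""
        return self.residuals.add(self.row_effects, axis=0) + self.overall


def median_polish(
    matrix: ExpressionMatrix | pd.DataFrame,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> MedianPolishResult:
    """Tukey median polish with missing cells skipped, never imputed.

    Sweeps row then column medians until the largest absolute row/column
    median of the residuals is <= ``tol``.  All-missing rows or columns are
    rejected by name.
    """
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("median polish needs at least 2 rows and 2 columns")
    z = df.to_numpy(dtype=float).copy()
    obs = np.isfinite(z)
    if not obs.any(axis=1).all():
        bad = df.index[~obs.any(axis=1)][0]
        raise ValueError(f"all-missing row: {bad!r}")
    if not obs.any(axis=0).all():
        bad = df.columns[~obs.any(axis=0)][0]
        raise ValueError(f"all-missing column: {bad!r}")

    overall = 0.0
    row_eff = np.zeros(df.shape[0])
    col_eff = np.zeros(df.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rmed = np.nanmedian(z, axis=1)
        z -= rmed[:, None]
        row_eff += rmed
        shift = np.median(col_eff)
        col_eff -= shift
        overall += shift

        cmed = np.nanmedian(z, axis=0)
        z -= cmed[None, :]
        col_eff += cmed
        shift = np.median(row_eff)
        row_eff -= shift
        overall += shift

        resid_r = np.nanmedian(z, axis=1)
        resid_c = np.nanmedian(z, axis=0)
        if max(np.abs(resid_r).max(), np.abs(resid_c).max()) <= tol:
            converged = True
            break
    if not converged:
        logger.warning("median polish did not converge in %d iterations", max_iter)
    residuals = pd.DataFrame(z, index=df.index, columns=df.columns)
    return MedianPolishResult(
        overall=float(overall),
        row_effects=pd.Series(row_eff, index=df.index),
        col_effects=pd.Series(col_eff, index=df.columns),
        residuals=residuals,
        iterations=it,
        converged=converged,
    )


def median_polish_normalize(matrix: ExpressionMatrix, **kw) -> ExpressionMatrix:
    """Convenience wrapper: matrix with column effects removed, same scale."""
    res = median_polish(matrix, **kw)
    return ExpressionMatrix(res.normalized(), matrix.scale)


@dataclass
class DeltaCtResult:
    """Per (gene, sample) delta-Ct bookkeeping plus the expression matrix."""

    target_mean_ct: pd.DataFrame  # gene x sample mean Ct over non-failed replicates
    reference_ct: pd.Series  # per-sample geometric mean of housekeeping mean Cts
    delta_ct: pd.DataFrame  # target_mean_ct - reference_ct
    expression: ExpressionMatrix  # relative scale, base**(-delta_ct)


def delta_ct_expression(
    ct: CtTable, panel: PanelDefinition, base: float = 2.0
) -> DeltaCtResult:
    """Relative expression from replicate Cts by the delta-Ct method.

    Per sample: ``dCt_g = mean(replicate Cts of g) - geometric mean of the
    per-housekeeping-gene mean Cts``; relative expression ``base**(-dCt)``.
    Failed replicates are excluded from means; a gene whose replicates all
    failed is missing.  A sample with any housekeeping gene fully failed
    yields all-missing values (no reference aggregate exists).
    """
    rec = ct.records
    ok = rec.loc[~rec["failed"]]
    mean_ct = (
        ok.groupby(["assay", "sample"], sort=False)["ct"].mean().unstack("sample")
    )
    samples = list(pd.unique(rec["sample"]))
    genes = list(panel.all_genes)
    mean_ct = mean_ct.reindex(index=genes, columns=samples)

    hk = list(panel.housekeeping_genes)
    hk_means = mean_ct.loc[hk]
    # geometric mean; NaN (skipna=False) if any housekeeping gene is missing
    ref = np.exp(np.log(hk_means).mean(axis=0, skipna=False))
    dead = ref.index[ref.isna()]
    for s in dead:
        logger.warning(
            "sample %r: housekeeping gene(s) fully failed; all values set missing", s
        )

    targets = list(panel.target_genes)
    delta = mean_ct.loc[targets].sub(ref, axis=1)
    rel = np.power(float(base), -delta)
    return DeltaCtResult(
        target_mean_ct=mean_ct,
        reference_ct=ref,
        delta_ct=delta,
        expression=ExpressionMatrix(rel, "relative"),
    )


def median_center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median (missing ignored); idempotent."""
    df = matrix.data
    with np.errstate(all="ignore"):
        med = np.nanmedian(df.to_numpy(), axis=1)
    med = np.where(np.isnan(med), 0.0, med)  # all-missing rows pass through
    return matrix.copy_with(df.to_numpy() - med[:, None], matrix.scale)


def standardize_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score: mean 0, sample SD 1 (n-1 denominator), missing ignored.

    Zero-variance rows become all zeros with a warning.
    """
    x = matrix.data.to_numpy(dtype=float).copy()
    with np.errstate(all="ignore"):
        mean = np.nanmean(x, axis=1)
        sd = np.nanstd(x, axis=1, ddof=1)
    mean = np.where(np.isnan(mean), 0.0, mean)
    degenerate = np.isnan(sd) | (sd == 0.0)
    if (degenerate & ~np.all(np.isnan(x), axis=1)).any():
        flagged = list(matrix.data.index[degenerate & ~np.all(np.isnan(x), axis=1)])
        logger.warning("zero-variance gene rows set to 0: %s", flagged[:5])
    sd = np.where(degenerate, 1.0, sd)
    z = (x - mean[:, None]) / sd[:, None]
    # degenerate rows: zero where observed, missing stays missing
    for i in np.where(degenerate)[0]:
        z[i, np.isfinite(x[i])] = 0.0
    return matrix.copy_with(z, "zscore")
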