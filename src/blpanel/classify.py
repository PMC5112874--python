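"""Welch-t gene ranking, diagonal LDA, and cross-validated misclassification.

The classifier is diagonal linear discriminant analysis (DLDA): a
Gaussian classifier with class-specific per-gene means and a shared
diagonal covariance (pooled per-gene variance), equal priors.  Gene
selection inside cross-validation ranks genes by the absolute Welch
t-statistic computed on the training folds only, so the held-out fold
never influences which genes enter the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import BASAL, ExpressionMatrix, LUMINAL, UNLABELED, as_labels

logger = logging.getLogger("blpanel")

#: genes with pooled variance below this are dropped from DLDA models
VARIANCE_FLOOR = 1e-12


@dataclass
class WelchResult:
    """Per-gene Welch two-sample t statistics, basal minus luminal.

    Positive t means the gene is more highly expressed in basal samples.
    """

    table: pd.DataFrame  # index gene; columns t, p, df, mean_basal, mean_luminal,
    #                      var_basal, var_luminal, n_basal, n_luminal

    def ranked_genes(self) -> list[str]:
        """Genes ordered by decreasing |t| (missing t last), ties by panel order."""
        t = self.table["t"]
        order = np.argsort(-np.abs(t.fillna(-np.inf).to_numpy()), kind="stable")
        return [self.table.index[i] for i in order]


def welch_t(matrix: ExpressionMatrix, labels) -> WelchResult:
    """Welch's unequal-variance t per gene between basal and luminal groups.

    t = (mean_b - mean_l) / sqrt(var_b/n_b + var_l/n_l), two-sided p from
    the t distribution with Welch-Satterthwaite degrees of freedom.  Genes
    with fewer than 2 observed values in either group get missing results.
    """
    lab = as_labels(labels, matrix.samples)
    idx_b = [s for s in matrix.samples if lab[s] == BASAL]
    idx_l = [s for s in matrix.samples if lab[s] == LUMINAL]
    if not idx_b or not idx_l:
        raise ValueError("both a basal and a luminal group are required")
    xb = matrix.data[idx_b].to_numpy()
    xl = matrix.data[idx_l].to_numpy()

    def moments(x):
        n = np.isfinite(x).sum(axis=1)
        with np.errstate(all="ignore"):
            m = np.nanmean(x, axis=1)
            v = np.nanvar(x, axis=1, ddof=1)
        return n, m, v

    nb, mb, vb = moments(xb)
    nl, ml, vl = moments(xl)
    with np.errstate(all="ignore"):
        se2 = vb / nb + vl / nl
        t = (mb - ml) / np.sqrt(se2)
        df = se2**2 / ((vb / nb) ** 2 / (nb - 1) + (vl / nl) ** 2 / (nl - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = (nb < 2) | (nl < 2)
    for arr in (t, p, df):
        arr[bad] = np.nan
    table = pd.DataFrame(
        {
            "t": t, "p": p, "df": df,
            "mean_basal": mb, "mean_luminal": ml,
            "var_basal": vb, "var_luminal": vl,
            "n_basal": nb, "n_luminal": nl,
        },
        index=matrix.data.index,
    )
    return WelchResult(table)


@dataclass
class DLDAModel:
    classes: list[str]
    genes: list[str]
    means: pd.DataFrame  # gene x class
    pooled_var: pd.Series  # per gene, > 0


def dlda_fit(matrix: ExpressionMatrix, labels) -> DLDAModel:
    """Fit DLDA: class means per gene and (n_c - 1)-weighted pooled variance.

    Genes whose pooled variance falls below the variance floor are dropped
    with a warning; classes with fewer than 2 samples are rejected.
    """
    lab = as_labels(labels, matrix.samples)
    classes = sorted(c for c in lab.unique() if c != UNLABELED)
    if len(classes) < 2:
        raise ValueError("need at least two labeled classes")
    members = {c: [s for s in matrix.samples if lab[s] == c] for c in classes}
    for c, m in members.items():
        if len(m) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    means = {}
    wvar = np.zeros(matrix.data.shape[0])
    wsum = 0
    for c, m in members.items():
        x = matrix.data[m].to_numpy()
        means[c] = np.nanmean(x, axis=1)
        wvar += np.nanvar(x, axis=1, ddof=1) * (len(m) - 1)
        wsum += len(m) - 1
    pooled = wvar / wsum
    means_df = pd.DataFrame(means, index=matrix.data.index)
    keep = np.isfinite(pooled) & (pooled >= VARIANCE_FLOOR)
    if (~keep).any():
        dropped = list(matrix.data.index[~keep])
        logger.warning("dropping %d near-zero-variance genes from DLDA model: %s",
                       len(dropped), dropped[:5])
    genes = list(matrix.data.index[keep])
    return DLDAModel(
        classes=classes,
        genes=genes,
        means=means_df.loc[genes],
        pooled_var=pd.Series(pooled[keep], index=genes),
    )


def dlda_predict(model: DLDAModel, matrix: ExpressionMatrix) -> pd.Series:
    """Predict classes by the minimum diagonal Mahalanobis distance.

    For each sample the discriminant sums (x_g - mu_cg)^2 / var_g over the
    genes shared between model and matrix that are observed for that
    sample.  Ties go to the lexicographically first class.  Samples with no
    usable genes are returned unlabeled with a warning.
    """
    shared = [g for g in model.genes if g in set(matrix.genes)]
    if not shared:
        raise ValueError("no gene overlap between model and matrix")
    x = matrix.data.reindex(shared).to_numpy()  # genes x samples
    mu = model.means.loc[shared].to_numpy()  # genes x classes
    var = model.pooled_var.loc[shared].to_numpy()[:, None]
    preds = []
    for j, s in enumerate(matrix.samples):
        col = x[:, j][:, None]
        ok = np.isfinite(col[:, 0])
        if not ok.any():
            logger.warning("sample %r has no usable genes; left unlabeled", s)
            preds.append(UNLABELED)
            continue
        d = (((col - mu) ** 2) / var)[ok].sum(axis=0)
        preds.append(model.classes[int(np.argmin(d))])  # argmin: first (lexicographic) wins ties
    return pd.Series(preds, index=matrix.samples, dtype=object)


@dataclass
class CVResult:
    """Cross-validated misclassification with per-fold detail."""

    fold_rates: list[float]
    n_genes: int | None  # None = all genes
    seed: int
    fold_genes: list[list[str]] = field(default_factory=list)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.fold_rates))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_rates, ddof=1))

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(len(self.fold_rates))

    def to_dict(self) -> dict:
        return {
            "fold_rates": [float(r) for r in self.fold_rates],
            "mean_rate": self.mean_rate,
            "sd": self.sd,
            "se": self.se,
            "n_genes": self.n_genes,
            "seed": self.seed,
            "fold_genes": self.fold_genes,
        }


def stratified_folds(labels: pd.Series, folds: int, seed: int) -> list[list[str]]:
    """Random class-stratified partition of labeled samples into folds.

    Members are sorted by sample ID before the seeded shuffle, so the
    partition depends only on (labels, folds, seed), not on column order.
    """
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    for c in sorted(labels.unique()):
        members = sorted(s for s in labels.index if labels[s] == c)
        perm = rng.permutation(len(members))
        for pos, idx in enumerate(perm):
            assignments[members[idx]] = pos % folds
    return [
        [s for s in labels.index if assignments[s] == f] for f in range(folds)
    ]


def cross_validate(
    matrix: ExpressionMatrix,
    labels,
    folds: int = 5,
    n_genes: int | None = None,
    seed: int = 0,
) -> CVResult:
    """K-fold cross-validated DLDA misclassification with nested gene selection.

    Folds are class-stratified from ``seed``.  Within each fold, genes are
    ranked by |Welch t| on the training samples only and the top
    ``n_genes`` kept (all genes when None); a DLDA model is fit on the
    training folds and scored on the held-out fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    lab = as_labels(labels, matrix.samples)
    lab = lab[lab != UNLABELED]
    counts = lab.value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index[0]
        raise ValueError(f"class {small!r} has fewer samples than folds")
    parts = stratified_folds(lab, folds, seed)
    rates, fold_genes = [], []
    for f in range(folds):
        test = parts[f]
        train = [s for s in lab.index if s not in set(test)]
        train_m = ExpressionMatrix(matrix.data[train], matrix.scale)
        if n_genes is not None:
            ranked = welch_t(train_m, lab[train]).ranked_genes()
            keep = ranked[: n_genes]
            train_m = ExpressionMatrix(train_m.data.loc[keep], matrix.scale)
        else:
            keep = list(matrix.genes)
        model = dlda_fit(train_m, lab[train])
        test_m = ExpressionMatrix(matrix.data.loc[keep, test], matrix.scale)
        pred = dlda_predict(model, test_m)
        rates.append(float((pred != lab[test]).mean()))
        fold_genes.append(list(model.genes))
    return CVResult(fold_rates=rates, n_genes=n_genes, seed=seed, fold_genes=fold_genes)
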