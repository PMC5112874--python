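"""Reading and writing the exchange formats.

All tables are tab-delimited UTF-8 with '.' decimal separator and no
quoting.  Expression tables are genes x samples with gene symbols in the
first column; Ct tables are long format (sample, assay, replicate, ct);
labels are two columns (sample, label); panels are YAML/JSON with keys
``target_genes``, ``housekeeping_genes``, ``pathway_tags``.

Missing expression values are written as empty strings so that
read -> write -> read round-trips bit-identically for finite values.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import CtTable, ExpressionMatrix, PanelDefinition, as_labels

logger = logging.getLogger("blpanel")


def read_expression_table(path, scale: str) -> ExpressionMatrix:
    """Read a genes x samples TSV into an ExpressionMatrix with the given scale.

    Empty cells become missing (NaN).  Duplicate gene symbols and
    non-numeric cells are rejected with the offending symbol/coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene symbol in {path}: {dup!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        for i, cell in enumerate(raw):
            if cell == "":
                out.iloc[i, j] = np.nan
            else:
                try:
                    out.iloc[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell at gene {df.index[i]!r}, "
                        f"sample {col!r}: {cell!r}"
                    ) from None
    return ExpressionMatrix(out, scale)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write an ExpressionMatrix as TSV; missing values as empty cells."""
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_ct_table(path, failure_sentinel: str = "NA") -> CtTable:
    """Read a long-format Ct TSV (columns sample, assay, replicate, ct).

    Occurrences of ``failure_sentinel`` in the ct column are recorded as
    failed reactions.  Replicate indices < 1 and negative Cts are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "assay", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if df.empty:
        logger.warning("Ct table %s is empty", path)
        return CtTable(pd.DataFrame(columns=list(CtTable.COLUMNS)))
    failed = df["ct"].to_numpy() == failure_sentinel
    ct = np.where(failed, np.nan, np.where(df["ct"] == "", np.nan, df["ct"]))
    rec = pd.DataFrame(
        {
            "sample": df["sample"].astype(str),
            "assay": df["assay"].astype(str),
            "replicate": df["replicate"].astype(int),
            "ct": pd.to_numeric(pd.Series(ct), errors="raise"),
            "failed": failed,
        }
    )
    return CtTable(rec)


def write_ct_table(ct: CtTable, path, failure_sentinel: str = "NA") -> None:
    df = ct.records.copy()
    out = pd.DataFrame(
        {
            "sample": df["sample"],
            "assay": df["assay"],
            "replicate": df["replicate"],
            "ct": [
                failure_sentinel if f else "%.17g" % v
                for v, f in zip(df["ct"], df["failed"])
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.Series:
    """Read a two-column (sample, label) TSV into a label Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels file must have two columns: sample, label")
    return as_labels(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample": labels.index, "label": labels.values}).to_csv(
        path, sep="\t", index=False
    )


def read_panel(path) -> PanelDefinition:
    """Load a panel definition from YAML or JSON."""
    text = Path(path).read_text()
    try:
        obj = json.loads(text)
    except json.JSONDecodeError:
        obj = yaml.safe_load(text)
    tags = {
        g: frozenset(v) for g, v in (obj.get("pathway_tags") or {}).items()
    }
    return PanelDefinition(
        target_genes=tuple(obj["target_genes"]),
        housekeeping_genes=tuple(obj["housekeeping_genes"]),
        pathway_tags=tags,
    )


def write_panel(panel: PanelDefinition, path) -> None:
    obj = {
        "target_genes": list(panel.target_genes),
        "housekeeping_genes": list(panel.housekeeping_genes),
        "pathway_tags": {g: sorted(v) for g, v in panel.pathway_tags.items()},
    }
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def align_to_panel(
    matrix: ExpressionMatrix,
    panel: PanelDefinition,
    collapse: str = "max_var",
    probe_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Restrict and order matrix rows to the panel's genes.

    ``probe_map`` maps row identifiers (probes) to gene symbols; rows
    already keyed by gene symbol need no map.  Multiple rows per gene are
    collapsed: ``max_var`` keeps the highest-variance probe (default),
    ``mean`` averages probes.  Panel genes absent from the matrix are
    retained as all-missing rows so downstream pairwise-complete
    correlation can skip them.
    """
    if collapse not in ("max_var", "mean"):
        raise ValueError(f"unknown collapse policy {collapse!r}")
    df = matrix.data
    gene_of = (lambda r: probe_map.get(r, r)) if probe_map else (lambda r: r)
    groups: dict[str, list[str]] = {}
    for row in df.index:
        groups.setdefault(gene_of(row), []).append(row)

    order = list(panel.all_genes)
    found = [g for g in order if g in groups]
    if not found:
        raise ValueError("no panel genes found in expression matrix")
    out = pd.DataFrame(np.nan, index=order, columns=df.columns)
    for g in found:
        rows = groups[g]
        if len(rows) == 1:
            out.loc[g] = df.loc[rows[0]].to_numpy()
        elif collapse == "mean":
            out.loc[g] = df.loc[rows].mean(axis=0, skipna=True).to_numpy()
        else:
            variances = df.loc[rows].var(axis=1, ddof=1, skipna=True)
            best = variances.idxmax()
            out.loc[g] = df.loc[best].to_numpy()
    n_absent = len(order) - len(found)
    if n_absent:
        logger.info("%d panel genes absent from matrix, kept as all-missing", n_absent)
    return ExpressionMatrix(out, matrix.scale)
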