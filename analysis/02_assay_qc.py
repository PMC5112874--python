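#!/usr/bin/env python
"""Technical QC of the simulated qPCR run: per-assay failure counts,
replicate coefficients of variation, run-to-run concordance, and flags.

Expects the tables written by 01_simulate_cohort.py; writes
results/qc_per_assay.tsv and results/qc_summary.yaml.
"""

from pathlib import Path

import numpy as np
import yaml

import blpanel as bl

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    panel = bl.read_panel(COHORT / "panel.yaml")
    ct = bl.read_ct_table(COHORT / "study_ct.tsv")
    report = bl.failure_summary(ct, panel)
    _, per_assay_cv = bl.replicate_cv(ct)
    report.table["mean_cv"] = per_assay_cv.reindex(report.table.index)
    report = bl.flag_assays(report)

    run_a = bl.delta_ct_expression(ct, panel).expression
    run_b = bl.delta_ct_expression(
        bl.read_ct_table(COHORT / "study_ct_run2.tsv"), panel).expression
    log2 = lambda m: bl.ExpressionMatrix(np.log2(m.data), "log2")
    per_gene_r2, overall_r2 = bl.run_concordance(log2(run_a), log2(run_b))

    t = report.table.copy()
    t["r2_run_concordance"] = per_gene_r2.reindex(t.index)
    t.index.name = "assay"
    t.to_csv(ROOT / "qc_per_assay.tsv", sep="\t", float_format="%.6g")

    worst = t["failure_rate"].idxmax()
    flagged = t.index[t["flag"] != "pass"]
    summary = {
        "n_assays": int(len(t)),
        "worst_assay": {"name": str(worst),
                        "failures": int(t.loc[worst, "failures"]),
                        "attempts": int(t.loc[worst, "attempts"]),
                        "failure_rate": float(t.loc[worst, "failure_rate"])},
        "flagged": {str(a): str(t.loc[a, "flag"]) for a in flagged},
        "median_assay_cv": float(t["mean_cv"].median()),
        "overall_run_r2": float(overall_r2),
        "r2_range_informative_assays": [
            float(per_gene_r2[t["flag"] == "pass"].dropna().min()),
            float(per_gene_r2[t["flag"] == "pass"].dropna().max())],
    }
    (ROOT / "qc_summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))

    print(f"worst assay {worst}: {summary['worst_assay']['failures']}/"
          f"{summary['worst_assay']['attempts']} failures "
          f"({summary['worst_assay']['failure_rate']:.1%})")
    print(f"flagged assays: {summary['flagged'] or 'none'}")
    print(f"median replicate CV: {summary['median_assay_cv']:.3f}; "
          f"run-to-run R^2 (passing assays): "
          f"{summary['r2_range_informative_assays'][0]:.3f}-"
          f"{summary['r2_range_informative_assays'][1]:.3f}")


if __name__ == "__main__":
    main()
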