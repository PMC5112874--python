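#!/usr/bin/env python
"""Generate the study cohorts: a labeled reference cohort (18 basal / 12
luminal, emulating a public discovery set) and a 204-sample target cohort
(balanced basal/luminal with NMIBC/MIBC/MET stage mix), plus a triplicate
qPCR Ct encoding of the target cohort with one deliberately broken assay
(96% reaction failure) to exercise QC.

Writes expression/Ct/label/mutation/stage tables under scratch/cohort/.
"""

import sys
from pathlib import Path

import pandas as pd
import yaml

import blpanel as bl

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2016
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"

#: assay given a MYC-like failure probability; all others fail at 2%
BROKEN_ASSAY = "G090"


def encode_run(study: bl.SyntheticCohort, seed: int) -> bl.CtTable:
    probs = {g: 0.02 for g in study.expression.genes}
    probs[BROKEN_ASSAY] = 0.956
    clean = bl.encode_as_ct(study, replicates=3, failure_prob=probs,
                            rep_sd=0.05, seed=seed)
    noisy = bl.encode_as_ct(study, replicates=3, failure_prob=probs,
                            rep_sd=1.5, seed=seed + 10)
    rec = clean.records
    spliced = pd.concat([rec[rec["assay"] != BROKEN_ASSAY],
                         noisy.records[noisy.records["assay"] == BROKEN_ASSAY]],
                        ignore_index=True)
    return bl.CtTable(spliced)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ref_spec = bl.CohortSpec(n_basal=18, n_luminal=12, seed=SEED)
    reference = bl.generate_cohort(ref_spec)
    bl.write_expression_table(reference.expression, OUT / "reference_expression.tsv")
    bl.write_labels(reference.labels, OUT / "reference_labels.tsv")

    study_spec = bl.CohortSpec(n_basal=102, n_luminal=102, seed=SEED + 1)
    study = bl.generate_cohort(study_spec)
    bl.write_expression_table(study.expression, OUT / "study_expression.tsv")
    bl.write_labels(study.labels, OUT / "study_labels.tsv")
    mut = study.mutations.copy()
    mut.index.name = "sample"
    mut.to_csv(OUT / "study_mutations.tsv", sep="\t")
    pd.DataFrame({"sample": study.stages.index, "stage": study.stages.values}).to_csv(
        OUT / "study_stages.tsv", sep="\t", index=False)
    bl.write_panel(study.panel, OUT / "panel.yaml")

    # Replicate SD of 0.05 Ct keeps working assays in the sub-5% CV regime
    # the QC thresholds assume; the broken assay gets both a 96% failure
    # probability and much noisier replicates, so it trips both QC limits.
    ct = encode_run(study, seed=SEED + 2)
    bl.write_ct_table(ct, OUT / "study_ct.tsv")

    # second technical run of the same cohort for concordance analysis
    ct2 = encode_run(study, seed=SEED + 3)
    bl.write_ct_table(ct2, OUT / "study_ct_run2.tsv")

    (OUT / "truth.yaml").write_text(yaml.safe_dump({
        "seed": SEED,
        "reference": {"n_basal": 18, "n_luminal": 12},
        "study": {"n_basal": 102, "n_luminal": 102, "n_de": study_spec.n_de,
                  "effect": study_spec.effect, "noise_sd": study_spec.noise_sd},
        "broken_assay": BROKEN_ASSAY,
    }, sort_keys=False))

    print(f"reference cohort: {len(reference.samples)} samples "
          f"({ref_spec.n_basal} basal / {ref_spec.n_luminal} luminal)")
    print(f"study cohort: {len(study.samples)} samples; stages: "
          f"{study.stages.value_counts().to_dict()}")
    print(f"Ct records per run: {len(ct)}; broken assay: {BROKEN_ASSAY}")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
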