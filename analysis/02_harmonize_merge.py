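#!/usr/bin/env python
"""Harmonize the three non-reference cohorts to the reference and merge.

Each non-reference cohort's pooled log2 distribution is mapped by one global
linear transform onto the reference cohort's mean and standard deviation
(skewness and kurtosis are reported as diagnostics).  The merged study keeps
the gene intersection and concatenates samples.

Reads results/data/, writes results/merged/ plus a moments table.
"""

import json
from pathlib import Path

import pandas as pd

from gcna import CohortStudy, harmonize_to_reference, merge_cohorts
from gcna.harmonize import (
    pooled_moments,
    read_clinical_table,
    read_expression_table,
    write_clinical_table,
    write_expression_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "merged"
REFERENCE = "cohortD"  # identity-shift cohort, plays the reference standard

cohorts = sorted(p.stem.split("_", 1)[1] for p in DATA.glob("expression_*.tsv"))
studies = {}
for label in cohorts:
    expr = read_expression_table(DATA / f"expression_{label}.tsv", cohort=label)
    clin = read_clinical_table(DATA / f"clinical_{label}.tsv")
    studies[label] = CohortStudy(expr, clin, [label])

OUT.mkdir(parents=True, exist_ok=True)
reference = studies[REFERENCE]
aligned, rows, diags = [], [], {}
for label, study in studies.items():
    if label == REFERENCE:
        aligned.append(study)
        rows.append({"cohort": label, "stage": "reference", **pooled_moments(study.expression)})
        continue
    rows.append({"cohort": label, "stage": "before", **pooled_moments(study.expression)})
    m, diag = harmonize_to_reference(study.expression, reference.expression)
    aligned.append(CohortStudy(m, study.clinical.copy(), [label]))
    diags[label] = diag
    rows.append({"cohort": label, "stage": "after", **pooled_moments(m)})

merged = merge_cohorts(aligned)
write_expression_table(merged.expression, OUT / "expression_merged.tsv")
write_clinical_table(merged.clinical, OUT / "clinical_merged.tsv")
moments = pd.DataFrame(rows)
moments.to_csv(OUT / "cohort_moments.tsv", sep="\t", index=False, float_format="%.4f")
with open(OUT / "harmonization.json", "w") as fh:
    json.dump(diags, fh, indent=2, sort_keys=True)

print(moments.to_string(index=False))
n_missing = int(merged.clinical.recurrence_event.isna().sum())
print(
    f"merged: {merged.n_samples} samples ({merged.n_samples - n_missing} survival-analyzable, "
    f"{n_missing} missing recurrence), {len(merged.genes)} genes"
)
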