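#!/usr/bin/env python
"""Screen quantified features by dual-test FDR at q = 0.01.

Mann-Whitney U for real-valued features, Fisher exact for binary
ones, Benjamini-Yekutieli step-up control. Selection uses the primary
(80%) cohort only — the validation cohort never influences it.
Writes results/selection.csv.
"""

import pandas as pd

from opcirc import io
from opcirc.modeling import assign_plos_labels, build_feature_tables, split_cohort
from opcirc.selection import fdr_select

COHORT = "results/cohort"
SEED = 20240921


def main():
    records = io.read_cohort(COHORT)
    records, med = assign_plos_labels(records)
    print(f"PLOS label: LOS > {med:.0f} d (cohort median)")
    quant, manual, clinical, labels, kept = build_feature_tables(records)
    primary, _ = split_cohort(kept, 0.8, seed=SEED)
    tr = [r.patient_id for r in primary]
    res = fdr_select(quant.loc[tr], labels.loc[tr], q=0.01)
    res.to_csv("results/selection.csv")
    print(f"{len(res.selected)} / {quant.shape[1]} features pass FDR q=0.01")
    top = res.table.nsmallest(10, "pvalue")
    print("ten smallest p-values:")
    print(top[["pvalue", "test", "rejected"]].to_string())


if __name__ == "__main__":
    main()
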