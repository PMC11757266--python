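#!/usr/bin/env python
"""Quantify the intraoperative circulation series.

Preprocesses every series (gap imputation, MAP derivation), computes
the four manual circulation metrics and the seven machine-learned
feature families over the five channels, and writes
results/features_quantified.csv, results/features_manual.csv and the
column manifest.
"""

import pandas as pd

from opcirc import io
from opcirc.features import extract_all, feature_manifest
from opcirc.manual_metrics import manual_feature_row
from opcirc.preprocess import impute_gaps

COHORT = "results/cohort"


def main():
    records = io.read_cohort(COHORT)
    processed = [impute_gaps(r.series) for r in records]
    quant = extract_all(processed)
    quant.to_csv("results/features_quantified.csv", index_label="patient_id")
    manual = pd.DataFrame(
        [manual_feature_row(s) for s in processed],
        index=[s.patient_id for s in processed],
    )
    manual.to_csv("results/features_manual.csv", index_label="patient_id")
    feature_manifest().to_csv("results/feature_manifest.csv", index=False)
    fams = feature_manifest().groupby("family").size()
    print(f"quantified {quant.shape[1]} features x {quant.shape[0]} patients")
    print("features per family (x5 channels):")
    print(fams.to_string())


if __name__ == "__main__":
    main()
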