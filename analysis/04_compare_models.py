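#!/usr/bin/env python
"""Train and compare the four PLOS prediction models.

Model 1: random forest + quantified circulation features
Model 2: xgboost      + quantified circulation features
Model 3: random forest + manual circulation metrics
Model 4: xgboost      + manual circulation metrics

Each model also receives the same clinical covariates, is trained on
the primary (80%) cohort and evaluated on the held-out validation
cohort (AUROC with DeLong 95% CI, overall accuracy at 0.5). SHAP
rankings for the two xgboost models go to results/.
"""

import pandas as pd

from opcirc import io
from opcirc.modeling import compare_assessments, run_experiment

COHORT = "results/cohort"
SEED = 20240921


def main():
    records = io.read_cohort(COHORT)
    table = compare_assessments(records, seed=SEED)
    table.to_csv("results/model_comparison.csv", index=False)
    print(table.round(3).to_string(index=False))

    for fs in ("quantified", "manual"):
        bundle, rep = run_experiment(
            io.read_cohort(COHORT), fs, "gbt", seed=SEED, with_shap=True
        )
        top = rep.shap_ranking.head(20)
        top.to_csv(f"results/shap_top20_gbt_{fs}.csv", index=False)
        print(f"\ntop-5 features by mean |SHAP|, gbt + {fs}:")
        print(top.head(5).round(4).to_string(index=False))


if __name__ == "__main__":
    main()
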