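#!/usr/bin/env python
"""Replay one patient's surgery as a real-time prediction score.

Trains a realtime-ready xgboost model on quantified features, then
re-extracts features on every growing 5-minute prefix of one
patient's record and scores it, mirroring how the model would run in
the operating room. Writes results/trajectory_<patient>.csv and a
two-panel figure (vitals above, score below).
"""

import numpy as np
import pandas as pd

from opcirc import io
from opcirc.modeling import run_experiment
from opcirc.preprocess import impute_gaps
from opcirc.realtime import score_trajectory

COHORT = "results/cohort"
SEED = 20240921


def main():
    records = io.read_cohort(COHORT)
    bundle, rep = run_experiment(
        records, "quantified", "gbt", seed=SEED, realtime_ready=True
    )
    print(f"realtime bundle: validation AUROC {rep.auroc:.3f}, "
          f"training prevalence {bundle.train_prevalence:.3f}")

    rng = np.random.default_rng(SEED)
    patient = records[int(rng.integers(len(records)))]
    series = impute_gaps(patient.series)
    traj = score_trajectory(bundle, series, pd.Series(patient.covariate_row()))
    out = f"results/trajectory_{patient.patient_id}.csv"
    traj.to_frame().to_csv(out, index=False)
    print(f"patient {patient.patient_id}: {series.n} grid points, "
          f"LOS {patient.los_days:.0f} d, PLOS={patient.plos}")
    print(f"score range {traj.scores.min():.3f}-{traj.scores.max():.3f}, "
          f"final {traj.scores[-1]:.3f} -> {out}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
        for ch, label in [("sbp", "SBP"), ("dbp", "DBP"), ("map", "MAP"),
                          ("hr", "HR"), ("pulse", "pulse")]:
            ax1.plot(series.t, getattr(series, ch), label=label, lw=1)
        ax1.set_ylabel("mmHg / bpm")
        ax1.legend(ncol=5, fontsize=8)
        ax2.plot(traj.times, traj.scores, drawstyle="steps-post")
        ax2.scatter(traj.times[traj.fallback_mask],
                    traj.scores[traj.fallback_mask], s=12, c="grey",
                    label="prevalence fallback")
        ax2.set_xlabel("minutes since first reading")
        ax2.set_ylabel("PLOS prediction score")
        ax2.set_ylim(0, 1)
        ax2.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(f"results/trajectory_{patient.patient_id}.png", dpi=120)
        print("figure written alongside the CSV")
    except ImportError:
        print("matplotlib unavailable; skipped the figure")


if __name__ == "__main__":
    main()
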