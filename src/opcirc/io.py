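"""CSV/JSON persistence for cohorts, series and model artifacts.

Series travel as long-format CSV (patient_id, t_min, sbp, dbp, hr,
pulse; missing points as empty cells); covariates and the LOS outcome
as one CSV row per patient; ground truth and normalization parameters
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLINICAL_COVARIATES, RECORDED_CHANNELS, CirculationSeries, PatientRecord
from .preprocess import NormalizationParams

SERIES_COLUMNS = ["patient_id", "t_min", *RECORDED_CHANNELS]
COHORT_COLUMNS = ["patient_id", *CLINICAL_COVARIATES, "los_days"]


def series_to_frame(series_list: list[CirculationSeries]) -> pd.DataFrame:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "t_min": s.t,
                    **{ch: getattr(s, ch) for ch in RECORDED_CHANNELS},
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_series(df: pd.DataFrame, grid_minutes: float = 5.0) -> list[CirculationSeries]:
    out = []
    for pid, g in df.groupby("patient_id", sort=False):
        g = g.sort_values("t_min")
        out.append(
            CirculationSeries(
                patient_id=str(pid),
                t=g["t_min"].to_numpy(float),
                grid_minutes=grid_minutes,
                **{ch: g[ch].to_numpy(float) for ch in RECORDED_CHANNELS},
            )
        )
    return out


def write_cohort(records: list[PatientRecord], ground_truth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series_to_frame([r.series for r in records]).to_csv(
        outdir / "series.csv", index=False, na_rep=""
    )
    rows = [
        {"patient_id": r.patient_id, **r.covariate_row(), "los_days": r.los_days}
        for r in records
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(
        outdir / "cohort.csv", index=False
    )
    if ground_truth is not None:
        ground_truth.to_json(outdir / "ground_truth.json")


def read_cohort(outdir) -> list[PatientRecord]:
    outdir = Path(outdir)
    series = {
        s.patient_id: s for s in frame_to_series(pd.read_csv(outdir / "series.csv"))
    }
    cov = pd.read_csv(outdir / "cohort.csv")
    records = []
    for _, row in cov.iterrows():
        pid = str(row["patient_id"])
        records.append(
            PatientRecord(
                patient_id=pid,
                covariates={k: float(row[k]) for k in CLINICAL_COVARIATES},
                series=series[pid],
                los_days=float(row["los_days"]),
            )
        )
    return records


def write_norm_params(params: NormalizationParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)


def read_norm_params(path) -> NormalizationParams:
    with open(path) as fh:
        return NormalizationParams.from_dict(json.load(fh))
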