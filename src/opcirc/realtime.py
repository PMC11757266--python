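"""Real-time prediction-score trajectories.

Replays a patient's intraoperative record: at every 5-minute grid
point the manual metrics and quantified features are re-extracted on
the growing prefix, joined with the static clinical covariates,
normalized with the training-cohort parameters (no per-prefix refit:
a deployed scorer cannot refit online), and scored with the trained
bundle. Prefixes shorter than 5 grid points (25 min) carry too little
information and fall back to the training-cohort PLOS prevalence.

The final non-fallback score equals the static full-series prediction
exactly, and every score is causal: it depends only on data up to its
own grid time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CirculationSeries
from .features import series_feature_row
from .manual_metrics import MANUAL_FEATURES, manual_feature_row
from .modeling import ModelBundle, _indicator_columns
from .preprocess import apply_minmax

__all__ = ["ScoreTrajectory", "prefix_features", "score_trajectory", "MIN_PREFIX_POINTS"]

MIN_PREFIX_POINTS = 5  # 25 minutes of data before real scoring


@dataclass
class ScoreTrajectory:
    times: np.ndarray  # minutes, grid points
    scores: np.ndarray  # probability of PLOS
    fallback_mask: np.ndarray  # True where the prevalence fallback was used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_min": self.times,
                "score": self.scores,
                "fallback": self.fallback_mask.astype(int),
            }
        )


def prefix_features(series: CirculationSeries, t_cut: float) -> pd.Series:
    """Manual + quantified features of the prefix up to ``t_cut``.

    The baseline MAP stays reading 0 regardless of the cut. Features
    undefined on a short prefix are NaN sentinels (mapped to 0 after
    normalization downstream, with the family's missingness indicator
    raised).
    """
    if t_cut < series.t[0]:
        raise ValueError(f"t_cut={t_cut} precedes the first grid point")
    pre = series.prefix(t_cut)
    row: dict[str, float] = {}
    if pre.n >= 2:
        row.update(manual_feature_row(pre))
        row.update(series_feature_row(pre))
    else:  # a single reading carries no dynamics: everything is sentinel
        from .features import feature_manifest

        row.update({name: np.nan for name in MANUAL_FEATURES})
        row.update({c: np.nan for c in feature_manifest()["column"]})
    return pd.Series(row)


def score_trajectory(
    bundle: ModelBundle, series: CirculationSeries, clinical_row: pd.Series
) -> ScoreTrajectory:
    """Score every growing 5-minute prefix of one patient's series."""
    if bundle.norm_params is None:
        raise ValueError("bundle carries no normalization parameters")
    times = np.asarray(series.t, float)
    scores = np.full(len(times), bundle.train_prevalence)
    fallback = np.arange(len(times)) + 1 < MIN_PREFIX_POINTS
    live = np.flatnonzero(~fallback)
    if len(live):
        rows = [
            {**prefix_features(series, times[i]).to_dict(), **clinical_row.to_dict()}
            for i in live
        ]
        frame = pd.DataFrame(rows)
        quant_cols = [c for c in frame.columns if "__" in c]
        frame = pd.concat([frame, _indicator_columns(frame[quant_cols])], axis=1)
        frame = frame[list(bundle.feature_names)]
        normed = apply_minmax(frame, bundle.norm_params).fillna(0.0)
        scores[live] = bundle.predict_proba(normed)
    return ScoreTrajectory(times=times, scores=scores, fallback_mask=fallback)
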