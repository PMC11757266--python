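"""Grid regularization, gap imputation, MAP computation, min-max scaling.

Raw intraoperative readings are linearly interpolated onto the 5-minute
grid, short gaps (<= 10 min) are imputed, longer gaps exclude the
patient, and MAP is derived pointwise from systolic/diastolic pressure.
Feature matrices are min-max normalized with parameters fitted on the
training cohort only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import (
    RECORDED_CHANNELS,
    CirculationSeries,
    SeriesExclusionError,
    UnusableSeriesError,
)

__all__ = [
    "regularize_grid",
    "impute_gaps",
    "compute_map",
    "with_map",
    "NormalizationParams",
    "fit_minmax",
    "apply_minmax",
]


def compute_map(sbp, dbp):
    """Mean arterial pressure from systolic/diastolic pressure.

    Uses the standard clinical estimate MAP = DBP + (SBP - DBP)/3.
    Accepts scalars or arrays; requires SBP > DBP > 0 wherever both
    are observed (NaN pairs pass through as NaN).
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    observed = ~(np.isnan(sbp) | np.isnan(dbp))
    bad = observed & ((sbp <= dbp) | (dbp <= 0))
    if np.any(bad):
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"invalid reading at index {k}: sbp={sbp.flat[k]}, dbp={dbp.flat[k]} "
            "(requires sbp > dbp > 0)"
        )
    out = dbp + (sbp - dbp) / 3.0
    if out.ndim == 0:
        return float(out)
    return out


def with_map(series: CirculationSeries) -> CirculationSeries:
    """Populate the derived MAP channel and the pre-induction baseline.

    The baseline is the first grid reading: the arterial line is placed
    before anesthesia induction, so reading 0 precedes induction.
    """
    m = compute_map(series.sbp, series.dbp)
    m = np.atleast_1d(m)
    return replace(series, map=m, baseline_map=float(m[0]))


def regularize_grid(
    patient_id: str,
    t_raw,
    channels: dict[str, np.ndarray],
    grid_minutes: float = 5.0,
) -> CirculationSeries:
    """Resample irregular readings onto the regular grid by linear interpolation.

    The grid spans [first reading, last reading] in steps of
    ``grid_minutes`` and is re-anchored to t=0; values beyond the
    recorded range are never extrapolated. Already-gridded input is
    returned unchanged (idempotent).
    """
    t_raw = np.asarray(t_raw, dtype=float)
    if len(t_raw) < 2:
        raise UnusableSeriesError(
            f"patient {patient_id!r}: {len(t_raw)} reading(s), need >= 2"
        )
    order = np.argsort(t_raw, kind="stable")
    t_sorted = t_raw[order]
    grid = np.arange(0.0, t_sorted[-1] - t_sorted[0] + 1e-9, grid_minutes)
    resampled = {}
    for ch in RECORDED_CHANNELS:
        x = np.asarray(channels[ch], dtype=float)[order]
        if len(x) != len(t_sorted):
            raise ValueError(f"channel {ch!r} length mismatch")
        obs = ~np.isnan(x)
        if obs.sum() >= 2:
            y = np.interp(grid, t_sorted[obs] - t_sorted[0], x[obs])
        else:
            # too few observed points to interpolate; leave for gap logic
            y = np.full_like(grid, np.nan)
        # a grid point coinciding with a missing raw reading stays missing
        nan_times = np.round(t_sorted[~obs] - t_sorted[0], 6)
        if len(nan_times):
            y[np.isin(np.round(grid, 6), nan_times)] = np.nan
        resampled[ch] = y
    return CirculationSeries(
        patient_id=patient_id, t=grid, grid_minutes=grid_minutes, **resampled
    )


def _fill_channel(x: np.ndarray, patient_id: str, channel: str) -> np.ndarray:
    """Linear fill of interior NaN runs of length <= 2; longer runs raise."""
    x = x.copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    idx = np.arange(len(x))
    # locate interior runs
    run_start = None
    for k in range(len(x)):
        if isnan[k] and run_start is None:
            run_start = k
        elif not isnan[k] and run_start is not None:
            if k - run_start > 2:
                raise SeriesExclusionError(patient_id, channel, k - run_start)
            run_start = None
    if run_start is not None and len(x) - run_start > 2:
        raise SeriesExclusionError(patient_id, channel, len(x) - run_start)
    obs = ~isnan
    x[isnan] = np.interp(idx[isnan], idx[obs], x[obs])
    return x


def impute_gaps(series: CirculationSeries) -> CirculationSeries:
    """Impute short gaps; drop unfillable edges; exclude long gaps.

    An isolated missing point becomes the mean of its two grid
    neighbors (linear interpolation degenerates to exactly that); runs
    of two missing points are linearly interpolated between the
    flanking values. Leading/trailing missing points are dropped and
    the grid re-anchored to t=0. Any interior run longer than two
    points (> 10 min) raises :class:`SeriesExclusionError`.
    """
    data = {ch: series.channel(ch) for ch in RECORDED_CHANNELS}
    anynan = np.column_stack([np.isnan(v) for v in data.values()])
    # trim rows where any channel is missing at the edges
    interior = ~anynan.any(axis=1)
    if not interior.any():
        raise SeriesExclusionError(series.patient_id, "all", series.n)
    first, last = np.flatnonzero(interior)[[0, -1]]
    t = series.t[first : last + 1]
    out = {}
    for ch in RECORDED_CHANNELS:
        out[ch] = _fill_channel(
            data[ch][first : last + 1], series.patient_id, ch
        )
    trimmed = CirculationSeries(
        patient_id=series.patient_id,
        t=t - t[0],
        grid_minutes=series.grid_minutes,
        **out,
    )
    return with_map(trimmed)


@dataclass
class NormalizationParams:
    """Per-feature training-cohort min and max for min-max scaling."""

    min_: pd.Series
    max_: pd.Series

    def to_dict(self) -> dict:
        return {
            name: [float(self.min_[name]), float(self.max_[name])]
            for name in self.min_.index
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        names = list(d)
        return cls(
            min_=pd.Series({n: d[n][0] for n in names}),
            max_=pd.Series({n: d[n][1] for n in names}),
        )


def fit_minmax(train: pd.DataFrame) -> NormalizationParams:
    """Fit min-max parameters on training rows only (NaN ignored)."""
    return NormalizationParams(min_=train.min(axis=0), max_=train.max(axis=0))


def apply_minmax(matrix: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Scale x -> (x - min)/(max - min) using training-fitted parameters.

    Constant training features (max == min) map to 0 everywhere.
    Values outside the training range are NOT clipped and may fall
    outside [0, 1]. Unknown feature names raise a schema error.
    """
    unknown = set(matrix.columns) - set(params.min_.index)
    if unknown:
        raise KeyError(f"features not seen at fit time: {sorted(unknown)}")
    lo = params.min_[matrix.columns]
    span = params.max_[matrix.columns] - lo
    out = (matrix - lo).div(span.where(span != 0.0))
    constant = span.index[span == 0.0]
    out[constant] = matrix[constant].notna().astype(float) * 0.0
    # keep NaN where the input itself was undefined
    return out.where(matrix.notna())
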