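"""Manual intraoperative circulation assessment features.

Four scalar summaries of the MAP trace, as used in clinical appraisal
of intraoperative circulation:

* TW hypertension / TW hypotension — time-weighted burden of MAP
  excursion beyond +/-30% of the pre-induction baseline, in mmHg*min:
  the time-integral (trapezoid rule on the grid) of the clamped excess
  depth beyond the threshold, i.e. mean depth x time beyond threshold.
* ARV — generalized average real variability: interval-weighted mean
  absolute successive MAP difference, ARV = (1/T) sum_k dt_k |dMAP_k|.
* ARVs — squared generalized ARV, ARVs = (1/T) sum_k |dMAP_k|^2 / dt_k
  (mmHg^2/min).

Threshold crossings between grid points are not sub-resolved: the data
resolution is 5 minutes and the trapezoid rule on clamped values is
applied as-is.
"""

from __future__ import annotations

import numpy as np

from .containers import CirculationSeries

__all__ = [
    "thresholds",
    "tw_hypotension",
    "tw_hypertension",
    "arv",
    "arvs",
    "manual_feature_row",
    "MANUAL_FEATURES",
]

#: reserved feature-matrix column names, in emission order
MANUAL_FEATURES = ("tw_hypotension", "tw_hypertension", "arv_map", "arvs_map")


def thresholds(baseline_map: float) -> tuple[float, float]:
    """(hypotension, hypertension) thresholds: -/+30% of baseline MAP."""
    if not baseline_map > 0:
        raise ValueError(f"baseline MAP must be positive, got {baseline_map}")
    return 0.7 * baseline_map, 1.3 * baseline_map


def _tw(t: np.ndarray, excess: np.ndarray) -> float:
    """Trapezoidal integral of the clamped excess depth, mmHg*min."""
    return float(np.trapezoid(np.maximum(excess, 0.0), t))


def _map_and_t(series: CirculationSeries):
    m = series.channel("map")
    if len(m) < 2:
        raise ValueError("metric undefined on single-point series")
    return np.asarray(series.t, float), np.asarray(m, float)


def tw_hypotension(series: CirculationSeries) -> float:
    """Time-weighted hypotension: integral of max(0, thr_lo - MAP) over time."""
    t, m = _map_and_t(series)
    lo, _ = thresholds(series.baseline_map)
    return _tw(t, lo - m)


def tw_hypertension(series: CirculationSeries) -> float:
    """Time-weighted hypertension: integral of max(0, MAP - thr_hi) over time."""
    t, m = _map_and_t(series)
    _, hi = thresholds(series.baseline_map)
    return _tw(t, m - hi)


def arv(series: CirculationSeries) -> float:
    t, m = _map_and_t(series)
    dt = np.diff(t)
    T = t[-1] - t[0]
    if not T > 0:
        raise ValueError("total time T must be positive")
    return float(np.sum(dt * np.abs(np.diff(m))) / T)


def arvs(series: CirculationSeries) -> float:
    t, m = _map_and_t(series)
    dt = np.diff(t)
    T = t[-1] - t[0]
    if not T > 0:
        raise ValueError("total time T must be positive")
    return float(np.sum(np.diff(m) ** 2 / dt) / T)


def manual_feature_row(series: CirculationSeries) -> dict[str, float]:
    """One feature-matrix row of the four manual circulation metrics."""
    return {
        "tw_hypotension": tw_hypotension(series),
        "tw_hypertension": tw_hypertension(series),
        "arv_map": arv(series),
        "arvs_map": arvs(series),
    }
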