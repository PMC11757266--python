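"""Core data containers for intraoperative circulation analysis.

A patient's intraoperative record is a multichannel vital-sign series
(systolic/diastolic blood pressure, heart rate, pulse) sampled on a
regular 5-minute grid, together with a clinical covariate row and the
postoperative length of stay (LOS). The binary outcome PLOS (prolonged
length of stay) marks a stay strictly above the cohort median LOS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: channel names recorded by the monitor, in canonical order
RECORDED_CHANNELS = ("sbp", "dbp", "hr", "pulse")
#: channels features are extracted from (recorded + derived MAP)
ALL_CHANNELS = RECORDED_CHANNELS + ("map",)

#: clinical covariates carried into the predictive models
CLINICAL_COVARIATES = (
    "age",
    "sex",
    "smoking",
    "albumin_pre",
    "hb_post",
    "rbc_units",
    "reoperation",
)


class UnusableSeriesError(ValueError):
    """Raised when a raw recording cannot be regularized (< 2 readings)."""


class SeriesExclusionError(ValueError):
    """Raised when a series violates the gap rule (> 10 min of missing data).

    Mirrors the cohort exclusion criterion: patients missing blood
    pressure, heart rate or pulse values for more than 10 minutes
    (i.e. more than two consecutive 5-minute grid points) are excluded.
    """

    def __init__(self, patient_id: str, channel: str, gap_points: int):
        self.patient_id = patient_id
        self.channel = channel
        self.gap_points = gap_points
        super().__init__(
            f"patient {patient_id!r}: channel {channel!r} has "
            f"{gap_points} consecutive missing points (> 10 min)"
        )


@dataclass
class CirculationSeries:
    """One patient's vital-sign record on the 5-minute grid.

    ``t`` is minutes since the first reading; all channels share its
    length. ``map`` is the derived mean arterial pressure channel and
    ``baseline_map`` the pre-induction MAP (first grid reading).
    Missing points are NaN until :func:`opcirc.preprocess.impute_gaps`.
    """

    patient_id: str
    t: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    hr: np.ndarray
    pulse: np.ndarray
    map: np.ndarray | None = None
    baseline_map: float | None = None
    grid_minutes: float = 5.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for ch in RECORDED_CHANNELS:
            setattr(self, ch, np.asarray(getattr(self, ch), dtype=float))
        if self.map is not None:
            self.map = np.asarray(self.map, dtype=float)
        n = len(self.t)
        for ch in RECORDED_CHANNELS:
            if len(getattr(self, ch)) != n:
                raise ValueError(f"channel {ch!r} length != len(t)")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Total time T between first and last reading, minutes."""
        return float(self.t[-1] - self.t[0])

    def channel(self, name: str) -> np.ndarray:
        if name not in ALL_CHANNELS:
            raise KeyError(name)
        x = getattr(self, name)
        if x is None:
            raise ValueError(f"channel {name!r} not populated")
        return x

    def prefix(self, t_cut: float) -> "CirculationSeries":
        """Truncate to grid points with t <= t_cut (baseline unchanged)."""
        if t_cut < self.t[0]:
            raise ValueError(f"t_cut={t_cut} precedes first grid point {self.t[0]}")
        keep = self.t <= t_cut
        return replace(
            self,
            t=self.t[keep],
            sbp=self.sbp[keep],
            dbp=self.dbp[keep],
            hr=self.hr[keep],
            pulse=self.pulse[keep],
            map=None if self.map is None else self.map[keep],
        )


@dataclass
class PatientRecord:
    """Clinical covariates + circulation series + LOS outcome."""

    patient_id: str
    covariates: dict[str, float]
    series: CirculationSeries
    los_days: float
    plos: int | None = None

    def covariate_row(self) -> dict[str, float]:
        return {k: float(self.covariates[k]) for k in CLINICAL_COVARIATES}


@dataclass
class Episode:
    """One inserted blood-pressure excursion (synthetic ground truth)."""

    start_min: float
    duration_min: float
    depth_mmhg: float  # positive magnitude
    direction: int  # -1 hypotensive, +1 hypertensive
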