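"""Synthetic intraoperative cohorts with known, recoverable structure.

The study's clinical data are not publicly deposited, so cohorts are
emulated with a generative model whose ground truth is recorded:

* MAP follows patient baseline + a discretized Ornstein-Uhlenbeck
  fluctuation (mean-reverting, autocorrelated — the qualitative
  behavior of intraoperative arterial traces) + episodic hypotensive /
  hypertensive excursions (boxcar with 5-min ramps, random 10-30 min
  duration) + a slow sinusoidal oscillation whose per-patient
  amplitude is a latent trait with a spectral (not time-weighted)
  footprint.
* SBP/DBP are reconstructed around MAP with a noisy physiologic pulse
  pressure (mean 40 mmHg), inverting the MAP formula so that
  compute_map(SBP, DBP) recovers MAP exactly.
* HR couples baroreflex-style to MAP (hypotension -> tachycardia);
  pulse tracks HR with small noise.
* Points are deleted with a per-point missing probability, never more
  than 2 consecutive (gaps stay <= 10 min, inside the exclusion bound).
* PLOS is Bernoulli(sigmoid(intercept + sum effect * standardized true
  feature)); LOS is median-anchored (median 10 days) consistent with
  the label whenever prevalence <= 1/2.

One master seed spawns per-patient streams counter-style, so cohorts
are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import CirculationSeries, Episode, PatientRecord
from .manual_metrics import manual_feature_row
from .preprocess import with_map

__all__ = ["SimulationConfig", "GroundTruth", "simulate_series", "simulate_cohort"]

#: default clinical covariate distributions: head-and-neck free-flap
#: surgery skews older, male, with frequent smoking history; albumin
#: and hemoglobin centered on the perioperative ranges typical there.
DEFAULT_COVARIATE_SPECS: dict[str, tuple] = {
    "age": ("normal", 55.0, 12.0),
    "sex": ("bernoulli", 0.7),
    "smoking": ("bernoulli", 0.45),
    "albumin_pre": ("normal", 30.0, 4.0),
    "hb_post": ("normal", 110.0, 14.0),
    "rbc_units": ("poisson", 0.7),
    "reoperation": ("bernoulli", 0.08),
}

DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "tw_hypotension": 0.8,
    "age": 0.4,
    "albumin_pre": -0.4,
    "reoperation": 0.6,
}

#: series-derived quantities the outcome model may load on
TRUE_SERIES_FEATURES = (
    "tw_hypotension",
    "tw_hypertension",
    "arv_map",
    "arvs_map",
    "osc_amplitude",
)

MEDIAN_LOS = 10  # days, anchoring the LOS generator


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic cohort."""

    n_patients: int = 200
    series_len_range: tuple[int, int] = (60, 120)  # grid points
    grid_minutes: float = 5.0
    baseline_map_mean: float = 85.0  # mmHg
    baseline_map_sd: float = 8.0  # mmHg
    ou_theta: float = 0.03  # 1/min mean-reversion rate
    ou_sigma: float = 1.5  # mmHg/sqrt(min) fluctuation scale
    episode_rate: float = 1.2  # episodes/hour
    episode_depth_mean: float = 25.0  # mmHg
    episode_hypo_prob: float = 0.8  # fraction of episodes that are hypotensive
    osc_period: float = 60.0  # min, slow oscillation
    osc_amplitude_sd: float = 6.0  # mmHg, latent-trait scale (slow vasomotor waves)
    pulse_pressure_mean: float = 40.0  # mmHg
    pulse_pressure_sd: float = 4.0  # mmHg
    hr_mean: float = 75.0  # bpm
    hr_sd: float = 10.0  # bpm between-patient
    missing_prob: float = 0.03
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    outcome_intercept: float = 0.0
    covariate_specs: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_SPECS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not self.grid_minutes > 0:
            raise ValueError("grid_minutes must be positive")
        lo, hi = self.series_len_range
        if not (2 <= lo <= hi):
            raise ValueError("series_len_range must satisfy 2 <= min <= max")
        for name, p in [
            ("missing_prob", self.missing_prob),
            ("episode_hypo_prob", self.episode_hypo_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.episode_depth_mean < 0:
            raise ValueError("episode_depth_mean must be >= 0")
        known = set(TRUE_SERIES_FEATURES) | set(self.covariate_specs)
        unknown = set(self.effect_sizes) - known
        if unknown:
            raise ValueError(f"effect_sizes reference unknown features: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    effect_sizes: dict[str, float]
    intercept: float
    linear_predictor: np.ndarray  # per patient log-odds
    true_features: "object"  # DataFrame: standardized features used in the outcome
    raw_features: "object"  # DataFrame: unstandardized true feature values

    def to_json(self, path) -> None:
        payload = {
            "effect_sizes": self.effect_sizes,
            "intercept": self.intercept,
            "linear_predictor": [float(v) for v in self.linear_predictor],
            "true_features": json.loads(self.true_features.to_json(orient="index")),
            "raw_features": json.loads(self.raw_features.to_json(orient="index")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _episode_profile(t: np.ndarray, ep: Episode, ramp: float = 5.0) -> np.ndarray:
    """Trapezoidal (boxcar-with-ramps) perturbation profile in [0, 1]."""
    rise = (t - ep.start_min) / ramp
    fall = (ep.start_min + ep.duration_min + 2 * ramp - t) / ramp
    return np.clip(np.minimum(rise, fall), 0.0, 1.0)


def _ou_path(rng, n: int, dt: float, theta: float, sigma: float) -> np.ndarray:
    """Exact discretization of dX = -theta X dt + sigma dW, X0 = 0."""
    x = np.zeros(n)
    if sigma == 0 or n < 2:
        return x
    if theta > 0:
        decay = np.exp(-theta * dt)
        step_sd = sigma * np.sqrt((1 - decay**2) / (2 * theta))
    else:  # random-walk limit
        decay = 1.0
        step_sd = sigma * np.sqrt(dt)
    z = rng.standard_normal(n - 1)
    for k in range(1, n):
        x[k] = x[k - 1] * decay + step_sd * z[k - 1]
    return x


def _missing_mask(rng, n: int, p: float) -> np.ndarray:
    """Bernoulli(p) deletions, endpoints kept, never 3+ consecutive."""
    mask = np.zeros(n, dtype=bool)
    if p <= 0 or n <= 2:
        return mask
    draws = rng.random(n)
    run = 0
    for k in range(1, n - 1):
        if draws[k] < p and run < 2:
            mask[k] = True
            run += 1
        else:
            run = 0
    return mask


def _patient_rng(config: SimulationConfig, patient_seed: int):
    return np.random.default_rng([config.seed & 0x7FFFFFFF, patient_seed])


def simulate_series(
    config: SimulationConfig,
    patient_seed: int,
    return_info: bool = False,
):
    """Generate one patient's circulation series (complete, MAP populated).

    With ``return_info=True`` also returns a dict holding the inserted
    episode list, the latent oscillation amplitude, and the missingness
    mask to apply (deletions are returned separately so ground-truth
    features can be computed on the complete trace).
    """
    config.validate()
    rng = _patient_rng(config, patient_seed)
    lo, hi = config.series_len_range
    n = int(rng.integers(lo, hi + 1))
    dt = config.grid_minutes
    t = np.arange(n) * dt
    baseline = rng.normal(config.baseline_map_mean, config.baseline_map_sd)

    ou = _ou_path(rng, n, dt, config.ou_theta, config.ou_sigma)

    duration_h = t[-1] / 60.0
    n_ep = rng.poisson(config.episode_rate * duration_h)
    episodes: list[Episode] = []
    ep_wave = np.zeros(n)
    for _ in range(n_ep):
        depth = max(
            0.0, rng.normal(config.episode_depth_mean, config.episode_depth_mean / 5)
        )
        ep = Episode(
            start_min=float(rng.uniform(0, t[-1])),
            duration_min=float(rng.uniform(10, 30)),
            depth_mmhg=depth,
            direction=-1 if rng.random() < config.episode_hypo_prob else 1,
        )
        episodes.append(ep)
        ep_wave += ep.direction * ep.depth_mmhg * _episode_profile(t, ep)

    osc_amplitude = abs(rng.normal(0.0, config.osc_amplitude_sd))
    phase = rng.uniform(0, 2 * np.pi)
    osc = osc_amplitude * np.sin(2 * np.pi * t / config.osc_period + phase)

    map_trace = np.clip(baseline + ou + ep_wave + osc, 35.0, 170.0)
    map_trace[0] = baseline  # reading 0 is the pre-induction baseline

    pp = np.clip(
        rng.normal(config.pulse_pressure_mean, config.pulse_pressure_sd, n), 10.0, None
    )
    sbp = map_trace + (2.0 / 3.0) * pp
    dbp = map_trace - (1.0 / 3.0) * pp

    hr_base = rng.normal(config.hr_mean, config.hr_sd)
    hr = (
        hr_base
        - 0.3 * (map_trace - baseline)  # baroreflex-style coupling
        + _ou_path(rng, n, dt, config.ou_theta, 0.8 * config.ou_sigma)
    )
    hr = np.clip(hr, 30.0, 180.0)
    pulse = hr + rng.normal(0.0, 1.0, n)

    series = with_map(
        CirculationSeries(
            patient_id=f"p{patient_seed:05d}",
            t=t,
            sbp=sbp,
            dbp=dbp,
            hr=hr,
            pulse=pulse,
            grid_minutes=dt,
        )
    )
    if not return_info:
        return series
    info = {
        "episodes": episodes,
        "osc_amplitude": osc_amplitude,
        "missing_mask": _missing_mask(rng, n, config.missing_prob),
        "baseline": baseline,
    }
    return series, info


def _apply_missing(series: CirculationSeries, mask: np.ndarray) -> CirculationSeries:
    def holes(x):
        y = np.asarray(x, dtype=float).copy()
        y[mask] = np.nan
        return y

    return CirculationSeries(
        patient_id=series.patient_id,
        t=series.t.copy(),
        sbp=holes(series.sbp),
        dbp=holes(series.dbp),
        hr=holes(series.hr),
        pulse=holes(series.pulse),
        grid_minutes=series.grid_minutes,
    )


def _draw_covariates(rng, specs: dict[str, tuple]) -> dict[str, float]:
    out = {}
    for name, spec in specs.items():
        kind = spec[0]
        if kind == "normal":
            out[name] = float(rng.normal(spec[1], spec[2]))
        elif kind == "bernoulli":
            out[name] = float(rng.random() < spec[1])
        elif kind == "poisson":
            out[name] = float(rng.poisson(spec[1]))
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")
    return out


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a full cohort with recorded ground truth.

    PLOS is drawn from the logistic model on cohort-standardized true
    features; LOS is then generated consistent with the label around
    the 10-day median anchor.
    """
    import pandas as pd

    config.validate()
    master = np.random.default_rng([config.seed & 0x7FFFFFFF, 999_983])
    raw_rows, covs, complete, masks = [], [], [], []
    for i in range(config.n_patients):
        series, info = simulate_series(config, i, return_info=True)
        row = manual_feature_row(series)
        row["osc_amplitude"] = info["osc_amplitude"]
        cov = _draw_covariates(_patient_rng(config, 10_000_000 + i), config.covariate_specs)
        raw_rows.append(row)
        covs.append(cov)
        complete.append(series)
        masks.append(info["missing_mask"])

    ids = [s.patient_id for s in complete]
    raw = pd.DataFrame(raw_rows, index=ids)
    cov_df = pd.DataFrame(covs, index=ids)
    pool = pd.concat([raw, cov_df], axis=1)
    z = pd.DataFrame(
        np.column_stack([_standardize(pool[c].to_numpy(float)) for c in pool.columns]),
        index=ids,
        columns=pool.columns,
    )

    eta = np.full(config.n_patients, config.outcome_intercept, dtype=float)
    for name, beta in config.effect_sizes.items():
        eta += beta * z[name].to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    plos = (master.random(config.n_patients) < p).astype(int)

    if config.n_patients >= 50 and len(np.unique(plos)) == 1:
        warnings.warn(
            "degenerate configuration: single-class PLOS outcome", stacklevel=2
        )

    # LOS: non-PLOS mass concentrated at the 10-day anchor (P=0.6), PLOS
    # strictly above it; keeps the empirical median at 10 whenever
    # prevalence <= 1/2, so median-rule relabeling reproduces the labels.
    los = np.empty(config.n_patients)
    for i in range(config.n_patients):
        if plos[i]:
            los[i] = MEDIAN_LOS + master.geometric(0.35)
        else:
            los[i] = MEDIAN_LOS - min(master.geometric(0.6) - 1, MEDIAN_LOS - 1)

    records = []
    for i, (series, mask) in enumerate(zip(complete, masks)):
        records.append(
            PatientRecord(
                patient_id=series.patient_id,
                covariates=covs[i],
                series=_apply_missing(series, mask),
                los_days=float(los[i]),
                plos=int(plos[i]),
            )
        )
    used = sorted(config.effect_sizes)
    gt = GroundTruth(
        effect_sizes=dict(config.effect_sizes),
        intercept=config.outcome_intercept,
        linear_predictor=eta,
        true_features=z[used] if used else z.iloc[:, :0],
        raw_features=pool,
    )
    return records, gt
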