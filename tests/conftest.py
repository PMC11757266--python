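import numpy as np
import pytest

from opcirc.containers import CirculationSeries
from opcirc.preprocess import with_map
from opcirc.synthetic import SimulationConfig, simulate_cohort


def make_map_series(map_values, dt=5.0, pp=40.0, patient_id="t0"):
    """Build a series whose MAP channel equals ``map_values`` exactly."""
    m = np.asarray(map_values, dtype=float)
    t = np.arange(len(m)) * dt
    sbp = m + (2.0 / 3.0) * pp
    dbp = m - (1.0 / 3.0) * pp
    hr = np.full(len(m), 70.0)
    return with_map(
        CirculationSeries(
            patient_id=patient_id, t=t, sbp=sbp, dbp=dbp, hr=hr, pulse=hr.copy()
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """120 patients with the default planted effects, deterministic."""
    cfg = SimulationConfig(n_patients=120, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def random_map_series(rng):
    """100 random short MAP series for oracle-equivalence checks."""
    out = []
    for _ in range(100):
        n = int(rng.integers(5, 50))
        m = 85 + 12 * rng.standard_normal(n)
        out.append(make_map_series(m))
    return out
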