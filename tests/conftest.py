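import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from mixtox import BioassayRecord, MortalityTable, SimConfig, simulate_mixture_experiment


@pytest.fixture
def exact_line_table() -> MortalityTable:
    """Corrected mortality exactly on y = 10x + 30 (% vs log10 dose)."""
    doses = np.array([1.0, 10.0, 100.0])
    y = (10.0 * np.log10(doses) + 30.0) / 100.0
    n = np.full(3, 90.0)
    return MortalityTable(
        treatment_id="t",
        unit="mg/L",
        doses=doses,
        n_exposed=n,
        n_dead=n * y,
        raw_mortality=y,
        corrected_mortality=y,
    )


@pytest.fixture
def replicate_records() -> list[BioassayRecord]:
    """Three replicates of 30 insects at each of two doses plus controls."""
    recs = []
    for rep, dead in enumerate((10, 15, 20)):
        recs.append(BioassayRecord("t", 1.0, "mg/L", 30, dead, rep))
    for rep, dead in enumerate((25, 28, 27)):
        recs.append(BioassayRecord("t", 10.0, "mg/L", 30, dead, rep))
    for rep in range(3):
        recs.append(BioassayRecord("t", 0.0, "mg/L", 30, 0, rep, is_control=True))
    return recs


@pytest.fixture
def mixture_experiment():
    """One simulated experiment at the standard design with true CTC 150."""
    cfg = SimConfig(true_ctc=150.0, seed=42)
    rec_a, rec_b, rec_m, truth = simulate_mixture_experiment(cfg)
    return cfg, rec_a, rec_b, rec_m, truth
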