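import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from agr_screen.cohort import Cohort, PatientRecord
from agr_screen.synthetic import default_table1_spec, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_cohort(infected_values, aseptic_values, **extra) -> Cohort:
    """Cohort from raw AGR values; extras are per-record field arrays."""
    records = []
    for i, v in enumerate(infected_values):
        kw = {k: vals[i] for k, vals in extra.get("infected", {}).items()}
        records.append(PatientRecord(patient_id=f"i{i}", infected=1, agr=float(v), **kw))
    for i, v in enumerate(aseptic_values):
        kw = {k: vals[i] for k, vals in extra.get("aseptic", {}).items()}
        records.append(PatientRecord(patient_id=f"a{i}", infected=0, agr=float(v), **kw))
    return Cohort(records=records)


def lognormal_cohort(mu_inf, s_inf, mu_asep, s_asep, n_per_group, seed) -> Cohort:
    rng = np.random.default_rng(seed)
    inf = np.exp(rng.normal(mu_inf, s_inf, n_per_group))
    asep = np.exp(rng.normal(mu_asep, s_asep, n_per_group))
    return build_cohort(inf, asep)


@pytest.fixture
def make_cohort():
    return build_cohort


@pytest.fixture(scope="session")
def table1_cohort() -> Cohort:
    """One study-calibrated synthetic cohort (129 infected / 108 aseptic)."""
    return generate_cohort(default_table1_spec(seed=1))
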