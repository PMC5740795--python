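import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from traumascore.synthetic import SyntheticConfig, config_replace, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TOY_CSV = """patient_id,age,sex,mechanism,rr,sbp,gcs,died,injuries,site
P1,36,male,blunt,20,120,15,0,head_neck:3;chest:4,A
P2,62,female,penetrating,8,70,7,1,abdomen:4;abdomen:3;extremities:2,B
P3,14,male,blunt,35,95,14,0,extremities:2,A
P4,45,male,blast,0,0,3,1,head_neck:5;chest:5;abdomen:4,B
P5,28,female,blunt,22,130,15,0,,A
"""


@pytest.fixture
def toy_registry(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient calibrated synthetic cohort (fixed seed)."""
    return generate_cohort(config_replace(SyntheticConfig(), n=300, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20259)
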