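import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from burstfish import GeneModel, TelegraphParams

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def params_std() -> TelegraphParams:
    """Symmetric-switching reference point lam=gam=delta=1, mu=10."""
    return TelegraphParams(lam=1.0, gam=1.0, mu=10.0, delta=1.0, beta=1.0)


@pytest.fixture
def gene_single_intron() -> GeneModel:
    """Whole-gene intron with the probe at 0: every polymerase is detectable."""
    return GeneModel(
        length_bp=1000,
        exon_probe_positions=(100, 200, 300, 400),
        intron_probe_positions=(0,),
        intron_intervals=((0, 1000),),
        elongation_bp_per_s=50.0,
    )


@pytest.fixture
def gene_two_introns() -> GeneModel:
    return GeneModel(
        length_bp=2000,
        exon_probe_positions=(50, 400, 900, 1400, 1900),
        intron_probe_positions=(520, 1250),
        intron_intervals=((500, 600), (1200, 1400)),
        elongation_bp_per_s=50.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
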