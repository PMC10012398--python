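import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repeatable",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")

from mnlr_samplesize import OutcomeDistribution, SizingConfig

WORKED_COUNTS = (2557, 186, 176, 467, 120)

# pairwise Cox-Snell R2 grid as printed to 3 d.p.
WORKED_PAIRWISE_R2 = {
    (2, 1): 0.116,
    (3, 1): 0.179,
    (4, 1): 0.497,
    (5, 1): 0.170,
    (3, 2): 0.185,
    (4, 2): 0.499,
    (5, 2): 0.374,
    (4, 3): 0.328,
    (5, 3): 0.129,
    (5, 4): 0.210,
}

# published whole-cohort pairwise sizes for the same grid
WORKED_PAIR_N = {
    (2, 1): 1574,
    (3, 1): 982,
    (4, 1): 246,
    (5, 1): 1067,
    (3, 2): 7147,
    (4, 2): 1128,
    (5, 2): 3629,
    (4, 3): 2045,
    (5, 3): 13063,
    (5, 4): 3813,
}


@pytest.fixture
def worked_dist() -> OutcomeDistribution:
    """Five-category ovarian-tumour outcome distribution (n = 3506)."""
    return OutcomeDistribution(WORKED_COUNTS)


@pytest.fixture
def worked_cfg() -> SizingConfig:
    return SizingConfig(Q=17)
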