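import pytest
from hypothesis import HealthCheck, settings

from panpav.simdata import SimConfig, build_pangenome

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SMALL = SimConfig(
    seed=7,
    n_accessions=12,
    n_groups=2,
    chrom_lengths=(200_000, 200_000),
    n_core_genes=20,
    n_dispensable_genes=30,
    sv_counts={"DEL": 3, "INV": 2, "DUP": 2, "TRA": 1},
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_truth():
    return build_pangenome(SMALL)
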