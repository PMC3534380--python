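import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pgi import synthetic_data as sd  # noqa: E402


@pytest.fixture(scope="session")
def bundle():
    """Small two-contig genome bundle shared across tests."""
    cfg = sd.GenomeConfig(
        contig_lengths={"chr1": 120_000, "chr2": 80_000},
        n_genes=14,
        n_repeats=50,
        n_tfbs=20,
        n_enhancers=10,
    )
    return sd.generate_genome_bundle(cfg, seed=11)


@pytest.fixture(scope="session")
def callset(bundle):
    cfg = sd.VariantConfig(n_snp=3000, n_indel=300)
    return sd.generate_variant_calls(bundle, cfg, seed=11)


@pytest.fixture(scope="session")
def risk_bundle():
    return sd.generate_risk_bundle(sd.RiskConfig(n_diseases=6, snps_per_disease=8), seed=11)
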