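import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small signal-rich synthetic dataset shared across tests."""
    from mutgo.synthetic import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(
        n_proteins=60,
        variants_per_protein=(2, 6),
        sequence_length=(60, 120),
        effect_size=2.0,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def trivial_folds(small_dataset):
    """Round-robin fold assignment (synthetic proteins are unrelated)."""
    proteins = sorted(small_dataset.sequences)
    return {p: i % 5 for i, p in enumerate(proteins)}
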