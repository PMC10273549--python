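import pytest

from pavpan import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A compact two-group dataset shared by read-only tests."""
    cfg = SimConfig(
        seed=7, n_ref_genes=12, n_novel_genes=4,
        groups=(("wild", 8), ("cultivar", 10)),
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The default three-group study-shaped dataset (wild/landrace/cultivar)."""
    return generate_dataset(SimConfig(seed=11))
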