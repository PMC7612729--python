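import pytest

from regdyn import SimulationConfig, simulate_study

#: Small study shared by unit tests: quick to generate, every feature planted.
SMALL = dict(seed=7, n_genes=100, n_enhancers=600, targets_per_class=1)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SimulationConfig(**SMALL))


@pytest.fixture(scope="session")
def small_elements(small_study):
    """Promoters and enhancers reconstructed from the study's ATAC channel."""
    from regdyn import build_enhancer_set, build_promoter_set

    promoters = build_promoter_set(small_study.annotation)
    enhancers = build_enhancer_set(small_study.atac_by_celltype, promoters)
    return promoters, enhancers
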