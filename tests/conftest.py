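import numpy as np
import pytest

from hmcnet.synthetic import (
    CountModel,
    GeneModel,
    MarkProfile,
    SnpModel,
    SynthConfig,
    generate_dataset,
    generate_worked_micro_example,
)


@pytest.fixture(scope="session")
def micro():
    """The fixed worked micro example: 3 chromosomes, 12 peaks, hand-checkable
    read layout."""
    return generate_worked_micro_example()


def small_config(**overrides) -> SynthConfig:
    """A fast dataset: 400 peaks on 10 x 300 kb chromosomes."""
    kwargs = dict(
        n_chroms=10,
        chrom_len=300_000,
        n_pos=400,
        marks=(
            MarkProfile("enhancer_mark", "pos_up", bump_height=25.0,
                        baseline=15.0, noise_sd=0.5),
            MarkProfile("promoter_mark", "neg_up", bump_height=20.0,
                        baseline=15.0, noise_sd=0.5),
        ),
        gene_model=GeneModel(n_genes=60),
        snp_model=SnpModel(n_pos_snps=120),
        seed=7,
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def small_ds():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
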