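import numpy as np
import pytest

from goosepop.synthetic_data import (
    PopSpec,
    SynthConfig,
    default_config,
    generate_dataset,
    generate_worked_toy,
)


@pytest.fixture(scope="session")
def toy():
    """Deterministic 12-individual, 60-locus dataset with planted bad loci."""
    return generate_worked_toy()


@pytest.fixture(scope="session")
def synth():
    """Mid-sized study-like dataset: 6 populations, 3 gene pools, one
    admixed breed, 2,000 SNPs with 5% missingness."""
    cfg = default_config(seed=11, n_loci=2000, missingness=0.05)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def two_pop_factory():
    """Factory for simple two-population datasets with tunable divergence."""

    def make(f_a=0.05, f_b=0.05, n=8, n_loci=1000, seed=0, missingness=0.0):
        cfg = SynthConfig(
            populations=[
                PopSpec("pa", "wild", n, cluster="wild"),
                PopSpec("pb", "domestic_european", n, cluster="dom_eu"),
            ],
            n_loci=n_loci,
            total_sites=100 * n_loci,
            missingness=missingness,
            seed=seed,
            cluster_f={"wild": f_a, "dom_eu": f_b, "dom_cn": 0.3},
            pop_f=0.0,
        )
        return generate_dataset(cfg)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
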