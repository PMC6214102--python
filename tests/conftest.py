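import numpy as np
import pytest

from plastokit.simulate import (
    CohortConfig,
    DivergenceConfig,
    GenePlanEntry,
    default_cohort_config,
    generate_cohort,
    generate_reference,
)


def small_gene_plan() -> list[GenePlanEntry]:
    """A compact plan for fast small-genome tests: a few protein genes
    (one intron gene per single-copy region), tRNAs and one IR rRNA."""
    return [
        GenePlanEntry("geneA", "protein_coding", "LSC", (300,), "+"),
        GenePlanEntry("geneB", "protein_coding", "LSC", (210, 213), "-", (150,)),
        GenePlanEntry("geneC", "protein_coding", "LSC", (450,), "+"),
        GenePlanEntry("trnX-AAA", "tRNA", "LSC", (75,), "+"),
        GenePlanEntry("pseuD", "pseudogene", "LSC", (240,), "+"),
        GenePlanEntry("geneE", "protein_coding", "SSC", (330,), "-"),
        GenePlanEntry("geneF", "protein_coding", "SSC", (120, 120), "+", (90,)),
        GenePlanEntry("geneG", "protein_coding", "IR", (390,), "+"),
        GenePlanEntry("rrnS", "rRNA", "IR", (500,), "+"),
    ]


def small_config(seed: int = 0, n_genotypes: int = 2, divergence=None) -> CohortConfig:
    return CohortConfig(
        lsc_len=9000,
        ssc_len=3000,
        ir_len=2600,
        gene_plan=small_gene_plan(),
        junction_spanners=False,
        n_genotypes=n_genotypes,
        divergence=divergence,
        seed=seed,
    )


def small_divergence(seed: int = 0, **kw) -> DivergenceConfig:
    defaults = dict(
        snp_rate_sc=2e-3,
        snp_rate_ir=2e-4,
        indel_plan=[
            ("LSC", "ins", 6, "intergenic"),
            ("LSC", "del", 7, "intergenic"),
            ("SSC", "ins", 5, "intergenic"),
        ],
        seed=seed,
    )
    defaults.update(kw)
    return DivergenceConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size five-genotype cohort (shared across tests; treat as
    read-only)."""
    return generate_cohort(default_cohort_config(1))


@pytest.fixture(scope="session")
def reference(default_cohort):
    return default_cohort[0][0]


@pytest.fixture()
def small_pair():
    cohort, manifests = generate_cohort(
        small_config(seed=3, divergence=[small_divergence(11)])
    )
    return cohort, manifests


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
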