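import numpy as np
import pytest

from paraplex import (
    LocusConfig,
    build_catalog,
    amplicon_truth_genotypes,
    generate_cohort,
    generate_locus,
)


@pytest.fixture(scope="session")
def default_locus():
    """Reference-genome-like locus: 26/0/1/1/0 distinguishing bases."""
    return generate_locus(LocusConfig(seed=11))


@pytest.fixture(scope="session")
def small_locus():
    """Compact locus for read-level simulations: 7 distinguishing bases
    in exon 11, none in exons 12-15 (the fully degraded configuration)."""
    return generate_locus(
        LocusConfig(
            exon_lengths=(200, 130, 120, 130, 120),
            n_distinguishing=(7, 0, 0, 0, 0),
            intron_length=200,
            flank=150,
            spacer=400,
            seed=5,
        )
    )


def catalog_from_clean_cohort(model, n_samples=5, seed=17):
    cohort = generate_cohort(model, n_samples, seed=seed)
    positions = [db.gene_pos for db in model.distinguishing_bases]
    gene = amplicon_truth_genotypes(cohort, model, "gene", positions)
    pseudo = amplicon_truth_genotypes(cohort, model, "pseudogene", positions)
    return build_catalog(gene, pseudo, model.distinguishing_bases)


@pytest.fixture(scope="session")
def small_catalog(small_locus):
    """All seven exon-11 distinguishing bases reliable (no conversion)."""
    return catalog_from_clean_cohort(small_locus)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
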