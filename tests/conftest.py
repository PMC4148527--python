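import numpy as np
import pandas as pd
import pytest

from driverrank import (
    AlterationCatalog,
    GeneNetwork,
    generate_cohort,
    generate_network,
    rank_cohort,
)


@pytest.fixture
def chain_network() -> GeneNetwork:
    """g1 -> g2 (two genes, one edge)."""
    return GeneNetwork.from_edges([("g1", "g2")])


@pytest.fixture
def toy_network() -> GeneNetwork:
    """a -> b, a -> c, b -> c."""
    return GeneNetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-gene, 12-patient synthetic cohort with planted drivers."""
    net = generate_network(120, mean_out_degree=6, seed=42)
    return generate_cohort(
        net, n_patients=12, drivers_per_patient=2, passengers_per_patient=5,
        signal=5.0, decay=0.5, noise_sd=1.0, seed=43,
    )


@pytest.fixture(scope="session")
def small_cohort_percentiles(small_cohort):
    pct, _ = rank_cohort(small_cohort.network, small_cohort.tumor, small_cohort.normal)
    return pct


def make_catalog(assignments: dict[str, dict[str, str]], patients=None) -> AlterationCatalog:
    """Catalog from {patient: {gene: category}} for concise test setup."""
    rows = [
        (p, g, c)
        for p, genes in assignments.items()
        for g, c in genes.items()
    ]
    table = pd.DataFrame(rows, columns=["patient", "gene", "category"])
    return AlterationCatalog(table, patients or list(assignments))
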