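import numpy as np
import pandas as pd
import pytest

from phagenet import AbundanceTable


def make_table(values, domains=None, groups=None):
    """Build a small validated AbundanceTable from a taxa × samples array."""
    values = np.asarray(values, dtype=float)
    n_taxa, n_samples = values.shape
    taxa = [f"T{i:02d}" for i in range(n_taxa)]
    samples = [f"S{j:02d}" for j in range(n_samples)]
    domains = domains or ["bacteria"] * n_taxa
    groups = groups or ["G1"] * n_samples
    taxonomy = pd.DataFrame(
        {
            "domain": domains,
            "phylum": "PhyX",
            "order": "OrdX",
            "family": "FamX",
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    metadata = pd.DataFrame(
        {
            "group": groups,
            "diet": "omnivore",
            "host_order": "Carnivora",
            "host_family": "Ursidae",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    frame = pd.DataFrame(
        values, index=pd.Index(taxa, name="taxon_id"), columns=samples
    )
    return AbundanceTable(frame, taxonomy, metadata)


@pytest.fixture
def toy_table():
    rng = np.random.default_rng(42)
    values = rng.lognormal(size=(8, 12))
    return make_table(values, domains=["bacteria"] * 5 + ["phage"] * 3,
                      groups=["G1"] * 6 + ["G2"] * 6)
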