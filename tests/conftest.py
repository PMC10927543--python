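import numpy as np
import pandas as pd
import pytest

from pollentrends.synthetic import SyntheticConfig, generate_archipelago
from pollentrends.taxonomy import NameTable, TaxonEntry, TaxonStatus


@pytest.fixture(scope="session")
def small_config():
    """A reduced archipelago for fast structural tests."""
    return SyntheticConfig(
        n_sites=6, n_islands=5, pool_size=20, samples_per_site=30, seed=11
    )


@pytest.fixture(scope="session")
def small_archipelago(small_config):
    return generate_archipelago(small_config)


@pytest.fixture(scope="session")
def default_archipelago():
    return generate_archipelago(SyntheticConfig(seed=7))


@pytest.fixture
def toy_name_table():
    """Hand-built table covering every resolution status."""
    return NameTable(
        [
            TaxonEntry("Euphorbiaceae", TaxonStatus.ACCEPTED,
                       accepted_name="Euphorbiaceae", rank="family",
                       family="Euphorbiaceae"),
            TaxonEntry("Macaranga/Mallotus", TaxonStatus.MULTI_MATCH,
                       family="Euphorbiaceae",
                       multi_match_members=("Macaranga", "Mallotus")),
            TaxonEntry("Ipomoea cf. batatas", TaxonStatus.CF_SPECIES,
                       accepted_name="Ipomoea batatas", rank="species",
                       genus="Ipomoea", family="Convolvulaceae"),
            TaxonEntry("Ipomoea batatas", TaxonStatus.ACCEPTED,
                       accepted_name="Ipomoea batatas", rank="species",
                       genus="Ipomoea", family="Convolvulaceae"),
            TaxonEntry("Ipomoea", TaxonStatus.ACCEPTED,
                       accepted_name="Ipomoea", rank="genus",
                       genus="Ipomoea", family="Convolvulaceae"),
            TaxonEntry("Gramineae", TaxonStatus.SYNONYM,
                       accepted_name="Poaceae", rank="family", family="Poaceae"),
            TaxonEntry("Poaceae", TaxonStatus.ACCEPTED,
                       accepted_name="Poaceae", rank="family", family="Poaceae"),
            TaxonEntry("Indeterminate", TaxonStatus.INDETERMINATE),
            TaxonEntry("Trilete spore", TaxonStatus.UNCERTAIN_ABOVE_FAMILY),
        ]
    )


def make_samples(rows):
    """rows: (site_id, age_bp, taxon, value, value_kind) tuples."""
    return pd.DataFrame(
        rows, columns=["site_id", "age_bp", "taxon", "value", "value_kind"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
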