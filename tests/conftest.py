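import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from pvarch import fixtures
from pvarch.catalog_io import GeneCatalog, GeneRecord


@pytest.fixture(scope="session")
def ddr_catalog() -> GeneCatalog:
    return fixtures.load_ddr_catalog()


@pytest.fixture(scope="session")
def sharing_table() -> pd.DataFrame:
    return fixtures.load_ancient_sharing_table()


@pytest.fixture()
def toy_catalog() -> GeneCatalog:
    """Two genes on chrom 1: GA spans [100, 200), GB nested inside at [120, 150)."""
    return GeneCatalog({
        "GA": GeneRecord("GA", ("Homologous Recombination",), [("1", 100, 200)]),
        "GB": GeneRecord("GB", ("Fanconi anemia",), [("1", 120, 150)]),
    })
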