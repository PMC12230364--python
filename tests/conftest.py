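import numpy as np
import pandas as pd
import pytest

from floristics.io import OccurrenceTable


def make_table(rows):
    """Build an OccurrenceTable from (reserve, species, genus, family,
    areal_type, endemic, cultivated) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "reserve_id",
            "species",
            "genus",
            "family",
            "areal_type",
            "endemic",
            "cultivated",
        ],
    )
    return OccurrenceTable(df)


@pytest.fixture
def toy_table():
    """2 reserves, 3 families, 5 genera, 6 species, 2 endemic species."""
    return make_table(
        [
            ("A", "Acer truncatum", "Acer", "Sapindaceae", "T01", False, False),
            ("A", "Acer mono", "Acer", "Sapindaceae", "T01", False, False),
            ("A", "Rosa rugosa", "Rosa", "Rosaceae", "T02", False, False),
            ("A", "Biondia chinensis", "Biondia", "Apocynaceae", "T03", True, False),
            ("B", "Acer truncatum", "Acer", "Sapindaceae", "T01", False, False),
            ("B", "Rubus idaeus", "Rubus", "Rosaceae", "T02", False, False),
            ("B", "Taihangia rupestris", "Taihangia", "Rosaceae", "T03", True, False),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
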