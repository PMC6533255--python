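import pandas as pd
import pytest

from ecostrategy import SynthSpec, generate_trait_table, inject_missingness
from ecostrategy.io import DIET_COLUMNS


def make_tiny_table(n=3):
    """Hand-written minimal valid table."""
    rows = []
    for i in range(n):
        diet = {c: 0.0 for c in DIET_COLUMNS}
        diet["diet_inv"] = 60.0
        diet["diet_fruit"] = 40.0
        rows.append(
            {
                "species_id": f"A{i}",
                "taxon_class": "mammal" if i % 2 == 0 else "bird",
                "body_mass": 100.0 * (i + 1),
                "litter_clutch_size": 2.0 + i,
                "habitat_breadth": 1 + i,
                "generation_length": 3.0 + i,
                **diet,
                "iucn_category": "LC",
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_df():
    return make_tiny_table()


@pytest.fixture(scope="session")
def complete_table():
    """Complete synthetic table (no missingness), moderate size."""
    return generate_trait_table(SynthSpec(n_species=400), seed=11)


@pytest.fixture(scope="session")
def missing_table():
    spec = SynthSpec(n_species=400)
    table = generate_trait_table(spec, seed=11)
    masked, truth = inject_missingness(table, spec, seed=11)
    return masked, truth


@pytest.fixture(scope="session")
def coupled_table():
    """Risk coupled to body mass: the structure extinction tests must detect."""
    spec = SynthSpec(n_species=600, risk_trait_coupling=1.5)
    return generate_trait_table(spec, seed=13)
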