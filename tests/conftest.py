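import pandas as pd
import pytest

from pulldown.quantify import TAGGED, WILDTYPE
from pulldown.simulate import (
    IdirtSimConfig,
    LabelFreeSimConfig,
    simulate_idirt,
    simulate_labelfree,
)


@pytest.fixture(scope="session")
def small_idirt():
    """60-protein I-DIRT dataset with all four interactor classes."""
    return simulate_idirt(IdirtSimConfig(n_proteins=60, seed=1))


@pytest.fixture(scope="session")
def small_idirt_fit(small_idirt):
    from pulldown import IdirtSpecificity

    peptides, bulk, _ = small_idirt
    return IdirtSpecificity(peptides, bulk).fit()


@pytest.fixture(scope="session")
def small_labelfree():
    """8-per-group label-free KO panel with default planted effects."""
    return simulate_labelfree(LabelFreeSimConfig(n_per_group=8, seed=3))


def make_oriented(rows):
    """Build an oriented peptide table from (protein, peptide, orientation,
    replicate, tagged, wildtype) tuples; condition fixed to E1."""
    return pd.DataFrame(
        [
            {
                "protein_id": p,
                "peptide_id": pep,
                "condition_id": "E1",
                "orientation": o,
                "replicate": r,
                TAGGED: t,
                WILDTYPE: w,
            }
            for (p, pep, o, r, t, w) in rows
        ]
    )


@pytest.fixture
def oriented_builder():
    return make_oriented
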