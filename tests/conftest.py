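import numpy as np
import pandas as pd
import pytest

from silacodon import synthdata
from silacodon.quantfilter import FilterConfig


@pytest.fixture
def small_config():
    return synthdata.GeneratorConfig(n_proteins=150, seed=11)


@pytest.fixture
def small_dataset(small_config):
    return synthdata.simulate_dataset(small_config)


@pytest.fixture
def default_filter():
    return FilterConfig()


def make_peptide_frame(rows):
    """rows: (peptide_id, protein_id, replicate_id, design, log2_hl, prob)."""
    return pd.DataFrame(rows, columns=["peptide_id", "protein_id",
                                       "replicate_id", "design", "log2_hl",
                                       "probability"])


@pytest.fixture
def toy_peptides():
    return make_peptide_frame([
        ("pep1", "A", "r1", 1, 0.5, 0.99),
        ("pep1", "A", "r2", -1, -0.4, 0.99),
        ("pep2", "A", "r1", 1, 0.3, 0.99),
        ("pep2", "A", "r2", -1, -0.35, 0.99),
        ("pep3", "B", "r1", 1, 1.2, 0.99),
    ])
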