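from io import StringIO

import pytest
from hypothesis import settings

from utrintron import SyntheticConfig, compute_profiles, gen_gene_models, parse_gene_table

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


EXAMPLE_ROW = "NM_1\tchr1\t+\t0\t700\t300\t650\t3\t0,200,500,\t100,400,700,\n"


@pytest.fixture
def example_model():
    """Three-exon plus-strand gene: 5'UTR intron (100,200), coding intron (400,500)."""
    return parse_gene_table(StringIO(EXAMPLE_ROW))[0]


@pytest.fixture
def example_model_minus():
    """Mirror-style minus-strand gene on the same exon scaffold."""
    row = "NM_2\tchr1\t-\t0\t700\t50\t350\t3\t0,200,500,\t100,400,700,\n"
    return parse_gene_table(StringIO(row))[0]


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic transcript collection plus its profiles."""
    cfg = SyntheticConfig(seed=42, n_genes=500, n_tissues=12)
    models = gen_gene_models(cfg)
    return cfg, models, compute_profiles(models)
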