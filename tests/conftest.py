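import hypothesis
import numpy as np
import pandas as pd
import pytest

from taxalink import CommunityConfig, CountMatrix, generate_community

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_counts(values, rows=None, samples=None) -> CountMatrix:
    values = np.asarray(values)
    rows = rows or [f"r{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=rows, columns=samples))


@pytest.fixture(scope="session")
def small_community():
    """A small but well-powered community: strong signal, no confounders."""
    config = CommunityConfig(
        n_organisms=12,
        n_samples=60,
        genes_per_organism=(20, 30),
        gene_length_range=(300, 3000),
        otus_per_organism=(1, 2),
        log_abundance_sigma=1.5,
        shotgun_depth=50_000,
        amplicon_depth=10_000,
        seed=42,
    )
    return generate_community(config)
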