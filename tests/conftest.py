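import numpy as np
import pandas as pd
import pytest

from metagraph.annotation import AbundanceMatrix
from metagraph.graphs import GraphScale, build_sample_graphs
from metagraph.synthetic import SyntheticConfig, generate_samples


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared across tests (fixed seed)."""
    config = SyntheticConfig(
        n_samples=40,
        n_species=12,
        n_functions=15,
        n_predictive_species=3,
        depth_range=(400, 800),
        seed=11,
    )
    reads, species, functions, pairs, metadata, truth = generate_samples(config)
    return {
        "config": config,
        "reads": reads,
        "species": species,
        "functions": functions,
        "pairs": pairs,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_graphs(small_cohort):
    truth = small_cohort["truth"]
    allow = [s for s, _ in truth.predictive_species] + [s for s, _ in truth.streamlined_pairs]
    central = {f for _, f in truth.streamlined_pairs}
    return build_sample_graphs(
        small_cohort["pairs"],
        small_cohort["metadata"],
        GraphScale.small(allow),
        central_carbon_set=central,
    )


@pytest.fixture()
def toy_matrix():
    data = pd.DataFrame(
        [[5, 5, 0], [1, 2, 7], [0, 0, 0]],
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
        columns=["speciesA", "speciesB", "speciesC"],
    )
    return AbundanceMatrix(data=data, feature_kind="taxon")


def assignment_frame(rows):
    """Build a read-assignment table from (read, sample, source, kind, label, length) tuples."""
    return pd.DataFrame(
        rows, columns=["read_id", "sample_id", "source", "kind", "label", "mapped_length"]
    )
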