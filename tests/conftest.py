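import numpy as np
import pandas as pd
import pytest

from fieldexpr import core_data, synthgen


@pytest.fixture(scope="session")
def default_exp():
    """A small default-shaped experiment (two accessions, 53 arrays)."""
    cfg = synthgen.SimulationConfig(n_genes=300, seed=11)
    return synthgen.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def default_design(default_exp):
    return core_data.join_design(
        default_exp.samples, default_exp.environment, default_exp.phenotypes
    )


@pytest.fixture(scope="session")
def balanced_2x2():
    """Balanced 2-accession x 2-flowering design with planted 0.4/0.4/0.2."""
    cfg = synthgen.SimulationConfig(
        n_genes=800,
        vegetative_timepoints=(4, 4),
        flowering_timepoints=4,
        bolting_days=(29, 29),
        variance_fractions={"accession": 0.4, "flowering": 0.4,
                            "environment": 0.0, "cluster": 0.0},
        null_fraction=0.0,
        drop_one_replicate=False,
        seed=5,
    )
    return synthgen.simulate_experiment(cfg)


@pytest.fixture()
def tiny_matrix():
    df = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.5]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2"],
    )
    return core_data.ExpressionMatrix(df)


def make_samples(rows):
    return core_data.SampleTable(pd.DataFrame(rows))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
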