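import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import protovar as pv
from protovar.annotate import encode_features, encoded_labels, training_frame
from protovar.datamodel import WeightedDataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_gene():
    """A moderately sized synthetic gene with a clear class signal."""
    spec = pv.GeneSimSpec(gene_id="SYNG1", n_pathogenic=80, n_benign=40,
                          seq_length=150, seed=11)
    variants, context, pdb_text = pv.simulate_gene_dataset(spec)
    return variants, context, pdb_text


@pytest.fixture(scope="session")
def small_dataset(small_gene):
    variants, context, _ = small_gene
    df = training_frame(pv.annotate_gene(variants, context))
    X, names, _ = encode_features(df)
    y = encoded_labels(df)
    return WeightedDataset(X, y, np.ones(len(y)), names)


@pytest.fixture(scope="session")
def null_gene():
    """A gene whose pathogenic and benign variants are indistinguishable."""
    effect = pv.EffectProfile().null()
    spec = pv.GeneSimSpec(gene_id="NULLG", n_pathogenic=80, n_benign=40,
                          seq_length=150, effect=effect, seed=23)
    return pv.simulate_gene_dataset(spec)
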