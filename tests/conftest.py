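import numpy as np
import pytest

from nemii.classifier import RFConfig
from nemii.disease_similarity import similarity_matrix
from nemii.evaluation import PipelineConfig
from nemii.features import FeatureConfig
from nemii.sdne import SDNEConfig
from nemii.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_data():
    """Small dense synthetic dataset for fast unit tests."""
    cfg = SyntheticConfig(m=30, n=20, t=3, n_blocks=3, p_in=0.5, p_out=0.02, seed=11)
    ds, fam, onto, truth = generate_dataset(cfg)
    SS = similarity_matrix(ds.disease_ids, onto).SS
    return ds, fam, onto, truth, SS


@pytest.fixture(scope="session")
def study_data():
    """The default-scale synthetic dataset used for pipeline-level checks."""
    ds, fam, onto, truth = generate_dataset(SyntheticConfig(seed=0))
    SS = similarity_matrix(ds.disease_ids, onto).SS
    return ds, fam, onto, truth, SS


def study_pipeline(combo: int = 5, seed: int = 0, n_trees: int = 350, **rf_kw) -> PipelineConfig:
    """Pipeline settings used for default-scale experiments."""
    return PipelineConfig(
        sdne=SDNEConfig.small_network(seed=seed),
        features=FeatureConfig.from_combination(combo),
        rf=RFConfig(n_trees=n_trees, seed=seed, **rf_kw),
    )


@pytest.fixture
def tiny_pipeline():
    """Cheap pipeline for protocol-mechanics tests (not performance)."""
    return PipelineConfig(
        sdne=SDNEConfig.small_network(d=8, epochs=150, seed=0),
        features=FeatureConfig.from_combination(5),
        rf=RFConfig(n_trees=40, seed=0),
    )
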