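import numpy as np
import pandas as pd
import pytest

from clustmmra.io_formats import ExpressionMatrix, SubtypeLabels
from clustmmra.pipeline import PipelineConfig
from clustmmra.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_matrix(values, kind="mrna", feature_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{feature_prefix}{i}" for i in range(values.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(df, kind)


def small_generator_config(**overrides):
    """Reduced-scale study conditions for fast unit-level simulations."""
    base = dict(
        n_samples=120,
        n_mirnas=40,
        n_clusters=8,
        n_genes=600,
        signature_size=40,
        planted_target_set_size=60,
        background_targets_per_mirna=30,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def small_pipeline_config(**overrides):
    base = dict(n_rand=300, mi_n_pairs=20, mi_n_perm=40, seed=0)
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (200 samples, 4 subtypes, 30 clusters,
    2000 genes, planted effect 1.2), generated once per session."""
    return generate_dataset(GeneratorConfig(), 7)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_generator_config(), 11)


@pytest.fixture
def four_group_labels():
    assignments = {}
    i = 0
    for subtype, n in [("A", 5), ("B", 5), ("C", 5), ("D", 5)]:
        for _ in range(n):
            assignments[f"s{i}"] = subtype
            i += 1
    return SubtypeLabels(assignments)
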