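import numpy as np
import pytest

from brickplot import (
    ClusterExpressionTable,
    SyntheticSpec,
    ThresholdConfig,
    TransformState,
    apply_zero_threshold,
    build_layout,
    generate_table,
)


def random_raw_table(rng: np.random.Generator, n_clusters: int = 6, n_markers: int = 8):
    """A well-behaved random raw-count table (positive, non-degenerate)."""
    values = rng.gamma(shape=2.0, scale=20.0, size=(n_clusters, n_markers))
    return ClusterExpressionTable(
        marker_names=tuple(f"M{j}" for j in range(n_markers)),
        cluster_ids=tuple(f"C{i}" for i in range(n_clusters)),
        values=values,
        transform_state=TransformState.RAW_COUNTS,
    )


def random_arcsinh_table(rng: np.random.Generator, n_clusters: int = 6, n_markers: int = 8):
    values = rng.uniform(0.0, 5.0, size=(n_clusters, n_markers))
    return ClusterExpressionTable(
        marker_names=tuple(f"M{j}" for j in range(n_markers)),
        cluster_ids=tuple(f"C{i}" for i in range(n_clusters)),
        values=values,
        transform_state=TransformState.ARCSINH,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """4 clusters x 5 markers, arcsinh scale, values spanning the cutoff."""
    values = np.array(
        [
            [0.5, 2.0, 3.0, 1.2, 0.1],
            [1.5, 0.8, 2.5, 2.2, 0.2],
            [2.5, 1.1, 0.9, 3.0, 0.3],
            [3.0, 1.9, 1.0, 0.4, 0.2],
        ]
    )
    return ClusterExpressionTable(
        marker_names=("CD3", "CD4", "CD8", "CD25", "NEG"),
        cluster_ids=("A", "B", "C", "D"),
        values=values,
        transform_state=TransformState.ARCSINH,
    )


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default 3-block synthetic dataset (15 block markers + 2 negatives)."""
    return generate_table(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def synthetic_layout(synthetic_dataset):
    return build_layout(synthetic_dataset.table, ThresholdConfig(), seed=11)


@pytest.fixture(scope="session")
def synthetic_thresholded(synthetic_dataset):
    return apply_zero_threshold(synthetic_dataset.table, ThresholdConfig())


@pytest.fixture
def table_csv(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(
        "cluster,CD3,CD4,CD8,CD25,FOXP3\n"
        "c1,10,220,3,40,5\n"
        "c2,150,4,200,6,2\n"
        "c3,160,210,5,300,80\n"
        "c4,8,7,9,10,11\n"
    )
    return path
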