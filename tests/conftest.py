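import numpy as np
import pandas as pd
import pytest

from roilogit import (
    AtlasParcellation,
    CohortSpec,
    FeatureTable,
    ToyAtlasSpec,
    generate_feature_table,
    generate_toy_atlas,
)


@pytest.fixture
def toy_atlas() -> AtlasParcellation:
    return generate_toy_atlas(ToyAtlasSpec(grid_shape=(8, 8, 8), n_regions=4, voxels_per_region=20))


@pytest.fixture
def small_table() -> FeatureTable:
    spec = CohortSpec(
        n_per_group=[20, 15],
        n_regions=6,
        baseline_mean=15.0,
        dispersion=4.0,
        effect_regions={1: [8.0, 0.0]},
        seed=11,
    )
    return generate_feature_table(spec)


@pytest.fixture
def balanced_table() -> FeatureTable:
    spec = CohortSpec(
        n_per_group=[25, 25],
        n_regions=5,
        baseline_mean=20.0,
        dispersion=5.0,
        seed=5,
    )
    return generate_feature_table(spec)


def make_table(counts: np.ndarray, groups, region_names=None, subgroups=None) -> FeatureTable:
    """Hand-build a FeatureTable from a raw count matrix and labels."""
    counts = np.asarray(counts)
    n, k = counts.shape
    names = region_names or [f"Region_{i:03d}" for i in range(1, k + 1)]
    ids = [f"sub-{i:03d}" for i in range(1, n + 1)]
    meta = pd.DataFrame(
        {
            "group": list(groups),
            "subgroup": list(subgroups) if subgroups is not None else ["none"] * n,
            "age": np.linspace(30, 60, n),
            "sex": [i % 2 for i in range(n)],
            "bmi": np.linspace(22, 33, n),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    return FeatureTable(pd.DataFrame(counts, index=meta.index, columns=names), meta)
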