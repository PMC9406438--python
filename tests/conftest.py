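import numpy as np
import pytest

from omicsurv import SimConfig, generate_cohort
from omicsurv.cluster import cluster_scores, fit_pca
from omicsurv.reduction import (
    apply_layer_filters,
    build_integration_table,
    correlation_filter,
    map_segments_to_genes,
)


def small_config(seed: int = 42, **overrides) -> SimConfig:
    defaults = dict(
        n_samples=120,
        n_genes_per_layer=60,
        n_planted_per_layer=4,
        effect_size=2.5,
        n_cna_altered_blocks=2,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Reduced integration table + PCA + cluster labels for the small cohort."""
    bundle, truth = small_cohort
    cna = map_segments_to_genes(bundle.segments, bundle.annotation, bundle.samples)
    c, m, e = apply_layer_filters(cna, bundle.methylation, bundle.expression)
    table = correlation_filter(build_integration_table(c, m, e))
    model = fit_pca(table, n_components=10)
    assignment = cluster_scores(model, k=2, seed=0)
    return table, model, assignment, truth
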