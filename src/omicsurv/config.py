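"""Configuration dataclasses for the simulator, the filters and the pipeline.

All thresholds carry the pipeline defaults: copy-number alteration frequency
0.30, methylation level 0.3 / frequency 0.40, expression null fraction 0.50,
correlation threshold 0.8, ten principal components, k = 2 clusters, loading
percentile 90, 5000 importance-bootstrap replicates, 1000 stability-selection
runs, nine signature genes, 5000 Monte-Carlo iterations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from omicsurv.exceptions import ConfigError

LAYERS = ("cna", "methylation", "expression")


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass
class SimConfig:
    """Parameters of the synthetic linked-cohort generator.

    The defaults mirror the cohort the pipeline was designed for: 410
    patients, a 240/410 split between a longer- and a shorter-surviving
    subgroup, per-cluster median survival of 2900 vs 2064 days, and three
    omics layers over a shared 200-gene universe with five planted
    subgroup-informative genes per layer.

    Parameters
    ----------
    n_samples : int
        Cohort size.
    n_genes_per_layer : int
        Number of genes measured in each layer (shared gene universe).
    n_planted_per_layer : int
        Genes per layer carrying the between-cluster shift.
    cluster_fraction : float
        Fraction of samples assigned to cluster 1 (the longer-surviving,
        larger cluster); cluster sizes are floor(n * fraction) / remainder.
    effect_size : float
        Standardized mean shift of planted features between clusters, applied
        on the latent (logit / log) scale for methylation and expression and
        scaled by ``cna_shift_per_unit_effect`` for copy number.
    censoring_rate : float
        Expected fraction of censored samples under independent uniform
        administrative censoring.
    median_survival_days : (float, float)
        Median survival of clusters 1 and 2; exponential within cluster.
    seed : int
        Global seed; every stream is derived from it.
    construct_corr : float
        Latent correlation within a planted construct or a correlated noise
        block; must exceed the pipeline's 0.8 correlation threshold for the
        construct to survive filtering.
    noise_block_fraction : float
        Fraction of non-planted methylation/expression genes arranged in
        correlated blocks (co-regulated noise constructs).
    noise_block_size : int
        Genes per correlated noise block.
    metastasis_rate : float
        Bernoulli rate of the metastasis/relapse flag, independent of cluster.
    cna_shift_per_unit_effect : float
        log2-ratio loss per unit effect size planted in cluster 2.
    cna_noise_sd : float
        Standard deviation of segment-level log2 noise.
    n_cna_altered_blocks : int
        Number of commonly-altered (cluster-independent) copy-number regions.
    """

    n_samples: int = 410
    n_genes_per_layer: int = 200
    n_planted_per_layer: int = 5
    cluster_fraction: float = 240.0 / 410.0
    effect_size: float = 2.0
    censoring_rate: float = 0.4
    median_survival_days: tuple[float, float] = (2900.0, 2064.0)
    seed: int = 0
    construct_corr: float = 0.9
    noise_block_fraction: float = 0.3
    noise_block_size: int = 3
    metastasis_rate: float = 0.25
    cna_shift_per_unit_effect: float = 0.15
    cna_noise_sd: float = 0.05
    n_cna_altered_blocks: int = 4

    def __post_init__(self) -> None:
        self.median_survival_days = tuple(self.median_survival_days)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        _require(self.n_samples >= 4, "n_samples", "must be at least 4")
        _require(self.n_genes_per_layer >= 1, "n_genes_per_layer", "must be positive")
        _require(
            0 <= self.n_planted_per_layer <= self.n_genes_per_layer,
            "n_planted_per_layer",
            "must be between 0 and n_genes_per_layer",
        )
        _require(0.0 < self.cluster_fraction < 1.0, "cluster_fraction", "must lie in (0, 1)")
        _require(self.effect_size >= 0.0, "effect_size", "must be non-negative")
        _require(0.0 <= self.censoring_rate < 1.0, "censoring_rate", "must lie in [0, 1)")
        _require(
            len(self.median_survival_days) == 2
            and all(m > 0 for m in self.median_survival_days),
            "median_survival_days",
            "must be a pair of positive day counts",
        )
        _require(0.0 < self.construct_corr < 1.0, "construct_corr", "must lie in (0, 1)")
        _require(
            0.0 <= self.noise_block_fraction <= 1.0,
            "noise_block_fraction",
            "must lie in [0, 1]",
        )
        _require(self.noise_block_size >= 2, "noise_block_size", "must be at least 2")
        _require(0.0 <= self.metastasis_rate <= 1.0, "metastasis_rate", "must lie in [0, 1]")
        _require(self.cna_noise_sd > 0, "cna_noise_sd", "must be positive")
        _require(self.n_cna_altered_blocks >= 0, "n_cna_altered_blocks", "must be >= 0")


@dataclass
class FilterParams:
    """Per-layer alteration-frequency filter thresholds.

    A CNA gene is kept when at least ``cna_freq`` of samples are altered
    (|log2 ratio| >= ``cna_call_threshold``); a methylation gene when at least
    ``meth_freq`` of samples have beta >= ``meth_level`` (or deviate from the
    cohort median by that much with ``meth_mode="deviation"``); an expression
    gene when at most ``expr_null_max`` of its values are null (missing or
    exactly zero).
    """

    cna_freq: float = 0.30
    cna_call_threshold: float = 0.2
    meth_level: float = 0.3
    meth_freq: float = 0.40
    meth_mode: str = "high"
    expr_null_max: float = 0.50

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("cna_freq", "meth_freq", "expr_null_max"):
            _require(0.0 <= getattr(self, name) <= 1.0, name, "must lie in [0, 1]")
        _require(self.cna_call_threshold > 0, "cna_call_threshold", "must be positive")
        _require(0.0 <= self.meth_level <= 1.0, "meth_level", "must lie in [0, 1]")
        _require(self.meth_mode in ("high", "deviation"), "meth_mode", "must be 'high' or 'deviation'")


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs, serializable to/from YAML."""

    simulate: SimConfig | None = field(default_factory=SimConfig)
    paths: dict[str, str] | None = None
    filters: FilterParams = field(default_factory=FilterParams)
    r_threshold: float = 0.8
    standardize: bool = True
    n_pcs: int = 10
    k: int = 2
    kmeans_n_init: int = 25
    loading_percentile: float = 90.0
    gini_n_boot: int = 5000
    gini_mode: str = "quantile"
    gini_threshold: float = 10000.0
    gini_keep_fraction: float = 0.15
    gini_n_trees: int = 25
    lasso_n_runs: int = 1000
    n_select: int = 9
    mc_n_iter: int = 5000
    test_fraction: float = 0.127
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimConfig(**self.simulate)
        if isinstance(self.filters, dict):
            self.filters = FilterParams(**self.filters)
        self.validate()

    def validate(self) -> None:
        _require(
            self.simulate is not None or self.paths is not None,
            "simulate/paths",
            "either a synthetic config or input paths must be given",
        )
        self.filters.validate()
        if self.simulate is not None:
            self.simulate.validate()
        _require(0.0 < self.r_threshold < 1.0, "r_threshold", "must lie in (0, 1)")
        _require(self.n_pcs >= 1, "n_pcs", "must be positive")
        _require(self.k >= 2, "k", "must be at least 2")
        _require(self.kmeans_n_init >= 1, "kmeans_n_init", "must be positive")
        _require(0.0 < self.loading_percentile < 100.0, "loading_percentile", "must lie in (0, 100)")
        _require(self.gini_n_boot >= 1, "gini_n_boot", "must be positive")
        _require(self.gini_mode in ("quantile", "absolute"), "gini_mode", "must be 'quantile' or 'absolute'")
        _require(0.0 < self.gini_keep_fraction <= 1.0, "gini_keep_fraction", "must lie in (0, 1]")
        _require(self.gini_n_trees >= 1, "gini_n_trees", "must be positive")
        _require(self.lasso_n_runs >= 1, "lasso_n_runs", "must be positive")
        _require(self.n_select >= 1, "n_select", "must be positive")
        _require(self.mc_n_iter >= 1, "mc_n_iter", "must be positive")
        _require(0.0 < self.test_fraction < 1.0, "test_fraction", "must lie in (0, 1)")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d.get("simulate") is not None:
            d["simulate"]["median_survival_days"] = list(
                d["simulate"]["median_survival_days"]
            )
        return d

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "PipelineConfig":
        """Load from a YAML file path or a YAML string."""
        try:
            with open(source, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        except (OSError, ValueError):
            data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ConfigError("config: YAML document must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)
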