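"""Layer reduction: segment-to-gene mapping, alteration-frequency filters,
integration-table assembly and the Pearson-correlation construct filter.

The reduction stage turns three raw layers into one samples x features
integration table keeping only features that (a) are altered frequently
enough within their layer and (b) belong to a correlated construct —
features without a partner at |r| > 0.8 are discarded as non-constructs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from omicsurv.config import FilterParams
from omicsurv.exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class IntegrationTable:
    """Samples x features matrix with per-feature layer tags and provenance.

    ``data`` columns are ``"<gene>|<layer>"`` ids; ``features`` maps each id
    to (gene, layer); ``provenance`` records feature counts per stage.
    """

    data: pd.DataFrame
    features: pd.DataFrame  # index = feature id, columns = gene, layer
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def layer_counts(self) -> dict[str, int]:
        return self.features["layer"].value_counts().to_dict()

    def record(self, stage: str) -> None:
        self.provenance.append(
            {"stage": stage, "n_features": self.n_features, **self.layer_counts()}
        )

    def subset(self, feature_ids: list[str]) -> "IntegrationTable":
        return IntegrationTable(
            data=self.data[feature_ids],
            features=self.features.loc[feature_ids],
            provenance=list(self.provenance),
        )


def feature_id(gene: str, layer: str) -> str:
    return f"{gene}|{layer}"


# ---------------------------------------------------------------------------
# segment -> gene mapping

def map_segments_to_genes(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.Index | None = None,
) -> pd.DataFrame:
    """Aggregate per-sample segment log2 ratios to gene level.

    A gene's value in a sample is the overlap-length-weighted mean of the
    log2 ratios of all segments overlapping the gene interval (1-based,
    closed coordinates). Genes with no overlapping segment in a sample are
    missing (NaN) for that sample. Segments on chromosomes absent from the
    annotation are ignored with a warning.
    """
    if annotation.empty:
        raise ValidationError("map_segments_to_genes: empty annotation")
    if samples is None:
        samples = pd.Index(pd.unique(segments["sample"]), name="sample")
    known_chroms = set(annotation["chrom"])
    unknown = sorted(set(segments["chrom"]) - known_chroms)
    if unknown:
        warnings.warn(
            f"map_segments_to_genes: ignoring segments on chromosomes {unknown} "
            "absent from the annotation",
            stacklevel=2,
        )
        segments = segments[segments["chrom"].isin(known_chroms)]

    genes = annotation["gene"].to_numpy()
    out = np.full((len(samples), len(genes)), np.nan)
    sample_pos = {s: i for i, s in enumerate(samples)}

    for chrom, ann_chunk in annotation.groupby("chrom", sort=False):
        g_start = ann_chunk["start"].to_numpy(np.int64)
        g_end = ann_chunk["end"].to_numpy(np.int64)
        g_idx = ann_chunk.index.to_numpy()
        seg_chunk = segments[segments["chrom"] == chrom]
        for sample, seg in seg_chunk.groupby("sample", sort=False):
            if sample not in sample_pos:
                continue
            s_start = seg["start"].to_numpy(np.int64)
            s_end = seg["end"].to_numpy(np.int64)
            s_val = seg["log2_ratio"].to_numpy(float)
            # closed-interval overlap length, genes x segments
            ov = (
                np.minimum(g_end[:, None], s_end[None, :])
                - np.maximum(g_start[:, None], s_start[None, :])
                + 1
            ).clip(min=0)
            weight = ov.sum(axis=1)
            hit = weight > 0
            row = sample_pos[sample]
            vals = (ov[hit] * s_val[None, :]).sum(axis=1) / weight[hit]
            out[row, g_idx[hit]] = vals
    return pd.DataFrame(out, index=samples, columns=genes)


# ---------------------------------------------------------------------------
# per-layer frequency filters

def apply_layer_filters(
    cna: pd.DataFrame,
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply the per-layer alteration-frequency filters.

    * CNA: keep a gene iff the fraction of samples with |log2| >=
      ``cna_call_threshold`` is >= ``cna_freq`` (missing = not altered).
    * Methylation: keep iff the fraction of samples with beta >=
      ``meth_level`` is >= ``meth_freq`` (``meth_mode="deviation"`` instead
      calls samples with |beta - cohort median| >= ``meth_level`` altered).
    * Expression: keep iff the fraction of null values (missing or exactly
      zero) is <= ``expr_null_max``.
    """
    params = params or FilterParams()
    params.validate()

    altered = cna.abs() >= params.cna_call_threshold
    cna_keep = altered.fillna(False).mean(axis=0) >= params.cna_freq

    if params.meth_mode == "high":
        m_altered = methylation >= params.meth_level
    else:
        m_altered = (methylation - methylation.median(axis=0)).abs() >= params.meth_level
    meth_keep = m_altered.mean(axis=0) >= params.meth_freq

    null_frac = (expression.isna() | (expression == 0)).mean(axis=0)
    expr_keep = null_frac <= params.expr_null_max

    for layer, keep, total in (
        ("cna", cna_keep, cna.shape[1]),
        ("methylation", meth_keep, methylation.shape[1]),
        ("expression", expr_keep, expression.shape[1]),
    ):
        logger.info("layer filter %s: kept %d of %d genes", layer, int(keep.sum()), total)
    return (
        cna.loc[:, cna_keep],
        methylation.loc[:, meth_keep],
        expression.loc[:, expr_keep],
    )


# ---------------------------------------------------------------------------
# integration table

def build_integration_table(
    cna: pd.DataFrame,
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    standardize: bool = True,
) -> IntegrationTable:
    """Concatenate filtered layers into one table keyed by (gene, layer).

    Missing CNA values are imputed as 0 (copy-neutral: absence of a segment
    call conventionally means no alteration); missing expression values are
    imputed by the gene median. Features are z-standardized by default so
    downstream PCA is not dominated by expression scale; zero-variance
    features are dropped with a warning.
    """
    layers = [("cna", cna), ("methylation", methylation), ("expression", expression)]
    non_empty = [(name, frame) for name, frame in layers if frame.shape[1] > 0]
    for name, frame in layers:
        if frame.shape[1] == 0:
            warnings.warn(f"build_integration_table: layer {name!r} is empty, omitted", stacklevel=2)
    if not non_empty:
        raise ValidationError("build_integration_table: all layers empty")
    index = non_empty[0][1].index
    for name, frame in non_empty[1:]:
        if not frame.index.equals(index):
            raise ValidationError("build_integration_table: layers do not share a sample set")
    if len(index) == 0:
        raise ValidationError("build_integration_table: zero shared samples")

    blocks, feat_rows = [], []
    for name, frame in non_empty:
        block = frame.copy()
        if name == "cna":
            block = block.fillna(0.0)
        elif name == "expression":
            block = block.fillna(block.median(axis=0))
        block.columns = [feature_id(g, name) for g in frame.columns]
        blocks.append(block)
        feat_rows += [(feature_id(g, name), g, name) for g in frame.columns]

    data = pd.concat(blocks, axis=1)
    features = pd.DataFrame(
        feat_rows, columns=["feature", "gene", "layer"]
    ).set_index("feature")

    if standardize:
        sd = data.std(axis=0, ddof=0)
        constant = sd[sd == 0].index
        if len(constant):
            warnings.warn(
                f"build_integration_table: dropping {len(constant)} zero-variance feature(s)",
                stacklevel=2,
            )
            data = data.drop(columns=constant)
            features = features.drop(index=constant)
            sd = sd.drop(index=constant)
        data = (data - data.mean(axis=0)) / sd

    table = IntegrationTable(data=data, features=features)
    table.record("integration")
    return table


# ---------------------------------------------------------------------------
# correlation construct filter

class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Keep features that correlate with at least one *other* feature.

    A feature survives iff some other feature has |Pearson r| >
    ``threshold`` with it (absolute value: anti-correlated constructs are
    equally informative). Correlations are computed blockwise on z-scored
    data so memory stays bounded for tens of thousands of features.
    Constant features correlate with nothing and are dropped with a warning.

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_features,)
        Mask of surviving features after :meth:`fit`.
    """

    def __init__(self, threshold: float = 0.8, block_size: int = 2048):
        self.threshold = threshold
        self.block_size = block_size

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p < 2:
            raise ValidationError("CorrelationFilter: need at least 2 features")
        sd = X.std(axis=0, ddof=0)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"CorrelationFilter: {int(constant.sum())} constant feature(s) "
                "treated as uncorrelated and dropped",
                stacklevel=2,
            )
        safe_sd = np.where(constant, 1.0, sd)
        Z = (X - X.mean(axis=0)) / safe_sd
        Z[:, constant] = 0.0

        support = np.zeros(p, dtype=bool)
        for lo in range(0, p, self.block_size):
            hi = min(lo + self.block_size, p)
            corr = Z[:, lo:hi].T @ Z / n  # block x all correlations
            np.abs(corr, out=corr)
            for j in range(lo, hi):
                corr[j - lo, j] = 0.0  # exclude self
            support[lo:hi] = (corr > self.threshold).any(axis=1)
        support &= ~constant
        self.support_ = support
        self.n_features_in_ = p
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]


def correlation_filter(table: IntegrationTable, r_threshold: float = 0.8) -> IntegrationTable:
    """Apply the construct filter to an integration table.

    Idempotent: every kept feature's strong partner is kept too (the
    relation is symmetric), so a second pass changes nothing.
    """
    filt = CorrelationFilter(threshold=r_threshold)
    filt.fit(table.data.to_numpy())
    kept = table.data.columns[filt.get_support()].tolist()
    dropped = table.n_features - len(kept)
    logger.info("correlation filter: kept %d features, dropped %d", len(kept), dropped)
    out = table.subset(kept)
    out.record("correlation_filter")
    return out
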