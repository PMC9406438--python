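"""Three-stage signature selection: PC-loading percentile + exclusivity,
bootstrapped Gini-importance filtering, and LASSO inclusion-frequency
stability selection.

Stage 1 keeps features whose |loading| reaches the per-PC 90th percentile
in exactly one of the first ten PCs. Stage 2 accumulates random-forest
mean-decrease-in-Gini importance over bootstrap replicates and keeps either
the features above an absolute cumulative-importance threshold or the top
quantile (the scale-free default). Stage 3 refits an L1-penalized logistic
model on bootstrap resamples and ranks features by the fraction of runs in
which they receive a nonzero coefficient, returning the ``n_select`` most
frequent as the signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.utils.validation import check_is_fitted

from omicsurv.cluster import PCAModel, fit_pca
from omicsurv.exceptions import ValidationError
from omicsurv.reduction import IntegrationTable

logger = logging.getLogger(__name__)


@dataclass
class SelectionTrace:
    """Record of one selection stage: what entered, what survived, and the
    per-feature diagnostic that drove the decision."""

    stage: str
    entering: list[str]
    surviving: list[str]
    diagnostics: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        if not set(self.surviving) <= set(self.entering):
            raise ValidationError(f"{self.stage}: surviving features not a subset of entering")


@dataclass
class Signature:
    """Final ordered signature: (gene, layer, rank, inclusion frequency)."""

    entries: pd.DataFrame  # index: feature id; columns: gene, layer, rank, frequency
    trace: SelectionTrace | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def feature_ids(self) -> list[str]:
        return self.entries.index.tolist()

    def to_dict(self) -> dict:
        return {
            fid: {
                "gene": row["gene"],
                "layer": row["layer"],
                "rank": int(row["rank"]),
                "frequency": float(row["frequency"]),
            }
            for fid, row in self.entries.iterrows()
        }


def _split_feature_id(fid: str) -> tuple[str, str]:
    gene, _, layer = fid.rpartition("|")
    return (gene, layer) if gene else (fid, "")


# ---------------------------------------------------------------------------
# stage 1: PC loadings

class PCLoadingSelector(BaseEstimator, SelectorMixin):
    """Unsupervised selector: per-PC |loading| percentile + PC exclusivity.

    ``fit(X)`` runs a PCA with ``n_components`` components; a feature is
    marked in a PC when its |loading| is at or above that PC's
    ``percentile``-th percentile, and kept iff marked in exactly one PC.
    Invariant to feature order and to global sign flips of any PC.
    """

    def __init__(self, n_components: int = 10, percentile: float = 90.0):
        self.n_components = n_components
        self.percentile = percentile

    def fit(self, X, y=None):
        frame = X.data if isinstance(X, IntegrationTable) else pd.DataFrame(X)
        model = fit_pca(frame, n_components=self.n_components)
        marked = _mark_loadings(model, self.percentile)
        self.support_ = (marked.sum(axis=1) == 1).to_numpy()
        self.marked_ = marked
        self.pca_model_ = model
        self.n_features_in_ = frame.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def _mark_loadings(model: PCAModel, percentile: float) -> pd.DataFrame:
    absload = model.loadings.abs()
    thresholds = absload.quantile(percentile / 100.0, axis=0)
    return absload.ge(thresholds, axis=1)


def select_by_loadings(model: PCAModel, percentile: float = 90.0) -> SelectionTrace:
    """Keep features in the top |loading| decile of exactly one PC."""
    if model.n_components < 2:
        raise ValidationError("select_by_loadings: model needs at least 2 components")
    marked = _mark_loadings(model, percentile)
    n_marked = marked.sum(axis=1)
    surviving = marked.index[n_marked == 1].tolist()
    diagnostics = pd.DataFrame(
        {
            "n_pcs_marked": n_marked,
            "max_abs_loading": model.loadings.abs().max(axis=1),
        }
    )
    trace = SelectionTrace(
        stage="loadings",
        entering=marked.index.tolist(),
        surviving=surviving,
        diagnostics=diagnostics,
    )
    logger.info("loading selection: %d of %d features", len(surviving), len(marked))
    return trace


# ---------------------------------------------------------------------------
# stage 2: bootstrapped Gini importance

class GiniImportanceSelector(BaseEstimator, SelectorMixin):
    """Cumulative random-forest Gini importance over bootstrap replicates.

    Each replicate resamples rows with replacement and fits a random
    forest; each feature's mean-decrease-in-Gini importance is summed over
    replicates. ``mode="absolute"`` keeps features with cumulative
    importance >= ``threshold`` (the importance scale is bound to
    n_boot x trees x data scale); ``mode="quantile"`` — the scale-free
    default — keeps the top ``keep_fraction`` of features.
    """

    def __init__(
        self,
        n_boot: int = 5000,
        mode: str = "quantile",
        threshold: float = 10000.0,
        keep_fraction: float = 0.15,
        n_trees: int = 25,
        random_state: int | None = None,
    ):
        self.n_boot = n_boot
        self.mode = mode
        self.threshold = threshold
        self.keep_fraction = keep_fraction
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] < 2:
            raise ValidationError("GiniImportanceSelector: need at least 2 features")
        if len(np.unique(y)) < 2:
            raise ValidationError("GiniImportanceSelector: labels contain a single class")
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        cumulative = np.zeros(X.shape[1])
        for _ in range(self.n_boot):
            while True:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(y[idx])) == 2:
                    break
            rf = RandomForestClassifier(
                n_estimators=self.n_trees,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[idx], y[idx])
            cumulative += rf.feature_importances_
        self.cumulative_importance_ = cumulative
        if self.mode == "absolute":
            support = cumulative >= self.threshold
            if not support.any():
                warnings.warn(
                    "GiniImportanceSelector: threshold above the maximum cumulative "
                    "importance; empty survivor set",
                    stacklevel=2,
                )
        elif self.mode == "quantile":
            n_keep = max(1, int(round(self.keep_fraction * X.shape[1])))
            order = np.argsort(-cumulative, kind="stable")
            support = np.zeros(X.shape[1], dtype=bool)
            support[order[:n_keep]] = True
        else:
            raise ValidationError(f"GiniImportanceSelector: unknown mode {self.mode!r}")
        self.support_ = support
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def gini_bootstrap_filter(
    table,
    labels,
    n_boot: int = 5000,
    mode: str = "quantile",
    importance_threshold: float = 10000.0,
    keep_fraction: float = 0.15,
    n_trees: int = 25,
    seed: int | None = None,
) -> SelectionTrace:
    """Bootstrap Gini-importance filter over an integration table or frame."""
    frame = table.data if isinstance(table, IntegrationTable) else pd.DataFrame(table)
    sel = GiniImportanceSelector(
        n_boot=n_boot,
        mode=mode,
        threshold=importance_threshold,
        keep_fraction=keep_fraction,
        n_trees=n_trees,
        random_state=seed,
    )
    sel.fit(frame.to_numpy(), np.asarray(labels))
    surviving = frame.columns[sel.support_].tolist()
    diagnostics = pd.DataFrame(
        {"cumulative_importance": sel.cumulative_importance_}, index=frame.columns
    )
    logger.info("gini filter: %d of %d features", len(surviving), frame.shape[1])
    return SelectionTrace(
        stage="gini",
        entering=frame.columns.tolist(),
        surviving=surviving,
        diagnostics=diagnostics,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stage 3: LASSO stability selection

class LassoStabilitySelector(BaseEstimator, SelectorMixin):
    """L1-logistic stability selection by bootstrap inclusion frequency.

    Each run bootstrap-resamples the samples (redrawing resamples that lose
    a class, counted in ``n_redraws_``), fits an L1-penalized logistic model
    with the penalty chosen by internal cross-validation, and records which
    features receive nonzero coefficients. The ``n_select`` most frequently
    included features form the signature; ties at the cut rank are broken
    by higher mean |coefficient| across runs, then lexicographically.

    Two details keep the null behavior honest. CV folds are split by
    *original sample identity*, never by bootstrap row: a duplicated sample
    appearing in both train and test folds lets overfit penalties win on
    pure noise. And the penalty follows the one-standard-error rule (the
    strongest penalty whose CV score is within one SE of the best), the
    sparse choice standard in stability selection.
    """

    def __init__(
        self,
        n_runs: int = 1000,
        n_select: int = 9,
        Cs: int = 8,
        cv: int = 3,
        random_state: int | None = None,
    ):
        self.n_runs = n_runs
        self.n_select = n_select
        self.Cs = Cs
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) != 2:
            raise ValidationError("LassoStabilitySelector: binary labels required")
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        inclusion = np.zeros(p)
        coef_abs_sum = np.zeros(p)
        redraws = 0
        for _ in range(self.n_runs):
            while True:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(y[idx])) == 2:
                    break
                redraws += 1
            run_seed = int(rng.integers(0, 2**31 - 1))
            c_1se = self._choose_penalty(X, y, idx, rng)
            model = LogisticRegression(
                penalty="l1", solver="liblinear", C=c_1se,
                max_iter=200, random_state=run_seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[idx], y[idx])
            coef = model.coef_.ravel()
            nonzero = coef != 0
            inclusion += nonzero
            coef_abs_sum += np.abs(coef)
        if redraws:
            logger.info("lasso stability: %d degenerate resamples redrawn", redraws)
        self.n_redraws_ = redraws
        self.inclusion_frequency_ = inclusion / self.n_runs
        self.mean_abs_coef_ = coef_abs_sum / self.n_runs
        order = sorted(
            range(p),
            key=lambda j: (-self.inclusion_frequency_[j], -self.mean_abs_coef_[j], j),
        )
        selected = order[: self.n_select]
        support = np.zeros(p, dtype=bool)
        support[selected] = True
        self.support_ = support
        self.ranking_ = order
        self.n_features_in_ = p
        return self

    def _choose_penalty(self, X, y, idx, rng) -> float:
        """Group-aware CV over the C grid, one-SE rule (strongest penalty
        within one SE of the best CV accuracy)."""
        cs = np.logspace(-2, 2, self.Cs) if np.isscalar(self.Cs) else np.asarray(self.Cs)
        uniq = np.unique(idx)
        perm = rng.permutation(uniq)
        folds = np.array_split(perm, self.cv)
        scores = np.full((self.cv, len(cs)), np.nan)
        for f, test_groups in enumerate(folds):
            test_mask = np.isin(idx, test_groups)
            tr, te = idx[~test_mask], idx[test_mask]
            if len(np.unique(y[tr])) < 2 or len(te) == 0:
                continue
            for ci, c in enumerate(cs):
                m = LogisticRegression(
                    penalty="l1", solver="liblinear", C=c, max_iter=200,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(X[tr], y[tr])
                scores[f, ci] = m.score(X[te], y[te])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean = np.nanmean(scores, axis=0)
            n_ok = np.sum(~np.isnan(scores), axis=0)
            se = np.nanstd(scores, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
        if np.isnan(mean).all():
            return 1.0
        best = int(np.nanargmax(mean))
        eligible = np.flatnonzero(mean >= mean[best] - (se[best] if np.isfinite(se[best]) else 0.0))
        return float(cs[eligible[0]])  # ascending grid: first = strongest penalty

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def lasso_stability_select(
    table,
    labels,
    n_runs: int = 1000,
    n_select: int = 9,
    seed: int | None = None,
    feature_names: list[str] | None = None,
) -> Signature:
    """Stability selection over an integration table or frame; returns the
    ``n_select`` most frequently included features ranked by frequency."""
    frame = table.data if isinstance(table, IntegrationTable) else pd.DataFrame(table)
    frame = frame.copy()
    frame.columns = [str(c) for c in (feature_names if feature_names is not None else frame.columns)]
    sel = LassoStabilitySelector(n_runs=n_runs, n_select=n_select, random_state=seed)
    sel.fit(frame.to_numpy(), np.asarray(labels))

    # tie-break ordering already applied inside the selector
    chosen = [frame.columns[j] for j in sel.ranking_[:n_select]]
    rows = []
    for rank, fid in enumerate(chosen, start=1):
        gene, layer = _split_feature_id(str(fid))
        j = frame.columns.get_loc(fid)
        rows.append((fid, gene, layer, rank, sel.inclusion_frequency_[j]))
    entries = pd.DataFrame(
        rows, columns=["feature", "gene", "layer", "rank", "frequency"]
    ).set_index("feature")
    diagnostics = pd.DataFrame(
        {
            "inclusion_frequency": sel.inclusion_frequency_,
            "mean_abs_coef": sel.mean_abs_coef_,
        },
        index=frame.columns,
    )
    trace = SelectionTrace(
        stage="lasso",
        entering=frame.columns.tolist(),
        surviving=[str(c) for c in chosen],
        diagnostics=diagnostics,
        seed=seed,
    )
    return Signature(entries=entries, trace=trace)


# ---------------------------------------------------------------------------
# full cascade

def select_signature(
    table: IntegrationTable,
    labels,
    model: PCAModel | None = None,
    loading_percentile: float = 90.0,
    gini_n_boot: int = 5000,
    gini_mode: str = "quantile",
    gini_threshold: float = 10000.0,
    gini_keep_fraction: float = 0.15,
    gini_n_trees: int = 25,
    lasso_n_runs: int = 1000,
    n_select: int = 9,
    seed: int | None = None,
) -> tuple[Signature, list[SelectionTrace]]:
    """Run the full three-stage cascade; the per-stage survivor counts are
    strictly filtering (|loadings| >= |gini| >= |signature|)."""
    if model is None:
        model = fit_pca(table.data, n_components=10)
    seeds = np.random.SeedSequence(seed).spawn(2) if seed is not None else [None, None]
    gini_seed = int(np.random.default_rng(seeds[0]).integers(0, 2**31 - 1)) if seed is not None else None
    lasso_seed = int(np.random.default_rng(seeds[1]).integers(0, 2**31 - 1)) if seed is not None else None

    t1 = select_by_loadings(model, percentile=loading_percentile)
    sub1 = table.subset(t1.surviving)
    if sub1.n_features < 2:
        raise ValidationError("select_signature: fewer than 2 features after loading stage")
    t2 = gini_bootstrap_filter(
        sub1,
        labels,
        n_boot=gini_n_boot,
        mode=gini_mode,
        importance_threshold=gini_threshold,
        keep_fraction=gini_keep_fraction,
        n_trees=gini_n_trees,
        seed=gini_seed,
    )
    sub2 = table.subset(t2.surviving)
    n_final = min(n_select, sub2.n_features)
    signature = lasso_stability_select(
        sub2, labels, n_runs=lasso_n_runs, n_select=n_final, seed=lasso_seed
    )
    traces = [t1, t2, signature.trace]
    assert len(t1.surviving) >= len(t2.surviving) >= len(signature)
    return signature, traces
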