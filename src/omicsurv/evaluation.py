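"""Signature evaluation: Monte-Carlo classifier assessment, ROC/Youden
cut-points, the binarized logistic signature model (Nagelkerke R²,
Hosmer–Lemeshow), Fisher's exact cluster–metastasis association, and the
descriptive cross-omics profile.

Convention: cluster 2 (the shorter-surviving subgroup) is the positive
class for sensitivity/specificity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from omicsurv.exceptions import ValidationError
from omicsurv.io import CohortBundle
from omicsurv.reduction import map_segments_to_genes
from omicsurv.selection import Signature

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "sensitivity", "specificity")
SUMMARY_POINTS = ("min", "q1", "median", "mean", "q3", "max")
_Z = 1.959963984540054


@dataclass
class EvalSummary:
    """Six-number summaries of accuracy/sensitivity/specificity over
    Monte-Carlo iterations."""

    table: pd.DataFrame  # index: metric; columns: min, q1, median, mean, q3, max
    model: str
    n_iterations: int
    test_fraction: float
    seed: int | None


@dataclass
class ROCResult:
    auc: float
    ci: tuple[float, float]
    cutoff: float | None
    direction: str  # 'high' -> larger values predict the positive class
    youden_j: float
    ci_method: str = "hanley-mcneil"


@dataclass
class LogisticModel:
    """Reduced binarized logistic model with fit diagnostics."""

    coefficients: pd.DataFrame  # index: variable; B, se, p, or_adj, ci_low, ci_high
    intercept: float
    accuracy: float
    null_accuracy: float
    nagelkerke_r2: float
    hosmer_lemeshow_p: float
    removed: list[str] = field(default_factory=list)
    separation: bool = False


# ---------------------------------------------------------------------------
# Monte-Carlo classifier evaluation

def _make_model(model: str, seed: int):
    if model == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0))
    if model == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    raise ValidationError(f"monte_carlo_eval: unknown model {model!r}")


def monte_carlo_eval(
    features,
    labels,
    model: str = "rf",
    n_iter: int = 5000,
    test_fraction: float = 0.127,
    seed: int | None = None,
    positive_class=None,
) -> EvalSummary:
    """Repeated stratified train/test evaluation of a classifier.

    Per iteration: stratified random split (stratification guarantees both
    classes in the test set), fit on train, and score accuracy, sensitivity
    and specificity on test. The positive class defaults to the larger
    label value (cluster 2, the at-risk subgroup).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("monte_carlo_eval: binary labels required")
    if np.isnan(X).any():
        raise ValidationError("monte_carlo_eval: features must be complete")
    pos = positive_class if positive_class is not None else classes.max()

    rng = np.random.default_rng(seed)
    splitter = StratifiedShuffleSplit(
        n_splits=n_iter,
        test_size=test_fraction,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    rows = np.empty((n_iter, 3))
    for i, (train, test) in enumerate(splitter.split(X, y)):
        clf = _make_model(model, seed=int(rng.integers(0, 2**31 - 1)))
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        truth = y[test]
        tp = np.sum((truth == pos) & (pred == pos))
        tn = np.sum((truth != pos) & (pred != pos))
        fp = np.sum((truth != pos) & (pred == pos))
        fn = np.sum((truth == pos) & (pred != pos))
        rows[i] = (
            (tp + tn) / len(truth),
            tp / (tp + fn),
            tn / (tn + fp),
        )
    frame = pd.DataFrame(rows, columns=list(METRICS))
    table = pd.DataFrame(
        {
            "min": frame.min(),
            "q1": frame.quantile(0.25),
            "median": frame.median(),
            "mean": frame.mean(),
            "q3": frame.quantile(0.75),
            "max": frame.max(),
        }
    )
    return EvalSummary(
        table=table,
        model=model,
        n_iterations=n_iter,
        test_fraction=test_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ROC / Youden

def _mann_whitney_auc(values: np.ndarray, positive: np.ndarray) -> float:
    ranks = stats.rankdata(values)
    n1 = int(positive.sum())
    n0 = len(values) - n1
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(values: np.ndarray, positive: np.ndarray, auc: float) -> float:
    pos = values[positive]
    neg = values[~positive]
    # placement values
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / len(neg) for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / len(pos) for x in neg])
    var = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_youden(values, labels, positive_class=None, ci_method: str = "hanley-mcneil") -> ROCResult:
    """Empirical ROC with Mann–Whitney AUC and Youden-optimal cut-off.

    Orientation is auto-chosen so AUC >= 0.5; ``direction`` reports which
    side of the cut-off predicts the positive class. The cut-off is the
    observed value maximizing Youden's J = sensitivity + specificity − 1.
    Constant input yields AUC 0.5 with an undefined cut-off.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("roc_youden: both classes must be present")
    pos_label = positive_class if positive_class is not None else classes.max()
    positive = y == pos_label

    if np.all(values == values[0]):
        warnings.warn("roc_youden: constant values; AUC 0.5, cut-off undefined", stacklevel=2)
        return ROCResult(auc=0.5, ci=(0.5, 0.5), cutoff=None, direction="undefined", youden_j=0.0)

    auc = _mann_whitney_auc(values, positive)
    direction = "high"
    if auc < 0.5:
        auc = 1.0 - auc
        direction = "low"
    oriented = values if direction == "high" else -values

    thresholds = np.unique(oriented)
    # sensitivity/specificity of rule "oriented >= t predicts positive"
    best_j, best_t = -np.inf, thresholds[0]
    n1, n0 = int(positive.sum()), int((~positive).sum())
    for t in thresholds:
        pred = oriented >= t
        sens = np.sum(pred & positive) / n1
        spec = np.sum(~pred & ~positive) / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    cutoff = float(best_t if direction == "high" else -best_t)

    if ci_method == "delong":
        se = _delong_se(oriented, positive, auc)
    else:
        se = _hanley_mcneil_se(auc, n1, n0)
    ci = (max(0.0, auc - _Z * se), min(1.0, auc + _Z * se))
    return ROCResult(
        auc=auc, ci=ci, cutoff=cutoff, direction=direction,
        youden_j=float(best_j), ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# logistic signature model

def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke's rescaled pseudo-R²."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_null)
    return float(cox_snell / max_cs) if max_cs > 0 else 0.0


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray, n_groups: int = 10) -> float:
    """Hosmer–Lemeshow goodness-of-fit p-value on risk deciles (g − 2 df)."""
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    groups = [g for g in groups if len(g)]
    chi2 = 0.0
    for g in groups:
        obs = y[g].sum()
        exp = p[g].sum()
        pbar = exp / len(g)
        denom = len(g) * pbar * (1.0 - pbar)
        if denom > 0:
            chi2 += (obs - exp) ** 2 / denom
    df = len(groups) - 2
    if df <= 0:
        return float("nan")
    return float(stats.chi2.sf(chi2, df))


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 1e-2, n_iter: int = 100):
    """Newton IRLS with a small ridge penalty (intercept unpenalized);
    fallback for complete separation. SEs come from the penalized Hessian
    and are approximate."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    pen = np.full(Xd.shape[1], lam)
    pen[0] = 0.0
    for _ in range(n_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = Xd.T @ (y - mu) - pen * beta
        hess = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    cov = np.linalg.inv((Xd * (mu * (1 - mu))[:, None]).T @ Xd + np.diag(pen))
    se = np.sqrt(np.diag(cov))
    ll = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    return beta, se, mu, ll


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """statsmodels Logit; on separation/convergence failure, ridge fallback."""
    Xd = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 50:
            raise RuntimeError("separation suspected")
        params = res.params
        se = res.bse
        pvals = res.pvalues
        mu = np.asarray(res.predict(Xd))
        ll = float(res.llf)
        return params, se, pvals, mu, ll, False
    except Exception:
        beta, ses, mu, ll = _ridge_logit(X.to_numpy(float), y)
        names = ["const"] + list(X.columns)
        params = pd.Series(beta, index=names)
        se = pd.Series(ses, index=names)
        z = beta / ses
        pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
        return params, se, pvals, mu, ll, True


def logistic_signature_model(
    features: pd.DataFrame,
    labels,
    cutoffs: dict[str, float] | None = None,
    directions: dict[str, str] | None = None,
    binarize: bool = True,
    alpha: float = 0.05,
    positive_class=None,
) -> LogisticModel:
    """Binary logistic model of cluster membership on the signature.

    With ``binarize=True`` (default) each predictor is the indicator
    "value above its Youden cut-off"; backward elimination removes the
    least-significant predictor while any Wald p > ``alpha``, refitting at
    each step. Reports per-variable B, SE, p, OR_adj = exp(B) and Wald CIs
    exp(B ± 1.96·SE), the overall accuracy at probability threshold 0.5,
    the null (majority-class) accuracy, Nagelkerke R² and the
    Hosmer–Lemeshow p (10 risk deciles). Complete separation triggers a
    warning and a ridge-penalized fallback fit flagged in the result.
    """
    features = pd.DataFrame(features)
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if len(classes) != 2:
        raise ValidationError("logistic_signature_model: binary labels required")
    pos = positive_class if positive_class is not None else classes.max()
    y = (y_raw == pos).astype(float)

    if binarize:
        if cutoffs is None:
            raise ValidationError("logistic_signature_model: cut-offs required to binarize")
        X = pd.DataFrame(index=features.index)
        for col in features.columns:
            if col not in cutoffs:
                raise ValidationError(f"logistic_signature_model: no cut-off for {col!r}")
            X[col] = (features[col] > cutoffs[col]).astype(float)
    else:
        X = features.astype(float)

    removed: list[str] = []
    separation_seen = False
    while True:
        params, se, pvals, mu, ll, separated = _fit_logit(X, y)
        separation_seen = separation_seen or separated
        covar_p = pvals.drop("const")
        if len(covar_p) > 1 and covar_p.max() > alpha:
            worst = covar_p.idxmax()
            removed.append(str(worst))
            X = X.drop(columns=[worst])
            continue
        break
    if separation_seen:
        warnings.warn(
            "logistic_signature_model: complete separation; ridge-penalized "
            "fallback fit used",
            stacklevel=2,
        )

    ll_null = float(np.sum(
        y * np.log(y.mean() + 1e-300) + (1 - y) * np.log(1 - y.mean() + 1e-300)
    ))
    coef = params.drop("const")
    se_c = se.drop("const")
    table = pd.DataFrame(
        {
            "B": coef,
            "se": se_c,
            "p": pvals.drop("const"),
            "or_adj": np.exp(coef),
            "ci_low": np.exp(coef - _Z * se_c),
            "ci_high": np.exp(coef + _Z * se_c),
        }
    )
    pred = (mu >= 0.5).astype(float)
    accuracy = float((pred == y).mean())
    null_accuracy = null_model_accuracy(y)
    return LogisticModel(
        coefficients=table,
        intercept=float(params["const"]),
        accuracy=accuracy,
        null_accuracy=null_accuracy,
        nagelkerke_r2=nagelkerke_r2(ll, ll_null, len(y)),
        hosmer_lemeshow_p=hosmer_lemeshow(y, mu),
        removed=removed,
        separation=separation_seen,
    )


def null_model_accuracy(labels) -> float:
    """Accuracy of the intercept-only classifier: the majority-class share."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValidationError("null_model_accuracy: empty labels")
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / counts.sum())


def odds_ratio(coefficient: float) -> float:
    """Adjusted odds ratio implied by a logistic coefficient: exp(B)."""
    return float(np.exp(coefficient))


# ---------------------------------------------------------------------------
# Fisher association

def fisher_association(flag_a, flag_b) -> tuple[float, np.ndarray]:
    """Two-sided Fisher exact test (point-probability rule) of two binary
    per-sample flags; returns (p, 2x2 table)."""
    a = np.asarray(flag_a)
    b = np.asarray(flag_b)
    ua, ub = np.unique(a), np.unique(b)
    if len(ua) > 2 or len(ub) > 2:
        raise ValidationError("fisher_association: both variables must be binary")
    table = np.zeros((2, 2), dtype=np.int64)
    for i, va in enumerate(ua[:2]):
        for j, vb in enumerate(ub[:2]):
            table[i, j] = np.sum((a == va) & (b == vb))
    if len(ua) < 2 or len(ub) < 2 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("fisher_association: empty margin; p = 1", stacklevel=2)
        return 1.0, table
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table


# ---------------------------------------------------------------------------
# descriptive cross-omics profile

def cross_omics_profile(
    signature: Signature,
    bundle: CohortBundle,
    labels,
) -> pd.DataFrame:
    """Per signature gene, per cluster: mean CNA log2, mean methylation
    beta, median expression. Purely descriptive; genes absent from a layer
    yield missing cells."""
    labels = pd.Series(np.asarray(labels), index=bundle.samples)
    genes = signature.entries["gene"].unique().tolist()
    if not genes:
        return pd.DataFrame(
            columns=["gene", "cluster", "mean_cna_log2", "mean_beta", "median_expression"]
        )
    ann = bundle.annotation[bundle.annotation["gene"].isin(genes)].reset_index(drop=True)
    seg = bundle.segments[bundle.segments["chrom"].isin(set(ann["chrom"]))]
    cna = (
        map_segments_to_genes(seg, ann, samples=bundle.samples)
        if len(ann)
        else pd.DataFrame(index=bundle.samples)
    )
    rows = []
    for gene in genes:
        for cluster in sorted(labels.unique()):
            mask = labels == cluster
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "mean_cna_log2": float(cna.loc[mask, gene].mean()) if gene in cna.columns else np.nan,
                    "mean_beta": float(bundle.methylation.loc[mask, gene].mean())
                    if gene in bundle.methylation.columns
                    else np.nan,
                    "median_expression": float(bundle.expression.loc[mask, gene].median())
                    if gene in bundle.expression.columns
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
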