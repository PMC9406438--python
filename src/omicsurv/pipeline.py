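"""End-to-end pipeline: reduction → PCA/clustering → survival tests →
signature selection → evaluation, with per-stage artifacts and a
machine-readable summary.

A single global seed is fanned out to the stochastic stages through named
``numpy.random.SeedSequence`` substreams, so identical config + seed gives
an identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from omicsurv.cluster import cluster_scores, fit_pca
from omicsurv.config import PipelineConfig
from omicsurv.evaluation import (
    cross_omics_profile,
    fisher_association,
    logistic_signature_model,
    monte_carlo_eval,
    null_model_accuracy,
    roc_youden,
)
from omicsurv.exceptions import OmicsurvError, ValidationError
from omicsurv.io import load_cohort
from omicsurv.reduction import (
    apply_layer_filters,
    build_integration_table,
    correlation_filter,
    map_segments_to_genes,
)
from omicsurv.selection import select_signature
from omicsurv.simulate import generate_cohort, write_cohort
from omicsurv.survival import cox_fit, km_estimate, weighted_logrank

logger = logging.getLogger(__name__)

_STAGE_SEEDS = ("kmeans", "selection", "mc_pcs", "mc_svm", "mc_rf")

TABLE_FILES = {
    "table2": "table2_km_survival.tsv",
    "table3": "table3_pc_rf_eval.tsv",
    "table4": "table4_signature_eval.tsv",
    "table5": "table5_auc.tsv",
    "table6": "table6_cutoffs.tsv",
    "table7": "table7_logistic.tsv",
}


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_SEEDS))
    return {
        name: int(np.random.default_rng(child).integers(0, 2**31 - 1))
        for name, child in zip(_STAGE_SEEDS, children)
    }


def _summarize_eval(ev) -> dict:
    return {
        metric: {k: round(float(v), 6) for k, v in ev.table.loc[metric].items()}
        for metric in ev.table.index
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes per-stage artifacts (TSV), ``signature.json``, ``summary.json``
    and a log with per-stage feature counts and seeds. Any stage failure
    aborts the run with a stage-named error; partial artifacts remain.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("omicsurv")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    config.to_yaml(outdir / "config.yaml")
    logger.info("stage seeds: %s", seeds)

    try:
        summary: dict = {"seed": config.seed, "stage_seeds": seeds}

        # --- stage: input ------------------------------------------------
        stage = "input"
        truth = None
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            bundle, truth = generate_cohort(sim)
            write_cohort(bundle, truth, outdir / "cohort")
        else:
            bundle = load_cohort({k: Path(v) for k, v in config.paths.items()})
        labels_truth = truth.labels if truth is not None else None
        summary["n_samples"] = int(len(bundle.samples))

        # --- stage: reduction --------------------------------------------
        stage = "reduction"
        cna = map_segments_to_genes(bundle.segments, bundle.annotation, bundle.samples)
        cna_f, meth_f, expr_f = apply_layer_filters(
            cna, bundle.methylation, bundle.expression, config.filters
        )
        raw_table = build_integration_table(cna_f, meth_f, expr_f, standardize=False)
        table = build_integration_table(cna_f, meth_f, expr_f, standardize=config.standardize)
        table = correlation_filter(table, r_threshold=config.r_threshold)
        raw_data = raw_table.data[table.data.columns]
        counts = pd.DataFrame(table.provenance)
        counts.to_csv(outdir / "feature_counts.tsv", sep="\t", index=False)
        summary["feature_counts"] = table.provenance

        # --- stage: clustering -------------------------------------------
        stage = "clustering"
        model = fit_pca(table, n_components=config.n_pcs)
        assignment = cluster_scores(
            model, k=config.k, seed=seeds["kmeans"], n_init=config.kmeans_n_init
        )
        labels = assignment.labels
        model.scores.to_csv(outdir / "pc_scores.tsv", sep="\t")
        model.loadings.to_csv(outdir / "pc_loadings.tsv", sep="\t")
        labels.to_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t")
        cluster_sizes = labels.value_counts().sort_index()
        summary["clustering"] = {
            "silhouette_avg": round(assignment.silhouette_avg, 6),
            "cluster_sizes": {int(k): int(v) for k, v in cluster_sizes.items()},
            "larger_cluster_share": round(float(cluster_sizes.max() / cluster_sizes.sum()), 6),
            "explained_variance_ratio": [round(float(v), 6) for v in model.explained_variance_ratio],
        }
        if labels_truth is not None:
            from sklearn.metrics import adjusted_rand_score

            summary["clustering"]["ari_vs_truth"] = round(
                float(adjusted_rand_score(labels_truth.to_numpy(), labels.to_numpy())), 6
            )

        # --- stage: survival ----------------------------------------------
        stage = "survival"
        clin = bundle.clinical
        km = {}
        for c in sorted(labels.unique()):
            mask = (labels == c).to_numpy()
            curve = km_estimate(clin["time_days"][mask], clin["event"][mask])
            curve.table.to_csv(outdir / f"km_cluster{c}.tsv", sep="\t", index=False)
            km[c] = curve
        tests = {
            scheme: weighted_logrank(
                clin["time_days"], clin["event"], labels.to_numpy(), scheme=scheme
            )
            for scheme in ("logrank", "breslow", "tarone")
        }
        summary["survival"] = {
            "median_by_cluster": {int(c): float(k.median) for c, k in km.items()},
            "median_ci_by_cluster": {int(c): list(k.median_ci) for c, k in km.items()},
            "mean_by_cluster": {int(c): round(k.mean, 3) for c, k in km.items()},
            "median_gap_days": float(km[1].median - km[2].median)
            if len(km) == 2 and km[1].median_defined and km[2].median_defined
            else None,
            "tests": {s: {"statistic": round(t.statistic, 6), "p": round(t.p_value, 6)} for s, t in tests.items()},
        }

        # --- stage: selection ----------------------------------------------
        stage = "selection"
        signature, traces = select_signature(
            table,
            labels.to_numpy(),
            model=model,
            loading_percentile=config.loading_percentile,
            gini_n_boot=config.gini_n_boot,
            gini_mode=config.gini_mode,
            gini_threshold=config.gini_threshold,
            gini_keep_fraction=config.gini_keep_fraction,
            gini_n_trees=config.gini_n_trees,
            lasso_n_runs=config.lasso_n_runs,
            n_select=config.n_select,
            seed=seeds["selection"],
        )
        for trace in traces:
            trace.diagnostics.to_csv(outdir / f"selection_{trace.stage}.tsv", sep="\t")
        with open(outdir / "signature.json", "w", encoding="utf-8") as fh:
            json.dump(signature.to_dict(), fh, indent=1, sort_keys=True)
        summary["selection"] = {
            "stage_counts": {t.stage: len(t.surviving) for t in traces},
            "signature": signature.to_dict(),
        }
        if truth is not None:
            planted = {f"{g}|{l}" for g, l in truth.planted_features}
            hits = sum(1 for fid in signature.feature_ids() if fid in planted)
            summary["selection"]["planted_in_signature"] = hits

        # --- stage: evaluation ---------------------------------------------
        stage = "evaluation"
        y = labels.to_numpy()
        ev_pcs = monte_carlo_eval(
            model.scores.to_numpy(), y, model="rf",
            n_iter=config.mc_n_iter, test_fraction=config.test_fraction,
            seed=seeds["mc_pcs"],
        )
        sig_X = table.data[signature.feature_ids()].to_numpy()
        ev_svm = monte_carlo_eval(
            sig_X, y, model="svm", n_iter=config.mc_n_iter,
            test_fraction=config.test_fraction, seed=seeds["mc_svm"],
        )
        ev_rf = monte_carlo_eval(
            sig_X, y, model="rf", n_iter=config.mc_n_iter,
            test_fraction=config.test_fraction, seed=seeds["mc_rf"],
        )
        summary["evaluation"] = {
            "pc_scores_rf": _summarize_eval(ev_pcs),
            "signature_svm": _summarize_eval(ev_svm),
            "signature_rf": _summarize_eval(ev_rf),
        }

        roc_rows, cutoffs = [], {}
        for fid in signature.feature_ids():
            roc = roc_youden(raw_data[fid].to_numpy(), y)
            roc_rows.append(
                {
                    "feature": fid,
                    "auc": round(roc.auc, 6),
                    "ci_low": round(roc.ci[0], 6),
                    "ci_high": round(roc.ci[1], 6),
                    "cutoff": roc.cutoff,
                    "direction": roc.direction,
                    "youden_j": round(roc.youden_j, 6),
                }
            )
            if roc.cutoff is not None:
                cutoffs[fid] = roc.cutoff
        roc_table = pd.DataFrame(roc_rows).set_index("feature")
        roc_table.to_csv(outdir / "roc_youden.tsv", sep="\t")
        summary["roc"] = roc_table.to_dict(orient="index")

        logit = logistic_signature_model(
            raw_data[list(cutoffs)], y, cutoffs=cutoffs, binarize=True
        )
        summary["logistic"] = {
            "coefficients": {
                var: {k: round(float(v), 6) for k, v in row.items()}
                for var, row in logit.coefficients.iterrows()
            },
            "intercept": round(logit.intercept, 6),
            "accuracy": round(logit.accuracy, 6),
            "null_accuracy": round(logit.null_accuracy, 6),
            "nagelkerke_r2": round(logit.nagelkerke_r2, 6),
            "hosmer_lemeshow_p": round(logit.hosmer_lemeshow_p, 6)
            if np.isfinite(logit.hosmer_lemeshow_p) else None,
            "removed": logit.removed,
            "separation": logit.separation,
        }

        retained = logit.coefficients.index.tolist()
        cox_summary = None
        if retained:
            X_cox = pd.DataFrame(
                {fid: (raw_data[fid] > cutoffs[fid]).astype(float) for fid in retained}
            )
            try:
                cox = cox_fit(X_cox, clin["time_days"].to_numpy(), clin["event"].to_numpy())
                cox_summary = {
                    "lr_p": round(cox.lr_p, 6),
                    "penalized": cox.penalized,
                    "covariates": {
                        var: {k: round(float(v), 6) for k, v in row.items()}
                        for var, row in cox.summary.iterrows()
                    },
                }
            except (ValidationError, np.linalg.LinAlgError) as exc:
                logger.warning("cox model skipped: %s", exc)
        summary["cox"] = cox_summary

        meta = (clin["metastasis"] == "yes").to_numpy()
        fisher_p, fisher_table = fisher_association(labels.to_numpy(), meta)
        summary["metastasis"] = {
            "fisher_p": round(fisher_p, 6),
            "table": fisher_table.tolist(),
            "km_by_group": {},
        }
        for name, mask in (("metastasis", meta), ("no_metastasis", ~meta)):
            sub = {}
            for c in sorted(labels.unique()):
                m = mask & (labels == c).to_numpy()
                if m.sum() >= 2 and clin["event"][m].sum() > 0:
                    curve = km_estimate(clin["time_days"][m], clin["event"][m])
                    curve.table.to_csv(outdir / f"km_{name}_cluster{c}.tsv", sep="\t", index=False)
                    sub[int(c)] = float(curve.median)
            summary["metastasis"]["km_by_group"][name] = sub

        profile = cross_omics_profile(signature, bundle, labels.to_numpy())
        profile.to_csv(outdir / "cross_omics_profile.tsv", sep="\t", index=False)

        summary["null_model_accuracy"] = round(null_model_accuracy(y), 6)
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        logger.info("pipeline complete: %s", outdir / "summary.json")
        return outdir
    except Exception as exc:
        raise OmicsurvError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# report rendering

def report_tables(run_dir: str | Path) -> dict[str, Path]:
    """Render the six table analogues of a completed run as TSV files.

    Raises :class:`OmicsurvError` listing the missing artifacts when the run
    is incomplete.
    """
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        expected = ["summary.json"] + list(TABLE_FILES.values())
        raise OmicsurvError(
            f"report_tables: incomplete run at {run_dir}; missing artifacts: {expected}"
        )
    with open(summary_path, "r", encoding="utf-8") as fh:
        summary = json.load(fh)

    missing = [k for k in ("survival", "evaluation", "roc", "logistic") if summary.get(k) is None]
    if missing:
        raise OmicsurvError(f"report_tables: summary lacks sections {missing}")

    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    out: dict[str, Path] = {}

    surv = summary["survival"]
    rows = []
    for c, med in surv["median_by_cluster"].items():
        rows.append(
            {
                "cluster": c,
                "median": med,
                "median_ci_low": surv["median_ci_by_cluster"][c][0],
                "median_ci_high": surv["median_ci_by_cluster"][c][1],
                "mean": surv["mean_by_cluster"][c],
            }
        )
    _write(report_dir, "table2", pd.DataFrame(rows), out)

    ev = summary["evaluation"]
    _write(report_dir, "table3", _eval_frame(ev["pc_scores_rf"]), out)
    t4 = pd.concat(
        {
            "svm": _eval_frame(ev["signature_svm"]).set_index("metric"),
            "rf": _eval_frame(ev["signature_rf"]).set_index("metric"),
        },
        names=["model"],
    ).reset_index()
    _write(report_dir, "table4", t4, out)

    roc = pd.DataFrame(summary["roc"]).T.reset_index(names="feature")
    _write(report_dir, "table5", roc[["feature", "auc", "ci_low", "ci_high"]], out)
    _write(report_dir, "table6", roc[["feature", "cutoff", "direction", "youden_j"]], out)

    logit = summary["logistic"]
    t7 = pd.DataFrame(logit["coefficients"]).T.reset_index(names="variable")
    intercept_row = pd.DataFrame([{"variable": "(intercept)", "B": logit["intercept"]}])
    t7 = pd.concat([t7, intercept_row], ignore_index=True)
    _write(report_dir, "table7", t7, out)
    return out


def _eval_frame(metrics: dict) -> pd.DataFrame:
    return pd.DataFrame(metrics).T.reset_index(names="metric")


def _write(report_dir: Path, key: str, frame: pd.DataFrame, out: dict) -> None:
    path = report_dir / TABLE_FILES[key]
    frame.to_csv(path, sep="\t", index=False)
    out[key] = path
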