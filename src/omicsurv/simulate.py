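"""Synthetic linked multi-omics cohort generator with a planted two-cluster
structure and a subgroup-dependent survival difference.

The generator emulates a tumor cohort in which a latent two-subgroup
structure is expressed in a small set of planted genes in each of three
linked layers (copy-number segments, methylation betas, expression counts)
and in survival. Design:

* A shared universe of ``n_genes_per_layer`` genes laid out on four
  chromosomes (10 kb genes, 10 kb gaps, 1-based closed intervals).
* Cluster 1 (longer survival) receives ``floor(n_samples *
  cluster_fraction)`` samples; the remainder form cluster 2.
* Planted genes per layer are disjoint gene sets. Cluster 2 samples carry a
  deficit in each planted gene: a log2-ratio loss of ``effect_size * 0.15``
  for copy number, and a downward shift of ``effect_size`` latent standard
  deviations on the logit (methylation) or log (expression) scale — loss of
  material, hypo-methylation and under-expression in the short-survival
  subgroup.
* Planted genes within a layer share a latent construct factor (correlation
  ``construct_corr``) so they form the strongly correlated constructs that
  survive downstream |r| > 0.8 filtering; a fraction of non-planted
  methylation/expression genes is arranged in correlated noise blocks and a
  few copy-number regions are commonly altered independently of cluster, so
  filters face realistic distractors.
* Survival is exponential within cluster with scale = median / ln 2;
  censoring is independent uniform administrative censoring whose horizon is
  calibrated so the expected censored fraction equals ``censoring_rate``.
* Copy number is emitted as per-sample segments (one segment per region, a
  region being a planted run, a commonly-altered block, or a single gene) so
  gene-level values only exist after segment-to-gene mapping.

One global integer seed drives everything through named
``numpy.random.SeedSequence`` substreams, so identical configs give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from omicsurv import io as oio
from omicsurv.config import SimConfig
from omicsurv.io import CohortBundle

GENE_LENGTH = 10_000
GENE_GAP = 10_000
N_CHROMS = 4

_STREAMS = (
    "layout", "cna", "methylation", "expression", "survival", "censoring", "metastasis",
)


@dataclass
class TruthManifest:
    """Ground truth of a generated cohort: labels, planted features, params."""

    labels: pd.Series  # per-sample cluster index (1 or 2)
    planted_features: list[tuple[str, str]]  # (gene, layer)
    params: SimConfig

    def to_dict(self) -> dict:
        params = dataclasses.asdict(self.params)
        params["median_survival_days"] = list(params["median_survival_days"])
        return {
            "labels": {s: int(v) for s, v in self.labels.items()},
            "planted_features": [list(t) for t in self.planted_features],
            "params": params,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TruthManifest":
        labels = pd.Series(data["labels"], name="cluster").astype(int)
        labels.index.name = "sample"
        return cls(
            labels=labels,
            planted_features=[tuple(t) for t in data["planted_features"]],
            params=SimConfig(**data["params"]),
        )


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _gene_annotation(n_genes: int) -> pd.DataFrame:
    per_chrom = int(np.ceil(n_genes / N_CHROMS))
    rows = []
    for i in range(n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        pos = i % per_chrom
        start = 1 + pos * (GENE_LENGTH + GENE_GAP)
        rows.append((f"GENE{i + 1:04d}", chrom, start, start + GENE_LENGTH - 1))
    return pd.DataFrame(rows, columns=oio.ANNOTATION_COLUMNS)


def _pick_runs(
    rng: np.random.Generator, annotation: pd.DataFrame, run_lengths: list[int]
) -> list[np.ndarray]:
    """Pick non-overlapping runs of consecutive same-chromosome gene indices."""
    taken = np.zeros(len(annotation), dtype=bool)
    chroms = annotation["chrom"].to_numpy()
    runs: list[np.ndarray] = []
    for length in run_lengths:
        candidates = [
            s
            for s in range(len(annotation) - length + 1)
            if not taken[s : s + length].any()
            and (chroms[s : s + length] == chroms[s]).all()
        ]
        if not candidates:
            raise ValueError("gene universe too small for the requested planted/altered runs")
        start = int(rng.choice(candidates))
        taken[start : start + length] = True
        runs.append(np.arange(start, start + length))
    return runs


def _latent_signal(
    rng: np.random.Generator,
    n_samples: int,
    n_features: int,
    shift: np.ndarray,
    construct_corr: float,
) -> np.ndarray:
    """Unit-variance latent matrix with a shared construct factor and a
    per-sample additive shift (same for all features in the construct)."""
    rho = np.sqrt(construct_corr)
    factor = rng.standard_normal(n_samples)
    eps = rng.standard_normal((n_samples, n_features))
    return shift[:, None] + rho * factor[:, None] + np.sqrt(1.0 - construct_corr) * eps


def _noise_blocks(
    rng: np.random.Generator,
    n_samples: int,
    noise_idx: np.ndarray,
    block_fraction: float,
    block_size: int,
    construct_corr: float,
) -> np.ndarray:
    """Latent values for non-planted genes: correlated blocks + iid noise."""
    out = np.empty((n_samples, len(noise_idx)))
    n_blocks = int(round(block_fraction * len(noise_idx) / block_size))
    n_blocked = n_blocks * block_size
    zero = np.zeros(n_samples)
    for b in range(n_blocks):
        cols = slice(b * block_size, (b + 1) * block_size)
        out[:, cols] = _latent_signal(rng, n_samples, block_size, zero, construct_corr)
    out[:, n_blocked:] = rng.standard_normal((n_samples, len(noise_idx) - n_blocked))
    return out


def _censoring_horizon(rates: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Horizon u of Uniform(0, u) censoring with expected censored fraction
    ``target`` under an exponential mixture: P(C < T) = (1 - e^(-lam*u)) / (lam*u)."""

    def censored_fraction(u: float) -> float:
        lu = rates * u
        return float(np.dot(weights, (1.0 - np.exp(-lu)) / lu))

    lo, hi = 1e-6, 1e12
    return brentq(lambda u: censored_fraction(u) - target, lo, hi, xtol=1e-9)


def generate_cohort(config: SimConfig) -> tuple[CohortBundle, TruthManifest]:
    """Generate one linked cohort and its truth manifest.

    Returns a validated :class:`CohortBundle` whose copy-number layer is a
    per-sample segment table; gene-level CNA values are obtained downstream
    via :func:`omicsurv.reduction.map_segments_to_genes`.
    """
    config.validate()
    rngs = _rngs(config.seed)
    n, g = config.n_samples, config.n_genes_per_layer
    k = config.n_planted_per_layer
    samples = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample")

    n1 = int(np.floor(n * config.cluster_fraction))
    labels = pd.Series(np.where(np.arange(n) < n1, 1, 2), index=samples, name="cluster")
    c2 = (labels.to_numpy() == 2).astype(float)  # planted deficit lives in cluster 2

    annotation = _gene_annotation(g)
    genes = annotation["gene"].to_numpy()

    # --- layout: planted CNA run, commonly-altered blocks, planted meth/expr
    layout_rng = rngs["layout"]
    run_lengths = [k] if k else []
    run_lengths += [3] * config.n_cna_altered_blocks
    runs = _pick_runs(layout_rng, annotation, run_lengths) if run_lengths else []
    cna_planted = runs[0] if k else np.array([], dtype=int)
    altered_blocks = runs[1 if k else 0:]
    used = set(cna_planted.tolist())
    for blk in altered_blocks:
        used.update(blk.tolist())
    free = np.array([i for i in range(g) if i not in used], dtype=int)
    picked = layout_rng.choice(free, size=2 * k, replace=False) if k else np.array([], dtype=int)
    meth_planted = np.sort(picked[:k])
    expr_planted = np.sort(picked[k:])

    # --- copy number: one segment per region per sample -------------------
    cna_rng = rngs["cna"]
    shift_cna = config.effect_size * config.cna_shift_per_unit_effect
    regions: list[tuple[np.ndarray, np.ndarray]] = []  # (gene indices, per-sample value)
    if k:
        seg_noise = cna_rng.normal(0.0, config.cna_noise_sd, size=n)
        regions.append((cna_planted, -shift_cna * c2 + seg_noise))
    for blk in altered_blocks:
        altered = cna_rng.random(n) < 0.5
        sign = cna_rng.choice([-1.0, 1.0], size=n)
        value = cna_rng.normal(0.0, config.cna_noise_sd, size=n) + altered * sign * 0.35
        regions.append((blk, value))
    singleton = np.array(sorted(set(range(g)) - {i for r, _ in regions for i in r}), dtype=int)
    for idx in singleton:
        regions.append((np.array([idx]), cna_rng.normal(0.0, config.cna_noise_sd, size=n)))
    regions.sort(key=lambda r: int(r[0][0]))

    starts = annotation["start"].to_numpy()
    ends = annotation["end"].to_numpy()
    chroms = annotation["chrom"].to_numpy()
    rec_sample, rec_chrom, rec_start, rec_end, rec_val = [], [], [], [], []
    for si, sample in enumerate(samples):
        for gene_idx, values in regions:
            rec_sample.append(sample)
            rec_chrom.append(chroms[gene_idx[0]])
            rec_start.append(int(starts[gene_idx[0]]))
            rec_end.append(int(ends[gene_idx[-1]]))
            rec_val.append(round(float(values[si]), 6))
    segments = pd.DataFrame(
        {
            "sample": rec_sample,
            "chrom": rec_chrom,
            "start": np.array(rec_start, dtype=np.int64),
            "end": np.array(rec_end, dtype=np.int64),
            "log2_ratio": rec_val,
        }
    )

    # --- methylation: logit-scale shift, inverse-logit keeps [0, 1] -------
    meth_rng = rngs["methylation"]
    mu = meth_rng.normal(0.4, 1.2, size=g)
    mu[meth_planted] = 0.8
    latent = np.empty((n, g))
    latent[:, meth_planted] = _latent_signal(
        meth_rng, n, k, -config.effect_size * c2, config.construct_corr
    )
    noise_idx = np.array(sorted(set(range(g)) - set(meth_planted.tolist())), dtype=int)
    latent[:, noise_idx] = _noise_blocks(
        meth_rng, n, noise_idx, config.noise_block_fraction,
        config.noise_block_size, config.construct_corr,
    )
    methylation = pd.DataFrame(
        np.round(expit(mu[None, :] + 0.8 * latent), 6), index=samples, columns=genes
    )

    # --- expression: log-scale shift, exponentiated, dropout zeros --------
    expr_rng = rngs["expression"]
    base = expr_rng.normal(5.0, 1.5, size=g)
    base[expr_planted] = 6.0
    latent = np.empty((n, g))
    latent[:, expr_planted] = _latent_signal(
        expr_rng, n, k, -config.effect_size * c2, config.construct_corr
    )
    noise_idx = np.array(sorted(set(range(g)) - set(expr_planted.tolist())), dtype=int)
    latent[:, noise_idx] = _noise_blocks(
        expr_rng, n, noise_idx, config.noise_block_fraction,
        config.noise_block_size, config.construct_corr,
    )
    values = np.exp(base[None, :] + 0.7 * latent)
    # dropout: one fifth of iid noise genes get a gene-level zero rate
    n_blocks = int(round(config.noise_block_fraction * len(noise_idx) / config.noise_block_size))
    iid_noise = noise_idx[n_blocks * config.noise_block_size:]
    n_drop = len(iid_noise) // 5
    if n_drop:
        drop_genes = expr_rng.choice(iid_noise, size=n_drop, replace=False)
        drop_rates = expr_rng.uniform(0.3, 0.7, size=n_drop)
        zero_mask = expr_rng.random((n, n_drop)) < drop_rates[None, :]
        cols = values[:, drop_genes]
        cols[zero_mask] = 0.0
        values[:, drop_genes] = cols
    expression = pd.DataFrame(np.round(values, 3), index=samples, columns=genes)

    # --- survival: exponential per cluster, uniform censoring -------------
    med = np.asarray(config.median_survival_days, dtype=float)
    scales = med / np.log(2.0)
    per_sample_scale = np.where(labels.to_numpy() == 1, scales[0], scales[1])
    t_event = rngs["survival"].exponential(per_sample_scale)
    if config.censoring_rate > 0:
        weights = np.array([n1 / n, (n - n1) / n])
        horizon = _censoring_horizon(1.0 / scales, weights, config.censoring_rate)
        t_cens = rngs["censoring"].uniform(0.0, horizon, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(np.int64)
    else:
        time = t_event
        event = np.ones(n, dtype=np.int64)
    metastasis = np.where(
        rngs["metastasis"].random(n) < config.metastasis_rate, "yes", "no"
    )
    clinical = pd.DataFrame(
        {"time_days": np.round(time, 1), "event": event, "metastasis": metastasis},
        index=samples,
    )

    bundle = CohortBundle(
        segments=segments,
        annotation=annotation,
        methylation=methylation,
        expression=expression,
        clinical=clinical,
    )
    planted = (
        [(genes[i], "cna") for i in cna_planted]
        + [(genes[i], "methylation") for i in meth_planted]
        + [(genes[i], "expression") for i in expr_planted]
    )
    manifest = TruthManifest(labels=labels, planted_features=planted, params=config)
    return bundle, manifest


def write_cohort(
    bundle: CohortBundle, manifest: TruthManifest, directory: str | Path
) -> dict[str, Path]:
    """Write the five cohort files plus ``truth.json``; returns the path map."""
    directory = Path(directory)
    paths = oio.write_bundle(bundle, directory)
    truth_path = directory / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths


def read_truth(path: str | Path) -> TruthManifest:
    with open(path, "r", encoding="utf-8") as fh:
        return TruthManifest.from_dict(json.load(fh))
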