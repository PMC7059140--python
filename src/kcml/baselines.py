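"""Comparison pipelines: clustering- and correlation-based function assignment.

These reproduce the conventional screen-analysis recipes the per-term
classifiers are benchmarked against: cluster the gene profiles (k-means or a
1-D self-organising map) on the leading principal components and read term
membership off cluster composition, or call a gene a term member when its
profile correlates strongly with an annotated gene. Both are scored with the
same recall/AUROC machinery as the classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score

from .annotations import TermCatalog
from .profiles import feature_columns, pca_reduce

log = logging.getLogger(__name__)

__all__ = ["BaselineResult", "cluster_baseline", "correlation_baseline"]


@dataclass
class BaselineResult:
    method: str
    parameter: float
    per_term: pd.DataFrame  # term, recall, auroc
    mean_auroc: float
    mean_recall: float


def _fit_som_1d(x: np.ndarray, k: int, epochs: int = 20) -> np.ndarray:
    """Batch-train a 1-D chain of k units; returns per-sample unit labels.

    Codebook is initialised along the first principal component so training
    is deterministic; the neighbourhood width shrinks geometrically from k/4
    to 0.5 over the epochs.
    """
    centered = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    lo, hi = np.quantile(proj, [0.05, 0.95])
    codebook = x.mean(axis=0) + np.outer(np.linspace(lo, hi, k), vt[0])
    widths = np.geomspace(max(k / 4.0, 0.5), 0.5, epochs)
    units = np.arange(k)
    for w in widths:
        d = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        bmu = d.argmin(axis=1)
        h = np.exp(-((units[:, None] - bmu[None, :]) ** 2) / (2 * w**2))  # (k, n)
        denom = h.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        codebook = (h @ x) / denom
    d = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    return d.argmin(axis=1)


def cluster_baseline(
    matrix: pd.DataFrame,
    catalog: TermCatalog,
    method: str = "kmeans",
    k_values: tuple[int, ...] = (10, 50, 100, 150, 200),
    n_pcs: int = 100,
    seed: int = 0,
) -> list[BaselineResult]:
    """Cluster gene profiles and score cluster-composition term predictions.

    Profiles are reduced to the first *n_pcs* principal components and
    clustered for each cluster count k. Each gene's score for a term is the
    fraction of the other members of its cluster annotated to the term;
    per-term AUROC ranks genes by that score, and recall counts annotated
    genes co-clustered with at least one other annotated gene.
    """
    genes = list(matrix.index)
    pcs = pca_reduce(matrix, n_pcs)
    x = pcs[feature_columns(pcs)].to_numpy(dtype=float)
    results = []
    for k in k_values:
        if k > len(genes):
            log.warning("cluster_baseline: k=%d > %d genes; skipped", k, len(genes))
            continue
        if method == "kmeans":
            labels = KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(x)
        elif method == "som":
            labels = _fit_som_1d(x, k)
        else:
            raise ValueError(f"unknown clustering method {method!r}")
        labels = np.asarray(labels)
        cluster_sizes = np.bincount(labels, minlength=labels.max() + 1)
        rows = []
        for entry in catalog:
            is_pos = np.array([g in entry.genes for g in genes])
            pos_per_cluster = np.bincount(labels[is_pos], minlength=cluster_sizes.size)
            n_pos_cluster = pos_per_cluster[labels]  # annotated count in own cluster
            others = cluster_sizes[labels] - 1
            score = np.where(
                others > 0, (n_pos_cluster - is_pos) / np.maximum(others, 1), 0.0
            )
            if is_pos.all() or not is_pos.any():
                continue
            auroc = roc_auc_score(is_pos, score)
            predicted = (n_pos_cluster - is_pos) > 0
            recall = float(np.mean(predicted[is_pos]))
            rows.append({"term": entry.term_id, "recall": recall, "auroc": auroc})
        per_term = pd.DataFrame(rows)
        results.append(
            BaselineResult(
                method=method,
                parameter=float(k),
                per_term=per_term,
                mean_auroc=float(per_term["auroc"].mean()),
                mean_recall=float(per_term["recall"].mean()),
            )
        )
    return results


def correlation_baseline(
    matrix: pd.DataFrame,
    catalog: TermCatalog,
    r_threshold: float = 0.9,
) -> BaselineResult:
    """Call a gene a term member when its Pearson correlation with any other
    annotated gene of the term exceeds *r_threshold*.

    A correlated gene is a true positive if annotated to the term, a false
    positive otherwise. Zero-variance profiles yield no correlations.
    """
    genes = list(matrix.index)
    x = matrix[feature_columns(matrix)].to_numpy(dtype=float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("correlation_baseline: %d zero-variance profiles excluded", int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    np.fill_diagonal(corr, np.nan)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    gene_idx = {g: i for i, g in enumerate(genes)}
    rows = []
    for entry in catalog:
        members = [gene_idx[g] for g in sorted(entry.genes) if g in gene_idx]
        if len(members) < 2:
            continue
        sub = corr[:, members]
        # for annotated genes, "other genes in the term" excludes themselves
        with np.errstate(invalid="ignore"):
            max_r = np.nanmax(sub, axis=1)
        max_r[np.all(np.isnan(sub), axis=1)] = -np.inf
        predicted = max_r > r_threshold
        is_pos = np.zeros(len(genes), dtype=bool)
        is_pos[members] = True
        tp = int(np.sum(predicted & is_pos))
        fp = int(np.sum(predicted & ~is_pos))
        recall = tp / int(is_pos.sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        rows.append({"term": entry.term_id, "recall": recall,
                     "precision": precision, "tp": tp, "fp": fp})
    per_term = pd.DataFrame(rows)
    return BaselineResult(
        method="correlation",
        parameter=r_threshold,
        per_term=per_term,
        mean_auroc=float("nan"),
        mean_recall=float(per_term["recall"].mean()) if len(per_term) else float("nan"),
    )
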