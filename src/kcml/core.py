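"""Per-term classifier training, selection and genome-wide prediction.

For each candidate term a binary RBF-kernel SVM is trained to discriminate
profiles of annotated genes (positive class) from an equally sized random
sample of unannotated genes (negative class). Features are forward-selected
in order of two-sample KS significance, accepting a feature only when it
improves the cross-validated F-score; the kernel scale sigma is found by grid
search on the same criterion. A term is "classifiable" only when its
classifier clears explicit held-out performance thresholds (false-positive
rate < 20%, test recall > 30%, training recall > 40%), a gate calibrated so
that classifiers of random gene sets fail it. Classifiable terms then score
every gene in the screen; predictions are ranked by signed distance to the
decision boundary.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .annotations import AnnotationSet, CatalogEntry, TermCatalog
from .profiles import feature_columns

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ClassifierMetrics",
    "Partition",
    "TermClassifier",
    "PortableModel",
    "split_and_sample",
    "ks_feature_ranking",
    "cv_fscore",
    "forward_select",
    "optimize_sigma",
    "median_sigma_grid",
    "train_term_classifier",
    "train_catalog",
    "evaluate_scores",
    "select_classifiable",
    "predict_genome",
    "add_zscored_ranks",
    "consensus_retrain",
    "random_geneset_baseline",
    "validate_new_annotations",
]


@dataclass
class TrainConfig:
    """Knobs of the training pipeline, with the protocol's defaults."""

    train_fraction: float = 0.70
    cv_folds: int = 30
    sigma_grid: tuple[float, ...] | None = None  # None -> median-distance grid
    max_features: int = 100
    fpr_max: float = 0.20
    test_recall_min: float = 0.30
    train_recall_min: float = 0.40
    rng_seed: int = 0
    consensus_folds: int = 10
    consensus_required: int = 7
    C: float = 1.0
    fscore_tol: float = 1e-4
    sigma_screen_features: int = 20
    min_positives: int = 10

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        for t in (self.fpr_max, self.test_recall_min, self.train_recall_min):
            if not 0 <= t <= 1:
                raise ValueError("thresholds must be in [0, 1]")
        if self.consensus_required > self.consensus_folds:
            raise ValueError("consensus_required must be <= consensus_folds")


@dataclass
class ClassifierMetrics:
    precision: float = np.nan
    test_recall: float = np.nan
    train_recall: float = np.nan
    fpr: float = np.nan
    auroc: float = np.nan

    @property
    def recall(self) -> float:
        return self.test_recall

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.test_recall
        if not np.isfinite(p) or not np.isfinite(r) or p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)


@dataclass
class Partition:
    train_pos: list[str]
    test_pos: list[str]
    train_neg: list[str]
    test_neg: list[str]


@dataclass
class TermClassifier:
    """One trained per-term model with everything needed to reapply it."""

    term_id: str
    selected_features: list[str]
    sigma: float
    model: SVC
    metrics: ClassifierMetrics
    classifiable: bool
    partition: Partition
    seed: int
    cv_trace: list[float] = field(default_factory=list)

    def decision_scores(self, matrix: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.selected_features if f not in matrix.columns]
        if missing:
            raise KeyError(f"matrix lacks selected feature(s): {missing}")
        x = matrix[self.selected_features].to_numpy(dtype=float)
        return pd.Series(self.model.decision_function(x), index=matrix.index)

    def to_json(self, path: str | Path) -> None:
        """Portable model record (features, sigma, C, support vectors, metrics)."""
        payload = {
            "format_version": 1,
            "term_id": self.term_id,
            "selected_features": self.selected_features,
            "sigma": self.sigma,
            "C": float(self.model.C),
            "classifiable": self.classifiable,
            "seed": self.seed,
            "metrics": asdict(self.metrics),
            "support_vectors": self.model.support_vectors_.tolist(),
            "dual_coef": self.model.dual_coef_.tolist(),
            "intercept": self.model.intercept_.tolist(),
            "classes": self.model.classes_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


class PortableModel:
    """Scorer rebuilt from a :meth:`TermClassifier.to_json` record.

    Evaluates the RBF decision function directly from the stored support
    vectors and dual coefficients, so saved models do not depend on
    scikit-learn internals.
    """

    def __init__(self, payload: dict):
        if payload.get("format_version") != 1:
            raise ValueError(f"unsupported model format: {payload.get('format_version')}")
        self.term_id = payload["term_id"]
        self.selected_features = list(payload["selected_features"])
        self.sigma = float(payload["sigma"])
        self.classifiable = bool(payload["classifiable"])
        self.metrics = ClassifierMetrics(**payload["metrics"])
        self._sv = np.asarray(payload["support_vectors"], dtype=float)
        self._dual = np.asarray(payload["dual_coef"], dtype=float).ravel()
        self._b = float(payload["intercept"][0])

    @classmethod
    def from_json(cls, path: str | Path) -> "PortableModel":
        return cls(json.loads(Path(path).read_text()))

    def decision_scores(self, matrix: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.selected_features if f not in matrix.columns]
        if missing:
            raise KeyError(f"matrix lacks selected feature(s): {missing}")
        x = matrix[self.selected_features].to_numpy(dtype=float)
        gamma = _sigma_to_gamma(self.sigma)
        d2 = ((x[:, None, :] - self._sv[None, :, :]) ** 2).sum(-1)
        k = np.exp(-gamma * d2)
        return pd.Series(k @ self._dual + self._b, index=matrix.index)


def _term_rng(seed: int, term_id: str) -> np.random.Generator:
    # stable per-term stream: global seed + crc of the term id
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(term_id.encode())])


def _sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma**2)


def split_and_sample(
    term: CatalogEntry,
    universe: Sequence[str],
    cfg: TrainConfig,
    present: set[str] | None = None,
) -> Partition:
    """70/30 split of the term's positives plus balanced sampled negatives.

    Negatives are drawn uniformly without replacement from the universe minus
    the term's annotated genes, one per positive in both the training and the
    test split. Reproducible from (seed, term id).
    """
    rng = _term_rng(cfg.rng_seed, term.term_id)
    pos = sorted(term.genes if present is None else (set(term.genes) & present))
    if not pos:
        raise ValueError(f"term {term.term_id}: no positive genes available")
    candidates = sorted(set(universe) - set(term.genes))
    if len(candidates) < len(pos):
        raise ValueError(f"term {term.term_id}: not enough negatives to balance")
    pos = list(rng.permutation(pos))
    n_train = int(np.ceil(cfg.train_fraction * len(pos)))
    neg = list(rng.choice(candidates, size=len(pos), replace=False))
    return Partition(
        train_pos=pos[:n_train],
        test_pos=pos[n_train:],
        train_neg=neg[:n_train],
        test_neg=neg[n_train:],
    )


def ks_feature_ranking(
    matrix: pd.DataFrame, pos: Sequence[str], neg: Sequence[str]
) -> list[str]:
    """Features ordered by two-sample KS p-value (positives vs negatives),
    ascending; ties broken by larger KS statistic, then column order."""
    feats = feature_columns(matrix)
    xp = matrix.loc[list(pos), feats].to_numpy(dtype=float)
    xn = matrix.loc[list(neg), feats].to_numpy(dtype=float)
    keyed = []
    for j, f in enumerate(feats):
        res = stats.ks_2samp(xp[:, j], xn[:, j], method="asymp")
        keyed.append((res.pvalue, -res.statistic, j, f))
    keyed.sort()
    return [f for _, _, _, f in keyed]


def _fold_fscore(tp: int, fp: int, fn: int) -> float:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


def cv_fscore(
    x: np.ndarray, y: np.ndarray, sigma: float, cfg: TrainConfig
) -> float:
    """Mean F-score over stratified CV folds of an RBF-SVM at kernel scale
    sigma. Fold count is clipped to the smaller class size."""
    n_min = int(min(np.sum(y == 1), np.sum(y == 0)))
    folds = max(2, min(cfg.cv_folds, n_min))
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    gamma = _sigma_to_gamma(sigma)
    scores = []
    for tr, te in skf.split(x, y):
        clf = SVC(kernel="rbf", gamma=gamma, C=cfg.C)
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        tp = int(np.sum((pred == 1) & (y[te] == 1)))
        fp = int(np.sum((pred == 1) & (y[te] == 0)))
        fn = int(np.sum((pred == 0) & (y[te] == 1)))
        scores.append(_fold_fscore(tp, fp, fn))
    return float(np.mean(scores))


def median_sigma_grid(x: np.ndarray, powers: range = range(-4, 5)) -> tuple[float, ...]:
    """Default sigma grid: powers of two times the median pairwise distance."""
    if x.shape[0] > 400:
        x = x[:: int(np.ceil(x.shape[0] / 400))]
    d = pdist(x)
    d_med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return tuple(d_med * 2.0**k for k in powers)


def optimize_sigma(
    x: np.ndarray, y: np.ndarray, grid: Sequence[float], cfg: TrainConfig
) -> float:
    """Grid value maximising the CV F-score; ties go to the smallest sigma."""
    if len(grid) == 0:
        raise ValueError("sigma grid is empty")
    best_sigma, best_f = None, -np.inf
    for sigma in sorted(grid):
        f = cv_fscore(x, y, sigma, cfg)
        if f > best_f:
            best_sigma, best_f = sigma, f
    if best_sigma is None or not np.isfinite(best_f):
        raise ValueError("all sigma grid values degenerate")
    return float(best_sigma)


def forward_select(
    order: Sequence[str],
    train: pd.DataFrame,
    y: np.ndarray,
    sigma: float,
    cfg: TrainConfig,
) -> tuple[list[str], list[float]]:
    """Single sequential pass over KS-ordered features, keeping a feature only
    if it raises the mean CV F-score by more than ``fscore_tol``.

    The top-ranked feature is always retained (the model must use at least
    one feature); the accepted-feature F-score trace is non-decreasing by
    construction and at most ``max_features`` are kept.
    """
    if len(order) == 0:
        raise ValueError("empty feature order")
    if len(np.unique(y)) < 2:
        raise ValueError("training data has a single class")
    selected: list[str] = []
    trace: list[float] = []
    best = -np.inf
    for f in order:
        cand = selected + [f]
        score = cv_fscore(train[cand].to_numpy(dtype=float), y, sigma, cfg)
        if not selected or score > best + cfg.fscore_tol:
            selected = cand
            best = score
            trace.append(score)
        if len(selected) >= cfg.max_features:
            break
    return selected, trace


def evaluate_scores(
    train_pos_scores: np.ndarray,
    test_pos_scores: np.ndarray,
    test_neg_scores: np.ndarray,
) -> ClassifierMetrics:
    """Held-out metrics from decision scores (positive score => predicted).

    Recall = TP/(TP+FN) on test positives, FPR = FP/(FP+TN) on test
    negatives, training recall on training positives; AUROC over the pooled
    test scores.
    """
    if len(test_pos_scores) == 0 or len(test_neg_scores) == 0:
        log.warning("empty test class: metrics missing")
        return ClassifierMetrics()
    tp = int(np.sum(test_pos_scores > 0))
    fn = len(test_pos_scores) - tp
    fp = int(np.sum(test_neg_scores > 0))
    tn = len(test_neg_scores) - fp
    precision = tp / (tp + fp) if tp + fp else 0.0
    y = np.r_[np.ones(len(test_pos_scores)), np.zeros(len(test_neg_scores))]
    s = np.r_[test_pos_scores, test_neg_scores]
    return ClassifierMetrics(
        precision=precision,
        test_recall=tp / (tp + fn),
        train_recall=float(np.mean(train_pos_scores > 0)) if len(train_pos_scores) else np.nan,
        fpr=fp / (fp + tn),
        auroc=float(roc_auc_score(y, s)),
    )


def _passes_gate(m: ClassifierMetrics, cfg: TrainConfig) -> bool:
    return (
        np.isfinite(m.fpr) and np.isfinite(m.test_recall) and np.isfinite(m.train_recall)
        and m.fpr < cfg.fpr_max
        and m.test_recall > cfg.test_recall_min
        and m.train_recall > cfg.train_recall_min
    )


def train_term_classifier(
    term: CatalogEntry,
    matrix: pd.DataFrame,
    universe: Sequence[str] | None = None,
    cfg: TrainConfig | None = None,
) -> TermClassifier | None:
    """Full training pipeline for one term.

    split/sample -> KS feature ranking -> coarse sigma search on the
    top-ranked features -> forward selection at that sigma -> sigma re-search
    on the selected set -> refit on the training split -> held-out
    evaluation. Returns ``None`` (logged) when fewer than ``min_positives``
    annotated genes are present in the matrix.
    """
    cfg = cfg or TrainConfig()
    if universe is None:
        universe = list(matrix.index)
    present = set(matrix.index)
    pos_present = set(term.genes) & present
    missing = len(term.genes) - len(pos_present)
    if missing:
        log.info("term %s: %d annotated genes absent from matrix", term.term_id, missing)
    if len(pos_present) < cfg.min_positives:
        log.warning("term %s: only %d positives present; skipped", term.term_id, len(pos_present))
        return None
    part = split_and_sample(term, universe, cfg, present=present)
    train_genes = part.train_pos + part.train_neg
    y = np.r_[np.ones(len(part.train_pos)), np.zeros(len(part.train_neg))]
    feats = feature_columns(matrix)
    train = matrix.loc[train_genes, feats]

    order = ks_feature_ranking(matrix.loc[train_genes], part.train_pos, part.train_neg)
    screen = order[: cfg.sigma_screen_features]
    grid = cfg.sigma_grid or median_sigma_grid(train[screen].to_numpy(dtype=float))
    sigma0 = optimize_sigma(train[screen].to_numpy(dtype=float), y, grid, cfg)
    selected, trace = forward_select(order, train, y, sigma0, cfg)
    grid2 = cfg.sigma_grid or median_sigma_grid(train[selected].to_numpy(dtype=float))
    sigma = optimize_sigma(train[selected].to_numpy(dtype=float), y, grid2, cfg)

    model = SVC(kernel="rbf", gamma=_sigma_to_gamma(sigma), C=cfg.C)
    model.fit(train[selected].to_numpy(dtype=float), y)
    sc_train_pos = model.decision_function(matrix.loc[part.train_pos, selected].to_numpy(dtype=float))
    sc_test_pos = model.decision_function(matrix.loc[part.test_pos, selected].to_numpy(dtype=float))
    sc_test_neg = model.decision_function(matrix.loc[part.test_neg, selected].to_numpy(dtype=float))
    metrics = evaluate_scores(sc_train_pos, sc_test_pos, sc_test_neg)
    return TermClassifier(
        term_id=term.term_id,
        selected_features=selected,
        sigma=sigma,
        model=model,
        metrics=metrics,
        classifiable=_passes_gate(metrics, cfg),
        partition=part,
        seed=cfg.rng_seed,
        cv_trace=trace,
    )


def train_catalog(
    catalog: TermCatalog,
    matrix: pd.DataFrame,
    cfg: TrainConfig | None = None,
) -> list[TermClassifier]:
    """Train one classifier per catalog term (skipping data-poor terms)."""
    out = []
    for entry in catalog:
        clf = train_term_classifier(entry, matrix, cfg=cfg)
        if clf is not None:
            out.append(clf)
    return out


def select_classifiable(
    classifiers: Sequence[TermClassifier], cfg: TrainConfig | None = None
) -> list[TermClassifier]:
    """Classifiers clearing all three strict threshold inequalities."""
    cfg = cfg or TrainConfig()
    return [c for c in classifiers if _passes_gate(c.metrics, cfg)]


def predict_genome(clf: TermClassifier, matrix: pd.DataFrame) -> pd.DataFrame:
    """Score every gene in the matrix with one term's classifier.

    Returns a table (gene, term, decision_score, predicted, rank, off_target)
    where ``rank`` orders the predicted genes by decreasing signed distance to
    the decision boundary (phenotype strength) and is NaN otherwise.
    """
    scores = clf.decision_scores(matrix)
    df = pd.DataFrame(
        {
            "gene": scores.index,
            "term": clf.term_id,
            "decision_score": scores.to_numpy(),
        }
    )
    df["predicted"] = df["decision_score"] > 0
    df["rank"] = np.nan
    pred_idx = df.index[df["predicted"]]
    order = df.loc[pred_idx, "decision_score"].sort_values(ascending=False).index
    df.loc[order, "rank"] = np.arange(1, len(order) + 1, dtype=float)
    df["off_target"] = False
    return df


def add_zscored_ranks(predictions: pd.DataFrame) -> pd.DataFrame:
    """Add a ``zscored_rank`` column: each gene's decision scores z-scored
    across terms, for cross-term heatmaps of relative phenotype strength."""
    df = predictions.copy()
    grp = df.groupby("gene")["decision_score"]
    mu, sd = grp.transform("mean"), grp.transform("std")
    z = (df["decision_score"] - mu) / sd
    df["zscored_rank"] = z.where(sd > 0, 0.0)
    return df


def consensus_retrain(
    clf: TermClassifier,
    term: CatalogEntry,
    matrix: pd.DataFrame,
    universe: Sequence[str] | None = None,
    cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Stringent predictions: refit on CV partitions of all annotated genes
    with the selected features and sigma fixed, and keep genes predicted
    positive in at least ``consensus_required`` of ``consensus_folds`` refits.
    """
    cfg = cfg or TrainConfig()
    if universe is None:
        universe = list(matrix.index)
    rng = _term_rng(cfg.rng_seed + 1, term.term_id)
    pos = sorted(set(term.genes) & set(matrix.index))
    candidates = sorted(set(universe) - set(term.genes))
    votes = pd.Series(0, index=matrix.index, dtype=int)
    kf = KFold(n_splits=cfg.consensus_folds, shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    for tr, _ in kf.split(pos):
        tr_pos = [pos[i] for i in tr]
        tr_neg = list(rng.choice(candidates, size=len(tr_pos), replace=False))
        x = matrix.loc[tr_pos + tr_neg, clf.selected_features].to_numpy(dtype=float)
        y = np.r_[np.ones(len(tr_pos)), np.zeros(len(tr_neg))]
        model = SVC(kernel="rbf", gamma=_sigma_to_gamma(clf.sigma), C=cfg.C)
        model.fit(x, y)
        scores = model.decision_function(
            matrix[clf.selected_features].to_numpy(dtype=float))
        votes[scores > 0] += 1
    out = pd.DataFrame({"gene": votes.index, "term": clf.term_id,
                        "votes": votes.to_numpy()})
    out["consensus"] = out["votes"] >= cfg.consensus_required
    return out


def random_geneset_baseline(
    matrix: pd.DataFrame,
    universe: Sequence[str] | None = None,
    cfg: TrainConfig | None = None,
    n_sets: int = 100,
    set_size: int = 200,
) -> pd.DataFrame:
    """Train the full pipeline on random gene sets (the null control).

    Returns per-set held-out metrics and the classifiable flag; the fraction
    passing the gate estimates the false-discovery behaviour of the
    thresholds.
    """
    cfg = cfg or TrainConfig()
    if universe is None:
        universe = list(matrix.index)
    rng = np.random.default_rng(cfg.rng_seed)
    rows = []
    for i in range(n_sets):
        genes = rng.choice(sorted(universe), size=set_size, replace=False)
        entry = CatalogEntry(f"random_{i:03d}", frozenset(genes))
        clf = train_term_classifier(entry, matrix, universe, cfg)
        m = clf.metrics
        rows.append(
            {
                "set": entry.term_id,
                "precision": m.precision,
                "test_recall": m.test_recall,
                "train_recall": m.train_recall,
                "fpr": m.fpr,
                "auroc": m.auroc,
                "fscore": m.fscore,
                "classifiable": clf.classifiable,
                "n_features": len(clf.selected_features),
            }
        )
    return pd.DataFrame(rows)


def validate_new_annotations(
    predictions: pd.DataFrame,
    old: AnnotationSet,
    new_diff: AnnotationSet,
) -> pd.DataFrame:
    """Score predictions against annotations added after the training release.

    For each term, genes already annotated in *old* are excluded; the 2x2
    table {predicted, not} x {newly annotated, not} over the remaining genes
    gives a right-tail Fisher p-value, alongside the fraction of the new
    annotations that were predicted.
    """
    overlap = new_diff.pairs() & old.pairs()
    if overlap:
        raise ValueError("new_diff must be disjoint from old annotations")
    old_t2g = old.term_to_genes
    new_t2g = new_diff.term_to_genes
    rows = []
    for term, sub in predictions.groupby("term"):
        new_genes = new_t2g.get(term, set())
        eligible = set(sub["gene"]) - old_t2g.get(term, set())
        new_genes = new_genes & eligible
        if not new_genes:
            log.info("term %s: no new annotations among scored genes; skipped", term)
            continue
        pred = set(sub.loc[sub["predicted"], "gene"]) & eligible
        a = len(pred & new_genes)
        b = len(pred - new_genes)
        c = len(new_genes - pred)
        d = len(eligible) - a - b - c
        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        rows.append({"term": term, "n_new": len(new_genes),
                     "fraction_predicted": a / len(new_genes), "fisher_p": p})
    return pd.DataFrame(rows)
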