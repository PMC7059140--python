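"""Post-processing of raw predictions.

Turns per-term prediction tables into curated outputs: flagging predictions
likely driven by shared siRNA seed sequences (off-target effects), building
the network of classifiable terms weighted by prediction overlap, testing
whether predictions concentrate on interaction-network first neighbours of
the annotated genes, embedding a term's subphenotypic feature space, and
summarising which feature categories each classifier relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "extract_seed",
    "read_seed_map",
    "seed_enrichment_filter",
    "build_term_network",
    "write_sif",
    "ppi_first_neighbor_enrichment",
    "subphenotypic_embedding",
    "EmbeddingResult",
    "feature_category_summary",
]

_RNA = set("ACGU")


def extract_seed(sequence: str) -> str:
    """Seed of an siRNA guide strand: positions 2-7 (1-based, inclusive),
    normalised to the RNA alphabet."""
    seq = sequence.strip().upper().replace("T", "U")
    if len(seq) < 7:
        raise ValueError(f"siRNA sequence shorter than 7 nt: {sequence!r}")
    if set(seq) - _RNA:
        raise ValueError(f"invalid characters in siRNA sequence: {sequence!r}")
    return seq[1:7]


def read_seed_map(path: str | Path) -> dict[str, list[str]]:
    """TSV of (gene, sirna_sequence) or (gene, seed); seeds are derived from
    full sequences, 6-mers are taken as-is."""
    seeds: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, seq = line.split("\t")[:2]
            if i == 0 and gene.lower() == "gene":
                continue
            seq = seq.strip().upper().replace("T", "U")
            seeds.setdefault(gene, []).append(seq if len(seq) == 6 else extract_seed(seq))
    return seeds


def seed_enrichment_filter(
    predictions: pd.DataFrame,
    seeds: Mapping[str, Sequence[str]],
    alpha: float = 0.01,
    min_carriers: int = 4,
    return_tests: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Flag predictions explainable by a shared siRNA seed.

    For every term and every seed carried by at least *min_carriers* genes,
    a right-tail Fisher test asks whether seed carriers are over-represented
    among the term's predicted genes (2x2 over the scored gene universe).
    When p < alpha, all predictions linking that seed's carriers to the term
    are marked ``off_target``; flagged rows are kept in the output. With
    ``return_tests`` the per-(term, seed) contingency tests are returned too.
    """
    df = predictions.copy()
    if "off_target" not in df.columns:
        df["off_target"] = False
    universe = sorted(set(df["gene"]))
    no_seed = [g for g in universe if g not in seeds]
    if no_seed:
        log.warning("seed filter: %d genes without seed records are unflaggable", len(no_seed))
    carriers: dict[str, set[str]] = {}
    for g in universe:
        for s in seeds.get(g, ()):
            carriers.setdefault(s, set()).add(g)
    eligible = {s: gs for s, gs in carriers.items() if len(gs) >= min_carriers}
    n_universe = len(universe)
    tests = []
    for term, sub in df.groupby("term"):
        predicted = set(sub.loc[sub["predicted"], "gene"])
        n_pred = len(predicted)
        if n_pred == 0:
            continue
        for seed, genes_with_seed in eligible.items():
            a = len(predicted & genes_with_seed)
            b = n_pred - a
            c = len(genes_with_seed) - a
            d = n_universe - a - b - c
            if a == 0:
                tests.append({"term": term, "seed": seed, "n_overlap": 0,
                              "p": 1.0, "flagged": False})
                continue
            p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            flagged = p < alpha
            tests.append({"term": term, "seed": seed, "n_overlap": a,
                          "p": float(p), "flagged": flagged})
            if flagged:
                hit = df["term"].eq(term) & df["gene"].isin(genes_with_seed) & df["predicted"]
                df.loc[hit, "off_target"] = True
    if return_tests:
        return df, pd.DataFrame(tests)
    return df


def _overlap(a: set, b: set, mode: str) -> float:
    union = a | b
    if not union:
        return 0.0
    if mode == "jaccard":
        return len(a & b) / len(union)
    if mode == "overlap":
        m = min(len(a), len(b))
        return len(a & b) / m if m else 0.0
    raise ValueError(f"unknown overlap mode {mode!r}")


def build_term_network(
    prediction_sets: Mapping[str, Iterable[str]],
    threshold: float = 0.70,
    overlap: str = "jaccard",
) -> nx.Graph:
    """Network of terms weighted by predicted-gene-list overlap.

    Term pairs overlapping above *threshold* get an edge (origin
    ``threshold``); each remaining edgeless term is then attached to its
    maximum-overlap partner (origin ``attachment``, ties to the
    lexicographically smaller id) until no term is isolated.
    """
    sets = {t: set(gs) for t, gs in prediction_sets.items()}
    terms = sorted(sets)
    if len(terms) < 2:
        raise ValueError("term network needs at least 2 terms")
    g = nx.Graph()
    g.add_nodes_from(terms)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            w = _overlap(sets[a], sets[b], overlap)
            if w > threshold:
                g.add_edge(a, b, weight=w, origin="threshold")
    for t in terms:
        if g.degree(t) > 0:
            continue
        if not sets[t]:
            log.warning("term %s has an empty prediction set; attached with weight 0", t)
        # ties resolved toward the lexicographically smaller partner
        best_w = max(_overlap(sets[t], sets[o], overlap) for o in terms if o != t)
        cands = [o for o in terms if o != t and _overlap(sets[t], sets[o], overlap) == best_w]
        best = min(cands)
        g.add_edge(t, best, weight=best_w, origin="attachment")
    return g


def write_sif(g: nx.Graph, path: str | Path, relation: str = "overlap") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(g.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


def ppi_first_neighbor_enrichment(
    predicted: Iterable[str],
    annotated: Iterable[str],
    net: nx.Graph,
    universe: Iterable[str],
) -> tuple[dict[str, int], float]:
    """Are a term's predicted genes enriched for interaction-network first
    neighbours of its annotated genes?

    First neighbours are genes adjacent to any annotated gene, excluding the
    annotated genes themselves. Returns the 2x2 counts and the upper-tail
    hypergeometric p-value of the predicted/neighbour overlap.
    """
    universe = set(universe)
    annotated = set(annotated)
    if not annotated <= universe:
        raise ValueError("annotated genes must be a subset of the universe")
    predicted = set(predicted) & universe
    neighbours = set()
    for a in annotated:
        if a in net:
            neighbours |= set(net.neighbors(a))
    neighbours = (neighbours - annotated) & universe
    counts = {
        "n_universe": len(universe),
        "n_predicted": len(predicted),
        "n_neighbours": len(neighbours),
        "n_overlap": len(predicted & neighbours),
    }
    if not neighbours:
        log.info("empty first-neighbour set; p = 1")
        return counts, 1.0
    p = float(
        stats.hypergeom.sf(
            counts["n_overlap"] - 1, len(universe), len(neighbours), len(predicted)
        )
    )
    return counts, p


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # gene x (x, y)
    weights: pd.Series  # per selected feature
    agreement: float  # logistic vs classifier label agreement


def subphenotypic_embedding(
    clf,
    predictions: pd.DataFrame,
    matrix: pd.DataFrame,
    seed: int = 0,
    perplexity: float = 30.0,
) -> EmbeddingResult:
    """2-D t-SNE of a term's subphenotypic space.

    A logistic regression is fitted to reproduce the classifier's predicted
    labels from its selected features; the embedding runs on those feature
    columns scaled by the absolute logistic weights, so directions the
    decision boundary uses dominate the map.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.manifold import TSNE

    feats = clf.selected_features
    sub = predictions[predictions["term"] == clf.term_id].set_index("gene")
    genes = [g for g in matrix.index if g in sub.index]
    x = matrix.loc[genes, feats].to_numpy(dtype=float)
    y = sub.loc[genes, "predicted"].to_numpy(dtype=bool)
    lr = LogisticRegression(max_iter=2000, random_state=seed)
    lr.fit(x, y)
    agreement = float(np.mean(lr.predict(x) == y))
    w = np.abs(lr.coef_.ravel())
    if not np.any(w > 0):
        raise ValueError("all logistic feature weights are zero")
    xw = x * w
    perp = min(perplexity, max(2.0, (len(genes) - 1) / 3.0))
    ts = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca")
    coords = ts.fit_transform(xw)
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=genes, columns=["x", "y"]),
        weights=pd.Series(w, index=feats),
        agreement=agreement,
    )


def feature_category_summary(
    classifiers: Sequence,
    category_map: Mapping[str, str],
    matrix: pd.DataFrame,
    control_means: pd.Series,
    predictions: pd.DataFrame,
) -> pd.DataFrame:
    """Signed, per-term-scaled counts of selected features per category.

    Each selected feature contributes +1 to its category when the mean over
    the term's predicted-positive genes exceeds the control mean, -1
    otherwise; per term, counts are scaled so the largest magnitude is 1.
    """
    terms = []
    rows = []
    for clf in classifiers:
        pred_genes = predictions.loc[
            (predictions["term"] == clf.term_id) & predictions["predicted"], "gene"
        ]
        pred_genes = [g for g in pred_genes if g in matrix.index]
        tally: dict[str, float] = {}
        for f in clf.selected_features:
            cat = category_map.get(f)
            if cat is None:
                log.warning("feature %s has no category tag; using 'other'", f)
                cat = "other"
            mean_pred = float(matrix.loc[pred_genes, f].mean()) if pred_genes else np.nan
            sign = 1.0 if mean_pred > float(control_means.get(f, 0.0)) else -1.0
            tally[cat] = tally.get(cat, 0.0) + sign
        peak = max((abs(v) for v in tally.values()), default=0.0)
        if peak > 0:
            tally = {c: v / peak for c, v in tally.items()}
        terms.append(clf.term_id)
        rows.append(tally)
    return pd.DataFrame(rows, index=terms).fillna(0.0)
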