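"""Synthetic perturbation screens with known ground truth.

Generates gene x feature profile matrices with planted term-specific
signatures, single-cell tables, siRNA seed maps with a planted off-target
seed, and modular interaction networks, so every pipeline stage can be
exercised and parameter recovery measured without external screen data.
All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .annotations import AnnotationSet

__all__ = [
    "TermSpec",
    "ScreenSpec",
    "GroundTruth",
    "generate_screen",
    "WellSpec",
    "generate_single_cell",
    "generate_seed_map",
    "generate_ppi",
]


@dataclass
class TermSpec:
    term_id: str
    n_positive: int = 150
    n_informative: int = 10
    effect_size: float = 1.0  # shift of positives on informative features, in SD units
    n_subphenotypes: int = 1  # >1 splits positives over disjoint feature subsets

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class ScreenSpec:
    """Defaults give the standard test fixture: a 2,000-gene x 200-feature
    screen with planted 100-200-gene terms, 10 informative features each and
    a 1.0 SD shift, light missingness, and a lognormal cell-count model."""

    n_genes: int = 2000
    n_features: int = 200
    terms: tuple[TermSpec, ...] = ()
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    n_plates: int = 4
    tcn_log_mean: float = np.log(6000.0)
    tcn_log_sd: float = 0.35
    confound_features: int = 0  # features made linear in TCN
    confound_coef: float = 2.0
    heavy_tails: bool = False  # Student-t (df=3) background instead of Gaussian

    def __post_init__(self):
        for t in self.terms:
            if t.n_positive > self.n_genes:
                raise ValueError(f"{t.term_id}: n_positive > n_genes")
            if t.n_informative > self.n_features:
                raise ValueError(f"{t.term_id}: n_informative > n_features")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    positives: dict[str, list[str]] = field(default_factory=dict)
    informative: dict[str, list[str]] = field(default_factory=dict)
    confounded: list[str] = field(default_factory=list)
    seeds: dict[str, list[str]] = field(default_factory=dict)
    planted_seed: str | None = None
    planted_carriers: list[str] = field(default_factory=list)


def generate_screen(
    spec: ScreenSpec, seed: int = 0
) -> tuple[pd.DataFrame, AnnotationSet, GroundTruth]:
    """Profile matrix + annotations + ground truth for a planted-signal screen.

    Background values are Normal(0, noise_sd^2) (or t_3, rescaled, when
    ``heavy_tails``); each term's positives are shifted by ``effect_size`` on
    its informative features; missing values are injected completely at
    random; TCN is lognormal and confounded features are a linear function of
    standardised TCN plus noise.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    feats = [f"f{j:04d}" for j in range(spec.n_features)]
    if spec.heavy_tails:
        x = rng.standard_t(3, size=(spec.n_genes, spec.n_features))
        x *= spec.noise_sd / np.sqrt(3.0)  # variance of t_3 is 3
    else:
        x = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_features))

    truth = GroundTruth()
    pairs = []
    for t in spec.terms:
        pos_idx = rng.choice(spec.n_genes, size=t.n_positive, replace=False)
        feat_idx = rng.choice(spec.n_features, size=t.n_informative, replace=False)
        groups = np.array_split(pos_idx, t.n_subphenotypes)
        feat_groups = np.array_split(feat_idx, t.n_subphenotypes)
        for g_idx, f_idx in zip(groups, feat_groups):
            shift_feats = f_idx if t.n_subphenotypes > 1 else feat_idx
            x[np.ix_(g_idx, shift_feats)] += t.effect_size * spec.noise_sd
        truth.positives[t.term_id] = [genes[i] for i in sorted(pos_idx)]
        truth.informative[t.term_id] = [feats[j] for j in sorted(feat_idx)]
        pairs += [(genes[i], t.term_id) for i in pos_idx]

    tcn = rng.lognormal(spec.tcn_log_mean, spec.tcn_log_sd, size=spec.n_genes)
    if spec.confound_features:
        cf = rng.choice(spec.n_features, size=spec.confound_features, replace=False)
        tcn_z = (tcn - tcn.mean()) / tcn.std()
        for j in cf:
            x[:, j] = spec.confound_coef * tcn_z + rng.normal(0, 0.1, spec.n_genes)
        truth.confounded = [feats[j] for j in sorted(cf)]

    if spec.missing_rate > 0:
        mask = rng.random(x.shape) < spec.missing_rate
        x[mask] = np.nan

    m = pd.DataFrame(x, index=genes, columns=feats)
    m.insert(0, "tcn", tcn)
    m.insert(0, "plate_id", [f"plate{i % spec.n_plates}" for i in range(spec.n_genes)])
    m.index.name = "gene"
    return m, AnnotationSet.from_pairs(pairs, "synthetic"), truth


@dataclass
class WellSpec:
    well_id: str
    gene_label: str
    plate_id: str = "plate0"
    shift: float = 0.0  # location shift of all features vs control
    bimodal_fraction: float = 0.0  # fraction of cells drawn from a +3 SD mode


def generate_single_cell(
    wells: list[WellSpec],
    n_features: int = 5,
    cells_per_well: int = 200,
    state_rates: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-cell table: one row per cell with well/gene/plate labels,
    numeric features drawn from shifted or bimodal-mixture distributions,
    and Bernoulli state labels."""
    if not any(w.gene_label in ("scrambled", "empty") for w in wells):
        raise ValueError("at least one control well (scrambled/empty) is required")
    rng = np.random.default_rng(seed)
    state_rates = state_rates or {}
    frames = []
    for w in wells:
        n = rng.poisson(cells_per_well)
        if n == 0:
            raise ValueError(f"well {w.well_id}: zero cells drawn")
        x = rng.normal(w.shift, 1.0, size=(n, n_features))
        if w.bimodal_fraction > 0:
            hi = rng.random(n) < w.bimodal_fraction
            x[hi] += 3.0
        df = pd.DataFrame(x, columns=[f"sc_f{j}" for j in range(n_features)])
        df.insert(0, "plate_id", w.plate_id)
        df.insert(0, "gene_label", w.gene_label)
        df.insert(0, "well_id", w.well_id)
        for s, rate in state_rates.items():
            df[s] = rng.random(n) < rate
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


_BASES = np.array(list("ACGU"))


def generate_seed_map(
    genes: list[str],
    n_seeds: int = 500,
    pool_size: int = 4,
    planted: tuple[str, list[str]] | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[str]], GroundTruth]:
    """siRNA seed assignment: each gene carries ``pool_size`` seeds drawn
    near-uniformly from a random 6-mer pool; an optional planted seed is
    given to a set of carrier genes (replacing one of their background
    seeds)."""
    rng = np.random.default_rng(seed)
    pool = []
    seen = set()
    while len(pool) < n_seeds:
        s = "".join(rng.choice(_BASES, size=6))
        if s not in seen:
            seen.add(s)
            pool.append(s)
    seeds = {g: list(rng.choice(pool, size=pool_size)) for g in genes}
    truth = GroundTruth(seeds=seeds)
    if planted is not None:
        planted_seed, carriers = planted
        unknown = set(carriers) - set(genes)
        if unknown:
            raise ValueError(f"planted carriers not in gene list: {sorted(unknown)}")
        for g in carriers:
            seeds[g][0] = planted_seed
        truth.planted_seed = planted_seed
        truth.planted_carriers = list(carriers)
    return seeds, truth


def generate_ppi(
    genes: list[str],
    modules: dict[str, list[str]] | None = None,
    p_within: float = 0.3,
    p_background: float = 0.005,
    seed: int = 0,
) -> nx.Graph:
    """Stochastic-block-model interaction network: gene pairs sharing a
    module connect with ``p_within``, all others with ``p_background``.
    Undirected, no self-loops."""
    for p in (p_within, p_background):
        if not 0 <= p <= 1:
            raise ValueError("edge probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    modules = modules or {}
    member: dict[str, set[str]] = {g: set() for g in genes}
    for mod, mgenes in modules.items():
        for g in mgenes:
            member[g].add(mod)
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    u = rng.random((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_within if member[genes[i]] & member[genes[j]] else p_background
            if u[i, j] < p:
                g.add_edge(genes[i], genes[j])
    return g
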