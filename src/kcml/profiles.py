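"""Per-gene phenotypic profile construction.

Single-cell feature tables are aggregated per well into a wide profile row
(location, spread, distribution-shape and distribution-distance statistics),
then the profile matrix is cleaned, imputed, plate-normalised, averaged per
gene, viability-filtered and corrected for the total-cell-number confound.

Profile matrices are plain :class:`pandas.DataFrame` objects. The columns
named in :data:`META_COLS` (``well_id``, ``gene_label``, ``plate_id``,
``tcn``) are reserved metadata; everything else is a numeric feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

META_COLS = ("well_id", "gene_label", "plate_id", "tcn")

__all__ = [
    "META_COLS",
    "feature_columns",
    "AggregationSpec",
    "rank_sum_scaled",
    "ks_distance_scaled",
    "bimodality_coefficient",
    "scaling_factor",
    "aggregate_well",
    "aggregate_screen",
    "state_fractions",
    "clean_matrix",
    "impute_knn_features",
    "plate_zscore",
    "average_replicates",
    "viability_filter",
    "cell_number_correction",
    "pca_reduce",
]


def feature_columns(m: pd.DataFrame) -> list[str]:
    """Columns of *m* that are features (everything not reserved metadata)."""
    return [c for c in m.columns if c not in META_COLS]


def scaling_factor(n1: int, n2: int) -> float:
    """sf = n1*n2 / (n1 + n2), the sample-size correction applied to the
    rank-sum and KS distances between perturbed and control populations."""
    return n1 * n2 / (n1 + n2)


def rank_sum_scaled(perturbed, control, sf_mode: str = "linear") -> float:
    """Scaled Mann-Whitney rank-sum statistic of perturbed vs control cells.

    All values are pooled and midranked; with R the rank sum of the perturbed
    sample, U = R - n1(n1+1)/2 and the result is U*sf. ``sf_mode='sqrt'``
    uses sqrt(sf) instead (the classical normalisation).
    """
    perturbed = np.asarray(perturbed, dtype=float)
    control = np.asarray(control, dtype=float)
    if perturbed.size == 0 or control.size == 0:
        log.debug("rank_sum_scaled: empty sample -> missing")
        return np.nan
    n1, n2 = perturbed.size, control.size
    ranks = stats.rankdata(np.concatenate([perturbed, control]))
    r = ranks[:n1].sum()
    u = r - n1 * (n1 + 1) / 2
    sf = scaling_factor(n1, n2)
    if sf_mode == "sqrt":
        sf = np.sqrt(sf)
    return float(u * sf)


def ks_distance_scaled(perturbed, control, sf_mode: str = "linear") -> float:
    """Scaled two-sample Kolmogorov-Smirnov distance, D*sf.

    D is the maximum gap between the empirical CDFs of the perturbed and
    control populations.
    """
    perturbed = np.asarray(perturbed, dtype=float)
    control = np.asarray(control, dtype=float)
    if perturbed.size == 0 or control.size == 0:
        return np.nan
    d = stats.ks_2samp(perturbed, control, method="asymp").statistic
    sf = scaling_factor(perturbed.size, control.size)
    if sf_mode == "sqrt":
        sf = np.sqrt(sf)
    return float(d * sf)


def bimodality_coefficient(values) -> float:
    """Sarle's bimodality coefficient b = (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3))).

    g1 is the sample skewness and g2 the excess kurtosis. Around 1/3 for a
    normal distribution, 5/9 for a uniform, approaching 1 for a well-separated
    two-point mixture. Missing for n < 4 or zero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4 or np.std(x) == 0:
        return np.nan
    g1 = stats.skew(x)
    g2 = stats.kurtosis(x)  # excess
    return float((g1**2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


@dataclass
class AggregationSpec:
    """Which per-well statistics to compute for every raw single-cell feature."""

    statistics: tuple[str, ...] = (
        "mean", "sd", "quantiles", "iqr", "range",
        "skewness", "kurtosis", "bimodality", "ks", "ranksum",
    )
    quantiles: tuple[float, ...] = (0.01, 0.05, 0.25, 0.50, 0.75, 0.95, 0.99)
    sf_mode: str = "linear"

    CONTROL_DEPENDENT = frozenset({"ks", "ranksum"})

    def __post_init__(self):
        if not self.statistics:
            raise ValueError("at least one statistic must be enabled")


def _single_sample_stats(x: np.ndarray, spec: AggregationSpec) -> dict[str, float]:
    out: dict[str, float] = {}
    n = x.size
    for s in spec.statistics:
        if s == "mean":
            out["mean"] = float(np.mean(x)) if n else np.nan
        elif s == "sd":
            out["sd"] = float(np.std(x, ddof=1)) if n > 1 else np.nan
        elif s == "quantiles":
            for q in spec.quantiles:
                out[f"q{int(round(q * 100)):02d}"] = float(np.quantile(x, q)) if n else np.nan
        elif s == "iqr":
            out["iqr"] = float(np.quantile(x, 0.75) - np.quantile(x, 0.25)) if n else np.nan
        elif s == "range":
            out["range"] = float(np.max(x) - np.min(x)) if n else np.nan
        elif s == "skewness":
            out["skewness"] = float(stats.skew(x)) if n > 2 and np.std(x) > 0 else np.nan
        elif s == "kurtosis":
            out["kurtosis"] = float(stats.kurtosis(x)) if n > 3 and np.std(x) > 0 else np.nan
        elif s == "bimodality":
            out["bimodality"] = bimodality_coefficient(x)
    return out


def aggregate_well(
    cells: pd.DataFrame,
    control_cells: pd.DataFrame | None,
    spec: AggregationSpec | None = None,
    state_labels: tuple[str, ...] = (),
) -> pd.Series:
    """One profile row for a well: every raw feature x every enabled statistic,
    plus the total cell number (``tcn``) and optional per-state fractions.

    Distance statistics (scaled KS and rank-sum) compare the well's cells to
    the pooled control cells and require ``control_cells``.
    """
    if spec is None:
        spec = AggregationSpec()
    if len(cells) == 0:
        raise ValueError("aggregate_well: well has no cells")
    needs_control = set(spec.statistics) & AggregationSpec.CONTROL_DEPENDENT
    if needs_control and (control_cells is None or len(control_cells) == 0):
        raise ValueError(f"statistics {sorted(needs_control)} require a control sample")

    feats = [c for c in cells.columns if c not in META_COLS and c not in state_labels]
    out: dict[str, float] = {}
    for f in feats:
        x = cells[f].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        for stat, val in _single_sample_stats(x, spec).items():
            out[f"{f}__{stat}"] = val
        if "ks" in spec.statistics:
            out[f"{f}__ks"] = ks_distance_scaled(x, control_cells[f].dropna(), spec.sf_mode)
        if "ranksum" in spec.statistics:
            out[f"{f}__ranksum"] = rank_sum_scaled(x, control_cells[f].dropna(), spec.sf_mode)
    if state_labels:
        out.update(state_fractions(cells, state_labels).to_dict())
    out["tcn"] = float(len(cells))
    return pd.Series(out)


def aggregate_screen(
    cells: pd.DataFrame,
    control_label: str = "scrambled",
    spec: AggregationSpec | None = None,
    state_labels: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Aggregate a whole single-cell table well by well.

    Control cells are pooled over all wells whose ``gene_label`` equals
    *control_label*. Returns one row per well with ``well_id``, ``gene_label``
    and ``plate_id`` carried over.
    """
    controls = cells[cells["gene_label"] == control_label]
    rows = []
    for well, wcells in cells.groupby("well_id", sort=True):
        row = aggregate_well(wcells, controls, spec, state_labels)
        row["well_id"] = well
        row["gene_label"] = wcells["gene_label"].iloc[0]
        if "plate_id" in wcells:
            row["plate_id"] = wcells["plate_id"].iloc[0]
        rows.append(row)
    df = pd.DataFrame(rows)
    meta = [c for c in META_COLS if c in df.columns]
    return df[meta + [c for c in df.columns if c not in meta]]


def state_fractions(cells: pd.DataFrame, state_labels: tuple[str, ...]) -> pd.Series:
    """Fraction of cells in each (non-exclusive) state, normalised by the
    well's cell count."""
    n = len(cells)
    if n == 0:
        return pd.Series({f"frac_{s}": np.nan for s in state_labels})
    return pd.Series(
        {f"frac_{s}": float(cells[s].astype(bool).sum()) / n for s in state_labels}
    )


def clean_matrix(m: pd.DataFrame, max_missing: float = 0.30) -> pd.DataFrame:
    """Drop samples, then features, with more than *max_missing* missing data."""
    feats = feature_columns(m)
    row_frac = m[feats].isna().mean(axis=1)
    dropped_rows = m.index[row_frac > max_missing]
    if len(dropped_rows):
        log.info("clean_matrix: dropping %d rows > %.0f%% missing", len(dropped_rows), 100 * max_missing)
    m = m.drop(index=dropped_rows)
    col_frac = m[feats].isna().mean(axis=0)
    dropped_cols = col_frac.index[col_frac > max_missing]
    if len(dropped_cols):
        log.info("clean_matrix: dropping %d features > %.0f%% missing", len(dropped_cols), 100 * max_missing)
    m = m.drop(columns=dropped_cols)
    if len(m) == 0 or not feature_columns(m):
        raise ValueError("clean_matrix removed every row or every feature")
    return m


def impute_knn_features(m: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing values with the inverse-distance-weighted mean of the k
    nearest *features* (columns), by Euclidean distance over rows where both
    columns are observed.

    A column with no observed overlap with any other falls back to its own
    column mean (logged).
    """
    m = m.copy()
    feats = feature_columns(m)
    x = m[feats].to_numpy(dtype=float)
    n_rows, n_cols = x.shape
    obs = np.isfinite(x)
    # pairwise column distances over shared observed rows, normalised per pair
    dist = np.full((n_cols, n_cols), np.inf)
    for a in range(n_cols):
        for b in range(a + 1, n_cols):
            shared = obs[:, a] & obs[:, b]
            ns = shared.sum()
            if ns == 0:
                continue
            d = np.sqrt(np.sum((x[shared, a] - x[shared, b]) ** 2) / ns)
            dist[a, b] = dist[b, a] = d
    col_means = np.nanmean(np.where(obs, x, np.nan), axis=0)
    eps = 1e-12
    filled = x.copy()
    for j in range(n_cols):
        missing_rows = np.where(~obs[:, j])[0]
        if missing_rows.size == 0:
            continue
        order = np.argsort(dist[j], kind="stable")
        neighbours = [l for l in order if np.isfinite(dist[j, l])][:k]
        if not neighbours:
            log.warning("impute: feature %s has no overlapping neighbour; column-mean fallback", feats[j])
            filled[missing_rows, j] = col_means[j]
            continue
        w_all = 1.0 / (dist[j, neighbours] + eps)
        for i in missing_rows:
            avail = [idx for idx, l in enumerate(neighbours) if obs[i, l]]
            if not avail:
                filled[i, j] = col_means[j]
                continue
            w = w_all[avail]
            vals = x[i, [neighbours[idx] for idx in avail]]
            filled[i, j] = np.sum(w * vals) / np.sum(w)
    m[feats] = filled
    return m


def plate_zscore(m: pd.DataFrame) -> pd.DataFrame:
    """Z-score every feature within its plate (plate mean 0, SD 1).

    Zero-variance features within a plate become 0; single-row plates become
    all zeros (warned).
    """
    if "plate_id" not in m.columns:
        raise ValueError("plate_zscore requires a plate_id column")
    m = m.copy()
    feats = feature_columns(m)
    m[feats] = m[feats].astype(float)
    for plate, idx in m.groupby("plate_id").groups.items():
        sub = m.loc[idx, feats]
        if len(idx) == 1:
            log.warning("plate %s has a single row; z-scores set to 0", plate)
            m.loc[idx, feats] = 0.0
            continue
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        z = (sub - mu).div(sd.replace(0.0, np.nan), axis=1)
        m.loc[idx, feats] = z.fillna(0.0).where(sub.notna(), np.nan)
    return m


def average_replicates(m: pd.DataFrame, by: str = "gene_label") -> pd.DataFrame:
    """One row per gene: arithmetic mean of its replicate wells (tcn included)."""
    feats = feature_columns(m)
    cols = feats + (["tcn"] if "tcn" in m.columns else [])
    cols = list(dict.fromkeys(cols))
    out = m.groupby(by, sort=True)[cols].mean()
    out.index.name = by
    return out.reset_index()


def viability_filter(m: pd.DataFrame, min_cells: int = 625) -> pd.DataFrame:
    """Remove rows whose total cell number is below *min_cells* (strict).

    Strong viability phenotypes otherwise dominate every classifier.
    """
    if "tcn" not in m.columns:
        raise ValueError("viability_filter requires a tcn column")
    keep = m["tcn"] >= min_cells
    if (~keep).any():
        log.info("viability_filter: removing %d rows with tcn < %d", int((~keep).sum()), min_cells)
    return m.loc[keep]


def cell_number_correction(
    m: pd.DataFrame, n_bins: int = 32, min_per_bin: int = 100
) -> tuple[pd.DataFrame, np.ndarray]:
    """Remove the cell-number confound by equal-frequency TCN binning and
    per-bin z-scoring of every feature.

    Rows are split into *n_bins* equal-frequency bins of ``tcn``; bins smaller
    than *min_per_bin* are merged rightward (the last bin merges left) and
    each feature is z-scored within its bin. Returns the corrected matrix and
    the bin assignment per row.
    """
    if "tcn" not in m.columns:
        raise ValueError("cell_number_correction requires a tcn column")
    m = m.copy()
    n = len(m)
    if n < min_per_bin:
        log.warning("cell_number_correction: %d rows < min_per_bin; single global bin", n)
        bins = np.zeros(n, dtype=int)
    else:
        order = np.argsort(m["tcn"].to_numpy(), kind="stable")
        bins = np.empty(n, dtype=int)
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            bins[chunk] = b
        # merge undersized bins into their right neighbour
        counts = np.bincount(bins, minlength=n_bins)
        mapping = np.arange(n_bins)
        b = 0
        while b < n_bins - 1:
            if counts[b] < min_per_bin and counts[b] > 0 or counts[b] == 0:
                counts[b + 1] += counts[b]
                counts[b] = 0
                mapping[mapping == b] = b + 1
            b += 1
        last = n_bins - 1
        if 0 < counts[last] < min_per_bin:
            prev = max((bb for bb in range(last) if counts[bb] > 0), default=None)
            if prev is not None:
                counts[prev] += counts[last]
                counts[last] = 0
                mapping[mapping == last] = prev
        bins = mapping[bins]
        # relabel to consecutive ids
        _, bins = np.unique(bins, return_inverse=True)
    feats = feature_columns(m)
    m[feats] = m[feats].astype(float)
    for b in np.unique(bins):
        idx = m.index[bins == b]
        sub = m.loc[idx, feats]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        z = (sub - mu).div(sd.replace(0.0, np.nan), axis=1)
        m.loc[idx, feats] = z.fillna(0.0)
    return m, bins


def pca_reduce(m: pd.DataFrame, n_components: int) -> pd.DataFrame:
    """Scores of the top principal components of the feature block, each
    column z-scored.

    Component signs are fixed by forcing each component's largest-magnitude
    loading positive, so output is reproducible.
    """
    from sklearn.decomposition import PCA

    feats = feature_columns(m)
    x = m[feats].to_numpy(dtype=float)
    cap = min(x.shape[0] - 1, len(feats))
    if n_components > cap:
        log.warning("pca_reduce: n_components clipped from %d to %d", n_components, cap)
        n_components = cap
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    flip = np.sign(pca.components_[np.arange(n_components),
                                   np.argmax(np.abs(pca.components_), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    sd = scores.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scores = (scores - scores.mean(axis=0)) / sd
    out = pd.DataFrame(scores, index=m.index,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    for c in META_COLS:
        if c in m.columns:
            out.insert(0, c, m[c])
    return out
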