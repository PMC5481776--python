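"""Cell clustering on correlation-matrix features and cluster-marker tests.

The workflow mirrors the single-cell qPCR analysis it was built for:

1. per-cell normalization to a common total (median of per-cell totals),
2. a cell x cell Pearson correlation matrix of log2(value + 1) profiles,
   whose rows serve as feature vectors (so k-means operates on Euclidean
   distances *of the correlation matrix*),
3. k-means with restarts (explicit k, or automatic selection by the
   Calinski-Harabasz criterion),
4. cluster-specific genes by an exact binomial test on transcript-count
   proxies, filtered at fold change > 1.5 or < 0.7,
5. a 2-D t-SNE map for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import calinski_harabasz_score

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

AUTO = "auto"


@dataclass
class ClusterParams:
    """Knobs of the clustering stage.

    ``k`` may be an integer >= 2 or :data:`AUTO`; ``fc_up``/``fc_down`` are
    the fold-change bounds a significant cluster-specific gene must clear
    (> 1.5 or < 0.7 by default); ``alpha`` the raw binomial-test level.
    """

    k: int | str = AUTO
    k_max: int = 10
    n_restarts: int = 50
    seed: int = 0
    alpha: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 0.7
    tsne_perplexity: float | None = None
    tsne_seed: int = 0
    log_features: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (self.fc_down < 1 < self.fc_up):
            raise ValueError("need fc_down < 1 < fc_up")
        if self.k != AUTO and (not isinstance(self.k, (int, np.integer)) or self.k < 2):
            raise ValueError("k must be an integer >= 2 or 'auto'")


@dataclass
class ClusterResult:
    """Labels (1..k), marker table and optional 2-D embedding."""

    labels: pd.Series
    k: int
    markers: pd.DataFrame | None = None
    embedding: pd.DataFrame | None = None
    degenerate: bool = False


def normalize_cells(e: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each cell to the median per-cell total; zeros preserved.

    Cells with all-zero profiles carry no signal and are dropped with a
    warning.
    """
    totals = e.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("dropping %d all-zero cell(s): %s", zero.sum(),
                       list(e.values.index[zero])[:5])
    vals = e.values.loc[~zero]
    totals = totals[~zero]
    target = float(totals.median())
    scaled = vals.mul(target / totals, axis=0)
    return ExpressionMatrix(scaled, e.lod_ct)


def correlation_features(e: ExpressionMatrix, log: bool = True,
                         method: str = "pearson") -> pd.DataFrame:
    """Cell x cell correlation matrix used as the k-means feature space.

    Profiles are log2(value + 1)-transformed by default (the raw scale
    spans 1..2**14).  A constant-profile cell has undefined correlation;
    it is assigned 0 against all others (diagonal stays 1) and logged.
    """
    if e.n_cells < 3:
        raise ValueError("need at least 3 cells")
    x = e.values.to_numpy(dtype=float)
    if log:
        x = np.log2(x + 1.0)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant-profile cell(s); correlations set to 0",
                       constant.sum())
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(x)
    elif method == "spearman":
        ranks = stats.rankdata(x, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(ranks)
    else:
        raise ValueError(f"unknown method {method!r}")
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=e.values.index, columns=e.values.index)


def kmeans_cluster(features: pd.DataFrame, p: ClusterParams) -> ClusterResult:
    """K-means on the rows of ``features``; best of ``n_restarts`` by WCSS.

    With ``k='auto'`` the number of clusters is picked in ``2..k_max`` by
    the Calinski-Harabasz criterion (pluggable upstream; explicit k is the
    recommended path for planned contrasts).  Deterministic given ``seed``.
    """
    x = features.to_numpy(dtype=float)
    n = x.shape[0]
    degenerate = np.ptp(x, axis=0).max(initial=0.0) == 0
    if not degenerate and x.shape[0] == x.shape[1]:
        # correlation-matrix features of mutually indistinguishable cells:
        # constant off-diagonal (e.g. identity for all-constant profiles)
        off = x[~np.eye(n, dtype=bool)]
        degenerate = off.size > 0 and np.ptp(off) == 0
    if degenerate:
        logger.warning("all cells identical: returning a single degenerate cluster")
        labels = pd.Series(1, index=features.index, name="cluster")
        return ClusterResult(labels=labels, k=1, degenerate=True)
    if p.k == AUTO:
        k = _select_k(x, p)
    else:
        k = int(p.k)
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells ({n})")
    km = KMeans(n_clusters=k, n_init=p.n_restarts, random_state=p.seed)
    raw = km.fit_predict(x)
    labels = pd.Series(_canonical_labels(raw), index=features.index, name="cluster")
    return ClusterResult(labels=labels, k=k)


def _select_k(x: np.ndarray, p: ClusterParams) -> int:
    best_k, best_score = 2, -np.inf
    for k in range(2, min(p.k_max, x.shape[0] - 1) + 1):
        km = KMeans(n_clusters=k, n_init=p.n_restarts, random_state=p.seed)
        lab = km.fit_predict(x)
        if len(np.unique(lab)) < 2:
            continue
        score = calinski_harabasz_score(x, lab)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..k by order of first appearance (stable under
    k-means' arbitrary internal label permutation)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def binomial_two_sided_p(n_obs: int, n_total: int, pi: float) -> float:
    """Exact two-sided binomial tail p, min(1, 2*min(lower, upper)).

    Small per-cluster totals make a normal approximation unreliable; both
    tails are evaluated exactly and doubled.
    """
    lower = stats.binom.cdf(n_obs, n_total, pi)
    upper = stats.binom.sf(n_obs - 1, n_total, pi)
    return float(min(1.0, 2.0 * min(lower, upper)))


def cluster_marker_genes(e: ExpressionMatrix, labels: pd.Series,
                         p: ClusterParams | None = None) -> pd.DataFrame:
    """Cluster-specific genes by exact binomial testing of count proxies.

    Expression values are rounded to pseudo-counts (the LoD scale
    ``2**(lod_ct - ct)`` is a transcript-count proxy).  For cluster ``c``
    and gene ``g``, the observed count ``n_gc`` is tested against
    Binomial(N_c, pi_g) where ``N_c`` is the cluster's total count over all
    genes and ``pi_g`` the gene's global count share.  A gene is flagged
    significant in a cluster when ``p < alpha`` *and* its fold change
    (cluster mean / all-cells mean) exceeds ``fc_up`` or falls below
    ``fc_down``.  Genes undetected globally are excluded.

    Returns a frame with one row per (cluster, gene) and columns
    ``cluster, gene, mean_cluster, mean_all, fold_change, p_value,
    significant``.
    """
    p = p or ClusterParams(k=2)
    labels = labels.reindex(e.values.index)
    if labels.isna().any():
        raise ValueError("labels must cover every cell")
    counts = np.rint(e.values.to_numpy(dtype=float))
    genes = np.array(e.gene_ids)
    g_tot = counts.sum(axis=0)
    total = g_tot.sum()
    testable = g_tot > 0
    pi = g_tot / total
    mean_all = e.values.mean(axis=0).to_numpy()

    rows = []
    for c in sorted(labels.unique()):
        in_c = (labels == c).to_numpy()
        n_gc = counts[in_c].sum(axis=0)
        n_c = n_gc.sum()
        mean_c = e.values.to_numpy()[in_c].mean(axis=0)
        lower = stats.binom.cdf(n_gc, n_c, pi)
        upper = stats.binom.sf(n_gc - 1, n_c, pi)
        pvals = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mean_all > 0, mean_c / mean_all, np.nan)
        for j in np.flatnonzero(testable):
            sig = (pvals[j] < p.alpha) and (fc[j] > p.fc_up or fc[j] < p.fc_down)
            rows.append((c, genes[j], mean_c[j], mean_all[j], fc[j],
                         pvals[j], bool(sig)))
    out = pd.DataFrame(rows, columns=["cluster", "gene", "mean_cluster",
                                      "mean_all", "fold_change", "p_value",
                                      "significant"])
    return out


def tsne_embed(features: pd.DataFrame, p: ClusterParams | None = None) -> pd.DataFrame:
    """2-D t-SNE of the correlation features; deterministic given tsne_seed."""
    p = p or ClusterParams(k=2)
    n = features.shape[0]
    if n < 4:
        raise ValueError("t-SNE needs at least 4 cells")
    perplexity = p.tsne_perplexity
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    if perplexity >= n:
        raise ValueError("perplexity must be < number of cells")
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=p.tsne_seed,
              init="pca")
    xy = ts.fit_transform(features.to_numpy(dtype=float))
    return pd.DataFrame(xy, index=features.index, columns=["x", "y"])
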