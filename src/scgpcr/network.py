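"""Gene-gene Spearman rank-correlation networks.

Co-expression across single cells is summarized as a thresholded network:
an edge joins two genes whose Spearman rank correlation across retained
cells exceeds the display threshold (0.3 by default, signed; an
absolute-value mode exists for callers interested in anti-correlation).
Undetected values participate as exact zeros, which the average-rank tie
handling deals with naturally.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CorrelationNetwork
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.3


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Returns NaN (reported as missing) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def build_network(e: ExpressionMatrix, genes=None,
                  threshold: float = DEFAULT_THRESHOLD,
                  mode: str = "positive_only",
                  detected_only: bool = False) -> CorrelationNetwork:
    """All-pairs Spearman network over ``genes`` (default: all genes).

    ``mode='positive_only'`` keeps edges with rho > threshold (the display
    rule this pipeline defaults to); ``mode='absolute'`` keeps
    |rho| > threshold.  ``detected_only`` restricts each pair to cells
    where both genes are detected (pairs left with fewer than 3 such cells
    are skipped).
    """
    if mode not in ("positive_only", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = sorted(genes) if genes is not None else sorted(e.gene_ids)
    missing = set(genes) - set(e.gene_ids)
    if missing:
        raise KeyError(f"genes not in expression matrix: {sorted(missing)[:5]}")
    if e.n_cells < 3:
        raise ValueError("need at least 3 cells")

    vals = e.values[genes]
    edges = []
    if detected_only:
        for a, b in itertools.combinations(genes, 2):
            both = (vals[a] > 0) & (vals[b] > 0)
            if both.sum() < 3:
                continue
            rho = spearman_rho(vals.loc[both, a], vals.loc[both, b])
            if _keep(rho, threshold, mode):
                edges.append((a, b, rho))
    else:
        corr = vals.corr(method="spearman")
        n_const = int((vals.nunique() == 1).sum())
        if n_const:
            logger.warning("%d constant gene(s) have undefined correlations", n_const)
        for a, b in itertools.combinations(genes, 2):
            rho = corr.loc[a, b]
            if _keep(rho, threshold, mode):
                edges.append((a, b, float(rho)))

    frame = pd.DataFrame(edges, columns=["source", "target", "rho"])
    return CorrelationNetwork(nodes=genes, edges=frame,
                              threshold=threshold, mode=mode)


def _keep(rho: float, threshold: float, mode: str) -> bool:
    if not np.isfinite(rho):
        return False
    value = abs(rho) if mode == "absolute" else rho
    return value > threshold
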