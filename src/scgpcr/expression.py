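"""Limit-of-detection expression transform and heterogeneity statistics.

The BioMark microfluidic qPCR system has an estimated limit of detection
(LoD) at Ct = 24 cycles.  Expression is quantified relative to that limit,

    expression = 2 ** (lod_ct - sample_ct),

so a gene amplifying 10 cycles before the limit has expression 2**10 = 1024
and an entry at/beyond the limit (or with no amplification) is undetected
and stored as exactly 0.  The transform is strictly decreasing in Ct on
detected entries and exactly invertible: Ct = lod_ct - log2(value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CtMatrix, GenePanel

logger = logging.getLogger(__name__)

DEFAULT_LOD_CT = 24.0


@dataclass
class ExpressionMatrix:
    """LoD-scale expression values, cells x genes; 0 means undetected."""

    values: pd.DataFrame
    lod_ct: float = DEFAULT_LOD_CT

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("expression values must be finite and >= 0")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def detected(self) -> pd.DataFrame:
        """Boolean cells x genes detection mask (value > 0)."""
        return self.values > 0

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(genes)].copy(), self.lod_ct)


def lod_transform(m: CtMatrix, lod_ct: float = DEFAULT_LOD_CT) -> ExpressionMatrix:
    """Map a Ct matrix onto the LoD expression scale.

    Detected entries (finite Ct strictly below ``lod_ct``) become
    ``2**(lod_ct - ct)``; no-amplification entries and entries at or beyond
    the limit become 0.
    """
    if lod_ct <= 0:
        raise ValueError("lod_ct must be > 0")
    ct = m.ct.to_numpy(dtype=float)
    if np.any(ct[np.isfinite(ct)] < 0):
        raise ValueError("negative Ct value")
    with np.errstate(invalid="ignore"):
        detected = np.isfinite(ct) & (ct < lod_ct)
    vals = np.where(detected, np.exp2(lod_ct - np.where(detected, ct, lod_ct)), 0.0)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.ct.index, columns=m.ct.columns), lod_ct)


def expression_frequency(e: ExpressionMatrix,
                         genes=None) -> pd.DataFrame:
    """Per-gene detection frequency across cells.

    Returns a frame indexed by gene with columns ``n_detected``, ``n_cells``
    and ``frequency`` (fraction of cells with value > 0).
    """
    genes = list(genes) if genes is not None else e.gene_ids
    missing = set(genes) - set(e.gene_ids)
    if missing:
        raise KeyError(f"genes not in expression matrix: {sorted(missing)[:5]}")
    if e.n_cells < 1:
        raise ValueError("need at least one cell")
    det = (e.values[genes] > 0).sum(axis=0)
    out = pd.DataFrame({
        "n_detected": det.astype(int),
        "n_cells": e.n_cells,
    })
    out["frequency"] = out["n_detected"] / out["n_cells"]
    out.index.name = "gene"
    return out


def filter_intron_spanning(panel: GenePanel) -> GenePanel:
    """Drop GPCRs lacking intron-spanning primers from the panel.

    Single-exon GPCRs amplify residual genomic DNA and give positive calls
    in every cell; they are removed from the analyzable set.  Non-GPCR
    genes are kept regardless of the flag.
    """
    tab = panel.table
    drop = tab.index[(tab["category"] == "gpcr") & ~tab["intron_spanning"]]
    if len(drop):
        logger.info("excluding %d non-intron-spanning GPCRs", len(drop))
    kept = tab.drop(index=drop)
    if not (kept["category"] == "gpcr").any():
        logger.warning("no analyzable GPCRs remain after intron-spanning filter")
    return GenePanel(kept.copy())


def receptors_per_cell(e: ExpressionMatrix, panel: GenePanel) -> pd.Series:
    """Number of (intron-spanning) GPCRs detected in each cell."""
    gpcrs = [g for g in panel.gpcrs(intron_spanning_only=True) if g in e.gene_ids]
    counts = (e.values[gpcrs] > 0).sum(axis=1).astype(int)
    counts.name = "n_gpcrs"
    return counts


def mean_sem(x: pd.Series | np.ndarray) -> tuple[float, float]:
    """Mean and s.e.m. (s.d./sqrt(n), sample s.d. with n-1)."""
    arr = np.asarray(x, dtype=float)
    n = arr.size
    if n == 0:
        return (np.nan, np.nan)
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return (float(arr.mean()), sem)


def group_compare(a, b=None, mode: str = "two_sample",
                  equal_var: bool = True) -> tuple[float, float]:
    """Two-group or one-sample-vs-1 t-test, two-sided.

    ``mode='two_sample'`` runs the classic (equal-variance) Student t-test
    between ``a`` and ``b``; pass ``equal_var=False`` for Welch.
    ``mode='one_sample_vs_1'`` tests the mean of ``a`` against 1, the
    convention for data normalized to a control group.

    Degenerate case: zero variance everywhere with equal means returns
    ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(a, dtype=float)
    if mode == "one_sample_vs_1":
        if a.size < 2:
            raise ValueError("one-sample test needs n >= 2")
        if a.std(ddof=1) == 0:
            return (0.0, 1.0) if a.mean() == 1.0 else (np.inf * np.sign(a.mean() - 1), 0.0)
        t, p = stats.ttest_1samp(a, popmean=1.0)
        return float(t), float(p)
    if mode != "two_sample":
        raise ValueError(f"unknown mode {mode!r}")
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample test needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return (0.0, 1.0)
        return (np.inf * np.sign(a.mean() - b.mean()), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
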