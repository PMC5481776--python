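"""Marker-panel identity gating of single cells.

Freshly sorted vascular cell preparations carry 10-18% contaminating cells
(leukocytes, epithelial cells, skeletal muscle, ...).  Cells are therefore
re-classified from the qPCR data itself: a cell is kept only when the
quality-control reference genes amplify, no lineage-exclusion marker
amplifies, and exactly one target identity marker (Cdh5 for endothelial
cells, Myh11 for smooth muscle cells) amplifies.  Everything else is
reported in a contamination table with one row per sample group and one
column per identity label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CtMatrix, GenePanel

logger = logging.getLogger(__name__)

#: Lineage-exclusion markers: detection of any of these flags a contaminant
#: (leukocyte, myeloid, T/B cell, neutrophil, epithelial, skeletal muscle).
DEFAULT_LINEAGE_EXCLUSION = ("Ptprc", "Itgam", "Cd4", "Cd8", "Cd19", "Ly6g",
                             "Cdh1", "Tnni2")

#: Target identity markers per sorted cell type.
DEFAULT_TARGET_MARKERS = {"ec": "Cdh5", "smc": "Myh11"}

#: Quality-control reference genes that must amplify in a usable cDNA.
DEFAULT_QC_GENES = ("Gapdh", "Hprt")


@dataclass
class GatingConfig:
    """Parameters of the cell-identity gate.

    Attributes
    ----------
    lod_ct
        Limit-of-detection cycle threshold; a gene is *detected* when its Ct
        is strictly below this (default 24 cycles).
    allow_low_cross_marker
        Optional ``(marker, max_expression)`` exception: a cell carrying the
        wrong-lineage target marker is still retained when that marker's
        LoD-scale expression ``2**(lod_ct - ct)`` is at or below
        ``max_expression`` (used for Cdh5+/Myh11-low aortic EC, where all
        endothelial cells co-amplify trace Myh11).  Default threshold 16,
        i.e. within 4 cycles of the detection limit.
    qc_require_all
        If True (default, the stricter reading) every QC gene must be
        detected; otherwise one detected QC gene suffices.
    """

    lod_ct: float = 24.0
    lineage_exclusion_genes: tuple[str, ...] = DEFAULT_LINEAGE_EXCLUSION
    target_markers: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_MARKERS))
    qc_genes: tuple[str, ...] = DEFAULT_QC_GENES
    allow_low_cross_marker: tuple[str, float] | None = None
    qc_require_all: bool = True

    def __post_init__(self) -> None:
        if self.lod_ct <= 0:
            raise ValueError("lod_ct must be > 0")
        if not self.qc_genes:
            raise ValueError("qc_genes must be nonempty")
        overlap = set(self.target_markers.values()) & set(self.lineage_exclusion_genes)
        if overlap:
            raise ValueError(f"target markers overlap lineage exclusion set: {overlap}")

    def label_for(self, marker: str) -> str:
        return f"{marker.lower()}_only"

    @property
    def marker_labels(self) -> list[str]:
        return [self.label_for(m) for m in self.target_markers.values()]


#: Contamination-table column order (QC failures are reported separately).
CONTAMINATION_LABELS = ("cdh5_only", "myh11_only", "other_markers", "no_marker")


def detect(entry: float, lod_ct: float = 24.0) -> bool:
    """True iff ``entry`` is a finite Ct strictly below the detection limit.

    NO_AMP (NaN) and Ct >= lod_ct are undetected; this is the same boundary
    the expression transform uses (Ct == lod_ct would map to 2**0 == 1 and
    is censored to 0 there).
    """
    if lod_ct <= 0:
        raise ValueError("lod_ct must be > 0")
    return bool(np.isfinite(entry) and entry < lod_ct)


def classify_cell(cell_row: pd.Series, panel: GenePanel, cfg: GatingConfig) -> str:
    """Assign one identity label to a single cell's Ct row.

    Order of the rules: QC failure first, then lineage contamination, then
    target-marker identity.  Double target-positives (beyond the optional
    low-cross-marker exception) are binned as ``other_markers``: the
    exclusive "only" identity labels admit exactly one marker.
    """
    for gene in (*cfg.qc_genes, *cfg.target_markers.values()):
        if gene not in cell_row.index:
            raise KeyError(f"gating gene {gene!r} missing from Ct matrix")

    qc_hits = [detect(cell_row[g], cfg.lod_ct) for g in cfg.qc_genes]
    qc_ok = all(qc_hits) if cfg.qc_require_all else any(qc_hits)
    if not qc_ok:
        return "qc_fail"

    lineage = [g for g in cfg.lineage_exclusion_genes
               if g in cell_row.index and detect(cell_row[g], cfg.lod_ct)]
    if lineage:
        return "other_markers"

    detected = {m for m in cfg.target_markers.values()
                if detect(cell_row[m], cfg.lod_ct)}
    if cfg.allow_low_cross_marker is not None and len(detected) > 1:
        marker, max_expr = cfg.allow_low_cross_marker
        if marker in detected:
            expr = 2.0 ** (cfg.lod_ct - cell_row[marker])
            if expr <= max_expr:
                detected.discard(marker)
    if len(detected) == 1:
        return cfg.label_for(detected.pop())
    if len(detected) > 1:
        return "other_markers"
    return "no_marker"


@dataclass
class GatingResult:
    """Outcome of :func:`gate_cells`.

    ``labels`` partitions all input cells; ``retained`` holds only cells
    whose label matches the run's target identity; ``contamination`` is a
    per-group percentage table over the non-QC-fail cells (rows sum to 100);
    ``diagnostics`` carries sub-counts (QC failures, double positives, cells
    admitted through the low-cross-marker exception).
    """

    labels: pd.Series
    retained: CtMatrix
    contamination: pd.DataFrame
    diagnostics: dict


def gate_cells(m: CtMatrix, panel: GenePanel, cfg: GatingConfig | None = None,
               target: str = "smc") -> GatingResult:
    """Gate every cell of ``m`` and build the contamination report.

    Parameters
    ----------
    m, panel
        Ct matrix and its gene panel (must cover the matrix's genes).
    target
        Which sorted identity this run declares (key of
        ``cfg.target_markers``); only cells with that identity label are
        retained.
    """
    cfg = cfg or GatingConfig()
    if not panel.covers(m.gene_ids):
        missing = sorted(set(m.gene_ids) - set(panel.genes))
        raise KeyError(f"panel does not cover Ct matrix genes: {missing[:5]}")
    if target not in cfg.target_markers:
        raise KeyError(f"unknown target {target!r}; options: {sorted(cfg.target_markers)}")

    labels = pd.Series(
        [classify_cell(m.ct.loc[c], panel, cfg) for c in m.cell_ids],
        index=m.ct.index, name="label")

    n_double = _count_double_positives(m, cfg)
    target_label = cfg.label_for(cfg.target_markers[target])
    retained_cells = labels.index[labels == target_label]
    if len(retained_cells) == 0:
        logger.warning("gating retained no cells for target %r", target)
    retained = m.subset_cells(retained_cells)

    contamination = contamination_table(labels, m.groups(), cfg)
    diagnostics = {
        "n_input": int(m.n_cells),
        "n_qc_fail": int((labels == "qc_fail").sum()),
        "n_retained": int(len(retained_cells)),
        "n_double_target_positive": n_double,
        "target_label": target_label,
    }
    return GatingResult(labels=labels, retained=retained,
                        contamination=contamination, diagnostics=diagnostics)


def _count_double_positives(m: CtMatrix, cfg: GatingConfig) -> int:
    markers = list(cfg.target_markers.values())
    det = m.ct[markers].lt(cfg.lod_ct).fillna(False)
    return int((det.sum(axis=1) > 1).sum())


def contamination_table(labels: pd.Series, groups: pd.Series,
                        cfg: GatingConfig | None = None) -> pd.DataFrame:
    """Percentage of cells per identity label, per sample group.

    QC failures are excluded from the denominator (unusable cDNAs say
    nothing about sorting purity), so each row sums to 100.
    """
    cfg = cfg or GatingConfig()
    columns = list(dict.fromkeys([*cfg.marker_labels, "other_markers", "no_marker"]))
    ok = labels != "qc_fail"
    rows = {}
    for grp, idx in groups[ok].groupby(groups[ok]).groups.items():
        sub = labels.loc[idx]
        n = len(sub)
        rows[grp] = {col: 100.0 * (sub == col).sum() / n for col in columns}
    tab = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    tab.index.name = "group"
    return tab
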