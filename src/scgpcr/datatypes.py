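"""Core in-memory containers shared by all pipeline stages.

All tabular containers wrap :class:`pandas.DataFrame` with cells as rows and
genes as columns (wide layout, matching microfluidic qPCR exports).  The
"no amplification" state of a qPCR reaction is represented as ``NaN`` inside
:class:`CtMatrix`; everywhere downstream an undetected gene is an exact ``0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """An external file or table violates the expected format/invariants."""


#: Valid gene-panel categories.
CATEGORIES = ("gpcr", "identity", "function", "reference")

#: Valid marker roles for gating.
MARKER_ROLES = ("target_ec", "target_smc", "lineage_exclusion",
                "quality_control", "none")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dup}")


@dataclass
class CtMatrix:
    """Cycle-threshold values for a set of single cells.

    Parameters
    ----------
    ct
        cells x genes frame of Ct values (cycles).  ``NaN`` encodes the
        distinguished no-amplification state; every other entry must be a
        finite value >= 0.
    metadata
        Optional per-cell annotations (index must equal the cell index);
        typically carries a ``group`` column (tissue / treatment) used by
        the gating report.
    """

    ct: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.ct, pd.DataFrame):
            self.ct = pd.DataFrame(self.ct)
        _check_unique(self.ct.index, "cell")
        _check_unique(self.ct.columns, "gene")
        vals = self.ct.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if np.any(np.isinf(vals)):
            raise FormatError("Ct matrix contains infinite values")
        if np.any(vals[finite] < 0):
            raise FormatError("Ct values must be >= 0")
        if self.metadata is not None and not self.metadata.index.equals(self.ct.index):
            raise FormatError("metadata index must match cell ids")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_cells(self) -> int:
        return self.ct.shape[0]

    def groups(self) -> pd.Series:
        """Per-cell sample-group labels ('all' when no metadata present)."""
        if self.metadata is not None and "group" in self.metadata.columns:
            return self.metadata["group"].astype(str)
        return pd.Series("all", index=self.ct.index, name="group")

    def subset_cells(self, cells: Iterable[str]) -> "CtMatrix":
        cells = list(cells)
        meta = self.metadata.loc[cells] if self.metadata is not None else None
        return CtMatrix(self.ct.loc[cells].copy(), meta)


@dataclass
class GenePanel:
    """Per-gene annotations of the primer array.

    ``table`` is indexed by gene with columns ``category`` (one of
    ``gpcr/identity/function/reference``), ``marker_role`` (one of
    ``target_ec/target_smc/lineage_exclusion/quality_control/none``) and
    boolean ``intron_spanning``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"category", "marker_role", "intron_spanning"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"gene panel missing column(s): {sorted(missing)}")
        _check_unique(self.table.index, "gene")
        bad_cat = set(self.table["category"]) - set(CATEGORIES)
        if bad_cat:
            raise FormatError(f"unknown category value(s): {sorted(bad_cat)}")
        bad_role = set(self.table["marker_role"]) - set(MARKER_ROLES)
        if bad_role:
            raise FormatError(f"unknown marker_role value(s): {sorted(bad_role)}")
        self.table["intron_spanning"] = self.table["intron_spanning"].astype(bool)
        ref_roles = self.table.loc[self.table["category"] == "reference", "marker_role"]
        if not (ref_roles == "quality_control").all():
            raise FormatError("reference genes must have marker_role quality_control")
        if not self.table["marker_role"].isin(["target_ec", "target_smc"]).any():
            raise FormatError("panel must contain at least one target marker")
        if not (self.table["marker_role"] == "quality_control").any():
            raise FormatError("panel must contain at least one quality-control gene")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def genes_of(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])

    def with_role(self, role: str) -> list[str]:
        return list(self.table.index[self.table["marker_role"] == role])

    def gpcrs(self, intron_spanning_only: bool = True) -> list[str]:
        """GPCR genes; by default only those with intron-spanning primers
        (single-exon designs amplify genomic DNA and are excluded)."""
        sel = self.table["category"] == "gpcr"
        if intron_spanning_only:
            sel &= self.table["intron_spanning"]
        return list(self.table.index[sel])

    def covers(self, genes: Iterable[str]) -> bool:
        return set(genes) <= set(self.table.index)


_BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PWM:
    """Position frequency matrix of a transcription-factor binding motif.

    ``counts`` is a 4 x L array of nonnegative base counts in fixed row
    order A, C, G, T.  ``pseudocount`` regularizes the count-to-probability
    conversion used for log-odds scoring.
    """

    tf_name: str
    counts: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError(f"PWM {self.tf_name}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise FormatError(f"PWM {self.tf_name}: motif length must be >= 1")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise FormatError(f"PWM {self.tf_name}: counts must be finite and >= 0")
        if np.any(self.counts.sum(axis=0) == 0):
            raise FormatError(f"PWM {self.tf_name}: a position has all-zero counts")
        if self.pseudocount <= 0:
            raise FormatError("pseudocount must be > 0")

    def __len__(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        """Pseudocount-smoothed per-position base probabilities (4 x L)."""
        tot = self.counts.sum(axis=0, keepdims=True)
        return (self.counts + self.pseudocount) / (tot + 4.0 * self.pseudocount)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class NanoStringLaneSet:
    """Raw multiplex count data: probes x lanes plus a probe-class label.

    ``probe_class`` maps each probe (row of ``counts``) to one of
    ``endogenous``, ``positive`` (spiked-in positive controls) or
    ``negative`` (background probes).
    """

    counts: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self) -> None:
        self.probe_class = self.probe_class.reindex(self.counts.index)
        if self.probe_class.isna().any():
            raise FormatError("every probe needs a probe_class entry")
        bad = set(self.probe_class) - {"endogenous", "positive", "negative"}
        if bad:
            raise FormatError(f"unknown probe class(es): {sorted(bad)}")
        vals = self.counts.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise FormatError("counts must be finite and nonnegative")
        if (self.probe_class == "positive").sum() < 1:
            raise FormatError("need at least one positive-control probe")

    @property
    def lanes(self) -> list[str]:
        return list(self.counts.columns)

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.counts.loc[self.probe_class == cls]


@dataclass
class CorrelationNetwork:
    """Thresholded gene-gene rank-correlation network.

    Edges are stored as a frame with columns ``source``, ``target``,
    ``rho`` where ``source < target`` lexicographically and rows are sorted
    by (source, target); this makes file output deterministic.
    """

    nodes: list[str]
    edges: pd.DataFrame
    threshold: float
    mode: str = "positive_only"

    def __post_init__(self) -> None:
        cols = ["source", "target", "rho"]
        self.edges = pd.DataFrame(self.edges, columns=cols).reset_index(drop=True)
        if len(self.edges):
            if (self.edges["source"] >= self.edges["target"]).any():
                raise FormatError("edges must satisfy source < target")
            pairs = self.edges[["source", "target"]].apply(tuple, axis=1)
            if pairs.duplicated().any():
                raise FormatError("duplicate edges")
            if (self.edges["rho"].abs() > 1 + 1e-12).any():
                raise FormatError("|rho| must be <= 1")
            self.edges = self.edges.sort_values(["source", "target"]).reset_index(drop=True)

    @property
    def n_edges(self) -> int:
        return len(self.edges)
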