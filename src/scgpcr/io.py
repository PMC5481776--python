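"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Ct matrices: CSV/TSV, header row = gene ids, first column = cell id
  (wide layout).  A long layout (``cell,gene,ct``) is available behind
  ``long_format=True``.
* Gene panel: CSV with columns ``gene,category,marker_role,intron_spanning``.
* Motifs: JASPAR PFM text; both the 2016 bracketed dialect
  (``A  [ 1 2 3 ]``) and the plain four-row dialect are accepted and
  auto-detected per record.
* Promoters: FASTA, gene id taken from the record id.
* Networks: TSV edge list ``source<TAB>target<TAB>rho``.
* NanoString: CSV, rows = probes, first column probe id, second column
  ``probe_class`` in {endogenous, positive, negative}, remaining columns =
  lanes.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (CorrelationNetwork, CtMatrix, FormatError, GenePanel,
                        NanoStringLaneSet, PWM)

#: Tokens interpreted as "no amplification" in Ct tables.  The qPCR export
#: dialect varies by instrument software, hence the configurable set.
DEFAULT_NO_AMP_TOKENS = frozenset({"", "NA", "999", "Undetermined"})


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


# ---------------------------------------------------------------------------
# Ct matrices
# ---------------------------------------------------------------------------

def read_ct_matrix(path: str | Path,
                   no_amp_tokens: Iterable[str] = DEFAULT_NO_AMP_TOKENS,
                   long_format: bool = False,
                   metadata: pd.DataFrame | None = None) -> CtMatrix:
    """Read a Ct table into a :class:`CtMatrix`.

    Entries matching ``no_amp_tokens`` (compared as stripped strings) map to
    the NO_AMP state (NaN).  Any other non-numeric entry is a format error.
    """
    tokens = {str(t).strip() for t in no_amp_tokens}
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if long_format:
        need = {"cell", "gene", "ct"}
        if not need <= set(raw.columns):
            raise FormatError("long-format Ct table needs columns cell,gene,ct")
        raw["ct"] = [_parse_ct(v, tokens) for v in raw["ct"]]
        dup = raw.duplicated(subset=["cell", "gene"])
        if dup.any():
            raise FormatError("duplicate (cell, gene) pair in long table")
        wide = raw.pivot(index="cell", columns="gene", values="ct")
        wide.index.name = None
        wide.columns.name = None
        return CtMatrix(wide.astype(float), metadata)
    cell_col = raw.columns[0]
    if raw[cell_col].duplicated().any():
        raise FormatError("duplicate cell id in Ct table")
    raw = raw.set_index(cell_col)
    raw.index.name = None
    if pd.Index(raw.columns).has_duplicates:
        raise FormatError("duplicate gene id in Ct table header")
    parsed = raw.map(lambda v: _parse_ct(v, tokens))
    return CtMatrix(parsed.astype(float), metadata)


def _parse_ct(value: str, tokens: set[str]) -> float:
    s = str(value).strip()
    if s in tokens:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise FormatError(f"non-numeric Ct entry {value!r} (not a NO_AMP token)") from None


def write_ct_matrix(m: CtMatrix, path: str | Path, no_amp_token: str = "NA") -> None:
    out = m.ct.copy()
    out.insert(0, "cell", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False, na_rep=no_amp_token)


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

def read_gene_panel(path: str | Path) -> GenePanel:
    tab = pd.read_csv(path, sep=_sep_for(path))
    need = {"gene", "category", "marker_role", "intron_spanning"}
    if not need <= set(tab.columns):
        raise FormatError(f"gene panel needs columns {sorted(need)}")
    tab["intron_spanning"] = tab["intron_spanning"].map(_parse_bool)
    tab = tab.set_index("gene")[["category", "marker_role", "intron_spanning"]]
    tab.index.name = None
    return GenePanel(tab)


def _parse_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise FormatError(f"cannot parse boolean {v!r}")


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    out = panel.table.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# JASPAR PFM files
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\s*([ACGT])?\s*\[?\s*([0-9.eE+\- ]+?)\s*\]?\s*$")


def read_jaspar_pfms(path: str | Path, pseudocount: float = 0.5) -> list[PWM]:
    """Parse a JASPAR-style PFM text file into a list of :class:`PWM`.

    Each record is a ``>ID [NAME]`` header followed by four count rows.
    Rows may be labeled and bracketed (``A [ 3 0 5 ]``, JASPAR 2016 style)
    or plain whitespace-separated numbers; labeled rows are normalized to
    A,C,G,T order, unlabeled rows are taken as already being in that order.
    """
    text = Path(path).read_text()
    records: list[PWM] = []
    header: str | None = None
    rows: list[tuple[str | None, list[float]]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(f"motif {header!r}: expected 4 base rows, got {len(rows)}")
        labels = [lab for lab, _ in rows]
        if all(lab is not None for lab in labels):
            if sorted(labels) != ["A", "C", "G", "T"]:
                raise FormatError(f"motif {header!r}: base labels must be A,C,G,T")
            ordered = [dict(rows)[b] for b in "ACGT"]
        elif all(lab is None for lab in labels):
            ordered = [vals for _, vals in rows]
        else:
            raise FormatError(f"motif {header!r}: mixed labeled/unlabeled rows")
        lengths = {len(v) for v in ordered}
        if len(lengths) != 1:
            raise FormatError(f"motif {header!r}: rows of unequal length")
        parts = header.split(None, 1)
        name = parts[1].strip() if len(parts) > 1 else parts[0]
        records.append(PWM(tf_name=name, counts=np.array(ordered), pseudocount=pseudocount))
        header, rows = None, []

    for line in text.splitlines():
        line = line.rstrip()
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            continue
        if header is None:
            raise FormatError("count row before any motif header")
        m = _ROW_RE.match(line)
        if not m:
            raise FormatError(f"unparseable PFM row: {line!r}")
        vals = [float(x) for x in m.group(2).split()]
        rows.append((m.group(1), vals))
    flush()
    return records


def write_jaspar_pfms(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write motifs in the labeled/bracketed JASPAR 2016 text dialect."""
    lines: list[str] = []
    for i, p in enumerate(pwms, 1):
        lines.append(f">M{i:04d} {p.tf_name}")
        for b, row in zip("ACGT", p.counts):
            joined = " ".join(_fmt_num(x) for x in row)
            lines.append(f"{b} [ {joined} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# Promoter FASTA
# ---------------------------------------------------------------------------

def read_promoters(path: str | Path) -> dict[str, str]:
    """Read promoter sequences keyed by gene id (uppercased, ACGTN only)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate promoter id {rec.id!r}")
        seq = str(rec.seq).upper()
        if re.search(r"[^ACGTN]", seq):
            raise FormatError(f"promoter {rec.id!r}: non-ACGTN character")
        out[rec.id] = seq
    return out


def write_promoters(promoters: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=gene, description="")
            for gene, seq in promoters.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Network edge lists
# ---------------------------------------------------------------------------

def write_edge_list(network: CorrelationNetwork, path: str | Path) -> None:
    """TSV edge list, lexicographic (source, target) order (deterministic)."""
    network.edges.to_csv(path, sep="\t", index=False,
                         columns=["source", "target", "rho"])


def read_edge_list(path: str | Path, threshold: float = 0.0,
                   mode: str = "positive_only") -> CorrelationNetwork:
    tab = pd.read_csv(path, sep="\t")
    if list(tab.columns) != ["source", "target", "rho"]:
        raise FormatError("edge list needs columns source,target,rho")
    nodes = sorted(set(tab["source"]) | set(tab["target"]))
    return CorrelationNetwork(nodes=nodes, edges=tab, threshold=threshold, mode=mode)


# ---------------------------------------------------------------------------
# NanoString count tables
# ---------------------------------------------------------------------------

def read_nanostring_counts(path: str | Path) -> NanoStringLaneSet:
    tab = pd.read_csv(path, sep=_sep_for(path))
    if tab.shape[1] < 3 or tab.columns[1] != "probe_class":
        raise FormatError("NanoString table needs probe, probe_class, then lane columns")
    probe_col = tab.columns[0]
    if tab[probe_col].duplicated().any():
        raise FormatError("duplicate probe id")
    tab = tab.set_index(probe_col)
    tab.index.name = None
    classes = tab["probe_class"].astype(str)
    counts = tab.drop(columns=["probe_class"]).astype(float)
    return NanoStringLaneSet(counts=counts, probe_class=classes)


def write_nanostring_counts(lanes: NanoStringLaneSet, path: str | Path) -> None:
    out = lanes.counts.copy()
    out.insert(0, "probe_class", lanes.probe_class)
    out.insert(0, "probe", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Flat YAML key-value config; every key mirrors a CLI flag."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config must be a YAML mapping")
    return cfg


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out
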