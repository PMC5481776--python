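"""Promoter scanning for TF binding sites and gene-set enrichment.

Each promoter window (by convention 1 kb spanning [TSS-950, TSS+50) on the
gene's strand) is scanned with every position weight matrix on both strands;
the best log-odds window score is min-max normalized onto [0, 1] by the
PWM's attainable score range.  A gene set is then tested against the global
promoter background with a z statistic on mean best-hit scores,

    z = (mean_set - mean_global) / (sd_global / sqrt(n_set)),

with a two-sided normal p-value; for display, p-values are z-transformed
(signed normal quantile) and clipped at +/-8.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PWM

logger = logging.getLogger(__name__)

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

#: Promoter window relative to the transcription start site, half-open,
#: 0-based internally (1-based in file interfaces).
PROMOTER_WINDOW = (-950, 50)


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> -1."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def background_frequencies(promoters: Mapping[str, str]) -> np.ndarray:
    """A,C,G,T frequencies of the supplied promoter set (Ns ignored)."""
    counts = np.zeros(4)
    for seq in promoters.values():
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc >= 0], minlength=4)
    if counts.sum() == 0:
        return uniform_background()
    return counts / counts.sum()


def pwm_log_odds(p: PWM, background: np.ndarray | None = None) -> np.ndarray:
    """4 x L log2-odds score matrix with pseudocount smoothing.

    Entry (b, j) = log2( (counts[b,j] + pc) / (column total + 4 pc)
                         / background[b] ).
    """
    bg = uniform_background() if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 strictly positive frequencies summing to 1")
    probs = p.probabilities()
    return np.log2(probs / bg[:, None])


def _rc_matrix(lom: np.ndarray) -> np.ndarray:
    """Log-odds matrix scoring the reverse-complement strand."""
    return lom[::-1, ::-1]


def best_hit_score(seq: str, p: PWM,
                   background: np.ndarray | None = None) -> float:
    """Best normalized PWM hit in ``seq``, scanning both strands.

    The maximum window log-odds score s is min-max normalized by the PWM's
    attainable range: (s - s_min) / (s_max - s_min), where s_min/s_max sum
    the per-position column minima/maxima.  Windows containing N are
    skipped; if no window is scoreable (or the sequence is shorter than the
    motif) NaN is returned and logged.  A degenerate PWM whose range is
    zero scores 1.0 (every window attains the maximum).
    """
    lom = pwm_log_odds(p, background)
    enc = encode_sequence(seq)
    return _best_hit_encoded(enc, lom, p.tf_name)


def _best_hit_encoded(enc: np.ndarray, lom: np.ndarray, name: str) -> float:
    L = lom.shape[1]
    if enc.size < L:
        logger.warning("sequence shorter than motif %s", name)
        return float("nan")
    s_min = lom.min(axis=0).sum()
    s_max = lom.max(axis=0).sum()
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        logger.warning("no N-free window for motif %s", name)
        return float("nan")
    w = windows[valid]
    pos = np.arange(L)
    fwd = lom[w, pos].sum(axis=1)
    rc = _rc_matrix(lom)
    rev = rc[w, pos].sum(axis=1)
    s = max(fwd.max(), rev.max())
    if s_max == s_min:
        return 1.0
    return float((s - s_min) / (s_max - s_min))


def score_promoters(promoters: Mapping[str, str], pwms: Iterable[PWM],
                    background: np.ndarray | str | None = "auto") -> pd.DataFrame:
    """Best-hit score of every PWM in every promoter (genes x TFs frame).

    ``background='auto'`` (default) recomputes base frequencies from the
    supplied promoter set; pass an explicit 4-vector or None (uniform).
    """
    if isinstance(background, str) and background == "auto":
        bg = background_frequencies(promoters)
    else:
        bg = uniform_background() if background is None else np.asarray(background, float)
    pwms = list(pwms)
    encoded = {g: encode_sequence(s) for g, s in promoters.items()}
    data = {}
    for p in pwms:
        lom = pwm_log_odds(p, bg)
        data[p.tf_name] = [_best_hit_encoded(encoded[g], lom, p.tf_name)
                           for g in promoters]
    return pd.DataFrame(data, index=list(promoters))


def set_enrichment(set_genes: Iterable[str], scores: pd.Series,
                   tf: str) -> dict:
    """One enrichment row: gene-set mean best-hit score vs global background.

    ``scores`` holds the best-hit scores of *all* genes for this TF (the
    set must be a subset).  Degenerate background (sd 0) yields z = 0,
    p = 1.
    """
    set_genes = list(set_genes)
    if len(set_genes) < 3:
        raise ValueError("gene set must contain at least 3 genes")
    scores = scores.dropna()
    missing = set(set_genes) - set(scores.index)
    if missing:
        raise KeyError(f"set genes without scores: {sorted(missing)[:5]}")
    mean_set = float(scores.loc[set_genes].mean())
    mean_global = float(scores.mean())
    sd_global = float(scores.std(ddof=1))
    if sd_global == 0:
        z = 0.0
        pval = 1.0
    else:
        z = (mean_set - mean_global) / (sd_global / np.sqrt(len(set_genes)))
        pval = float(2.0 * stats.norm.sf(abs(z)))
        pval = max(pval, np.finfo(float).tiny)
    direction = "over" if z > 0 else "under"
    return {
        "tf": tf,
        "n_set": len(set_genes),
        "mean_set": mean_set,
        "mean_global": mean_global,
        "sd_global": sd_global,
        "z": float(z),
        "p_value": pval,
        "direction": direction,
        "signed_z": signed_z_from_p(pval, direction),
    }


def enrich_gene_sets(score_table: pd.DataFrame,
                     gene_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Enrichment of every (TF, gene set) pair; one row each."""
    rows = []
    for set_name, genes in gene_sets.items():
        for tf in score_table.columns:
            row = set_enrichment(genes, score_table[tf], tf)
            row["gene_set"] = set_name
            rows.append(row)
    out = pd.DataFrame(rows)
    cols = ["tf", "gene_set", "n_set", "mean_set", "mean_global",
            "sd_global", "z", "p_value", "direction", "signed_z"]
    return out[cols]


def signed_z_from_p(p: float, direction: str, clip: float = 8.0) -> float:
    """Signed z-transform of a two-sided p: sign * Phi^-1(1 - p/2)."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    z = stats.norm.isf(p / 2.0)
    z = float(np.clip(z, 0.0, clip))
    return z if direction == "over" else -z


def z_transform_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Pivot enrichment rows into a TF x gene-set signed-z heat-map matrix."""
    return rows.pivot(index="tf", columns="gene_set", values="signed_z")
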