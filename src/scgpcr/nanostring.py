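"""NanoString-style bulk count normalization.

Fixed order of operations:

1. positive-spike normalization — every lane is scaled so its
   positive-control geometric mean equals the across-lane target (the
   arithmetic mean of the per-lane geometric means),
2. background correction — per lane, subtract mean + 2 s.d. of the eight
   negative-control counts (sample s.d., n-1), flooring at 0,
3. low-value flooring — corrected endogenous counts below 20 are fixed to
   the background level (the constant 20 by default) and flagged as not
   expressed.

A geNorm stability screen over candidate reference genes is included; it is
the check used to decide whether reference-gene normalization is justified
at all (genes with large M are unstable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import NanoStringLaneSet

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 20.0


@dataclass
class NormalizedLaneSet:
    """Output of the normalization chain."""

    counts: pd.DataFrame            # endogenous probes x lanes, final values
    scale_factors: pd.Series        # per lane
    backgrounds: pd.Series          # per lane, on the scaled counts
    below_floor: pd.DataFrame       # boolean, probes x lanes


def geometric_mean(x) -> float:
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def positive_spike_normalize(lanes: NanoStringLaneSet) -> tuple[NanoStringLaneSet, pd.Series]:
    """Scale every lane by target / geomean(its positive controls).

    The across-lane target is the arithmetic mean of the per-lane positive
    geometric means; after scaling, all lanes' positive geometric means are
    equal to machine precision.
    """
    pos = lanes.of_class("positive")
    if (pos <= 0).any().any():
        raise ValueError("positive-control counts must all be > 0")
    geomeans = pos.apply(geometric_mean, axis=0)
    target = float(geomeans.mean())
    factors = target / geomeans
    factors.name = "scale_factor"
    scaled = lanes.counts.mul(factors, axis=1)
    return NanoStringLaneSet(scaled, lanes.probe_class.copy()), factors


def lane_background(negatives) -> float:
    """mean + 2 s.d. (sample s.d., n-1) of a lane's negative controls."""
    arr = np.asarray(negatives, dtype=float)
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return float(arr.mean() + 2.0 * sd)


def background_correct(lanes: NanoStringLaneSet,
                       strict: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract each lane's negative-control background from endogenous counts.

    Expects exactly 8 negative-control probes; with ``strict=False`` other
    counts are tolerated with a warning.  Corrected counts are floored at 0
    (counts cannot be negative).  Returns (corrected endogenous frame,
    per-lane background levels).
    """
    neg = lanes.of_class("negative")
    if len(neg) != 8:
        msg = f"expected 8 negative-control probes, found {len(neg)}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    backgrounds = neg.apply(lane_background, axis=0)
    backgrounds.name = "background"
    endo = lanes.of_class("endogenous")
    corrected = (endo - backgrounds).clip(lower=0.0)
    return corrected, backgrounds


def floor_low_values(corrected: pd.DataFrame, floor: float = DEFAULT_FLOOR,
                     mode: str = "constant",
                     backgrounds: pd.Series | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fix corrected counts below ``floor`` to background level.

    ``mode='constant'`` (default) sets them to the floor constant itself —
    downstream such values are treated as not expressed.  ``mode='lane'``
    sets them to the lane's computed background instead (requires
    ``backgrounds``).  Returns (final frame, boolean below-floor flags).
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    flags = corrected < floor
    if mode == "constant":
        out = corrected.where(~flags, other=floor)
    elif mode == "lane":
        if backgrounds is None:
            raise ValueError("mode='lane' needs per-lane backgrounds")
        out = corrected.copy()
        for lane in out.columns:
            out.loc[flags[lane], lane] = backgrounds[lane]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out, flags


def normalize_lanes(lanes: NanoStringLaneSet, floor: float = DEFAULT_FLOOR,
                    floor_mode: str = "constant",
                    strict: bool = True) -> NormalizedLaneSet:
    """Full chain: spike normalization -> background correction -> flooring."""
    scaled, factors = positive_spike_normalize(lanes)
    corrected, backgrounds = background_correct(scaled, strict=strict)
    final, flags = floor_low_values(corrected, floor=floor, mode=floor_mode,
                                    backgrounds=backgrounds)
    return NormalizedLaneSet(counts=final, scale_factors=factors,
                             backgrounds=backgrounds, below_floor=flags)


def genorm_pairwise_variation(ref_counts: pd.DataFrame) -> pd.DataFrame:
    """geNorm pairwise variation V_jk: s.d. over samples of log2(j/k).

    ``ref_counts`` is genes x samples, strictly positive.  V is symmetric
    with a zero diagonal; two genes exactly proportional across samples
    have V = 0.
    """
    vals = ref_counts.to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("geNorm requires strictly positive counts")
    logv = np.log2(vals)
    n = logv.shape[0]
    v = np.zeros((n, n))
    for j in range(n):
        diffs = logv[j][None, :] - logv
        v[j] = diffs.std(axis=1, ddof=1)
    return pd.DataFrame(v, index=ref_counts.index, columns=ref_counts.index)


def genorm_stability(ref_counts: pd.DataFrame) -> pd.Series:
    """geNorm expression-stability measure M per candidate reference gene.

    ``ref_counts`` is genes x samples with strictly positive counts.  For
    each gene pair (j, k) the pairwise variation V_jk is the s.d. over
    samples of log2(count_j / count_k); M_j is the mean of V_jk over all
    k != j.  Returned ascending (most stable first).  M is invariant to
    rescaling any sample, being ratio-based.
    """
    if ref_counts.shape[0] < 3:
        raise ValueError("geNorm needs at least 3 candidate genes")
    if ref_counts.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    v = genorm_pairwise_variation(ref_counts).to_numpy()
    n = v.shape[0]
    m = np.array([np.delete(v[j], j).mean() for j in range(n)])
    return pd.Series(m, index=ref_counts.index, name="M").sort_values()
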