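"""Synthetic data with planted ground truth for every pipeline stage.

The cell simulator emulates the structure of microfluidic single-cell qPCR
data: a mixture of cell subpopulations, each gene detected per cell with a
subpopulation-specific Bernoulli probability, detected Ct values drawn from
a truncated normal on (0, lod_ct) (so the expression scale spans roughly
2**1..2**14, as observed on the instrument), reference genes amplifying in
every usable cell, identity markers tied to the subpopulation, and a
configurable fraction of contaminant cells that carry lineage-exclusion
markers (or no marker at all) instead of the target marker.

Dropout is Bernoulli, independent per (cell, gene), uncoupled from the Ct
mean — a deliberate simplification sufficient to exercise frequency,
gating, clustering and marker-test logic.

Every generator is bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .datatypes import CtMatrix, GenePanel, NanoStringLaneSet, PWM

_LINEAGE = ("Ptprc", "Itgam", "Cd4", "Cd8", "Cd19", "Ly6g", "Cdh1", "Tnni2")
_REFERENCE = ("Actb", "Gapdh", "Hprt")
_FUNCTION = ("Icam1", "Vcam1", "Acta2", "Il6", "Kdr", "Edn1", "Mki67",
             "Col1a2", "Sele", "Pecam1")


def default_panel(n_gpcrs: int = 154, n_non_spanning: int = 22) -> GenePanel:
    """A synthetic primer-array panel shaped like the real one.

    ``n_gpcrs`` GPCR genes (named ``Gpcr001``...), the last
    ``n_non_spanning`` of which lack intron-spanning primers and are
    excluded from analysis (154 and 22 by default, leaving 132 analyzable);
    the standard identity/lineage markers; a handful of function genes; and
    the three reference genes.
    """
    rows = []
    for i in range(1, n_gpcrs + 1):
        rows.append((f"Gpcr{i:03d}", "gpcr", "none",
                     i <= n_gpcrs - n_non_spanning))
    rows.append(("Cdh5", "identity", "target_ec", True))
    rows.append(("Myh11", "identity", "target_smc", True))
    for g in _LINEAGE:
        rows.append((g, "identity", "lineage_exclusion", True))
    for g in _FUNCTION:
        rows.append((g, "function", "none", True))
    for g in _REFERENCE:
        rows.append((g, "reference", "quality_control", True))
    tab = pd.DataFrame(rows, columns=["gene", "category", "marker_role",
                                      "intron_spanning"]).set_index("gene")
    tab.index.name = None
    return GenePanel(tab)


@dataclass
class SubpopulationSpec:
    """One planted cell subpopulation.

    ``detect_prob`` / ``mean_ct`` are indexed by analyte gene (GPCR and
    function genes); identity/reference genes are handled by the marker
    model, not listed here.
    """

    name: str
    n_cells: int
    target_marker: str
    detect_prob: pd.Series
    mean_ct: pd.Series

    def __post_init__(self) -> None:
        self.detect_prob = self.detect_prob.astype(float)
        self.mean_ct = self.mean_ct.reindex(self.detect_prob.index).astype(float)
        if ((self.detect_prob < 0) | (self.detect_prob > 1)).any():
            raise ValueError("detection probabilities must lie in [0, 1]")
        if self.mean_ct.isna().any():
            raise ValueError("mean_ct must cover every analyte gene")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class SimConfig:
    """Full configuration of the single-cell simulator."""

    panel: GenePanel
    subpops: list[SubpopulationSpec]
    lod_ct: float = 24.0
    sigma_ct: float = 1.5
    marker_mean_ct: float = 14.0
    contamination: float = 0.0
    contaminant_lineage_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_ct <= 0:
            raise ValueError("sigma_ct must be > 0")
        if not (0 <= self.contamination < 1):
            raise ValueError("contamination must be in [0, 1)")
        analytes = set(self.panel.genes_of("gpcr")) | set(self.panel.genes_of("function"))
        for sp in self.subpops:
            extra = set(sp.detect_prob.index) - analytes
            if extra:
                raise ValueError(f"subpop {sp.name}: non-analyte genes {sorted(extra)[:5]}")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    cell_labels: pd.Series          # true subpopulation of each cell
    is_contaminant: pd.Series
    contaminant_kind: pd.Series     # 'lineage', 'no_marker' or ''
    detect_prob: pd.DataFrame       # subpop x analyte gene
    mean_ct: pd.DataFrame
    diff_genes: dict[str, list[str]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _trunc_ct(rng: np.random.Generator, mean, sigma: float, lod: float,
              size) -> np.ndarray:
    """Detected Ct values ~ Normal(mean, sigma) truncated to (0, lod)."""
    mean = np.asarray(mean, dtype=float)
    a = (0.0 - mean) / sigma
    b = (lod - mean) / sigma
    return truncnorm.rvs(a, b, loc=mean, scale=sigma, size=size,
                         random_state=rng)


def simulate_ct_matrix(cfg: SimConfig) -> tuple[CtMatrix, SimTruth]:
    """Draw a Ct matrix (plus ground truth) from the mixture model.

    Pure cells amplify all reference genes and their subpopulation's target
    marker near ``marker_mean_ct``; analyte genes follow the per-gene
    Bernoulli/truncated-normal model.  Contaminant cells (drawn i.i.d. at
    rate ``contamination`` within every subpopulation) lack the target
    marker and instead carry one random lineage-exclusion marker (with
    probability ``contaminant_lineage_prob``) or no marker at all.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.panel.genes
    ref_genes = cfg.panel.with_role("quality_control")
    lineage_genes = cfg.panel.with_role("lineage_exclusion")
    gene_pos = {g: i for i, g in enumerate(genes)}

    blocks, labels, contam, kinds, ids = [], [], [], [], []
    cell_counter = 0
    for sp in cfg.subpops:
        n = sp.n_cells
        block = np.full((n, len(genes)), np.nan)
        is_cont = rng.random(n) < cfg.contamination
        has_lineage = is_cont & (rng.random(n) < cfg.contaminant_lineage_prob)

        for g in ref_genes:
            block[:, gene_pos[g]] = _trunc_ct(rng, cfg.marker_mean_ct,
                                              cfg.sigma_ct, cfg.lod_ct, n)
        pure = ~is_cont
        block[pure, gene_pos[sp.target_marker]] = _trunc_ct(
            rng, cfg.marker_mean_ct, cfg.sigma_ct, cfg.lod_ct, int(pure.sum()))
        for i in np.flatnonzero(has_lineage):
            g = lineage_genes[rng.integers(len(lineage_genes))]
            block[i, gene_pos[g]] = _trunc_ct(rng, cfg.marker_mean_ct,
                                              cfg.sigma_ct, cfg.lod_ct, 1)[0]

        analytes = list(sp.detect_prob.index)
        p = sp.detect_prob.to_numpy()
        mu = sp.mean_ct.to_numpy()
        detected = rng.random((n, len(analytes))) < p[None, :]
        cts = _trunc_ct(rng, np.broadcast_to(mu, (n, len(analytes))),
                        cfg.sigma_ct, cfg.lod_ct, (n, len(analytes)))
        cols = [gene_pos[g] for g in analytes]
        sub = np.full((n, len(analytes)), np.nan)
        sub[detected] = cts[detected]
        block[:, cols] = sub

        blocks.append(block)
        labels += [sp.name] * n
        contam += list(is_cont)
        kinds += ["lineage" if hl else ("no_marker" if ic else "")
                  for ic, hl in zip(is_cont, has_lineage)]
        ids += [f"{sp.name}_c{cell_counter + j:04d}" for j in range(n)]
        cell_counter += n

    ct = pd.DataFrame(np.vstack(blocks), index=ids, columns=genes)
    meta = pd.DataFrame({"group": labels}, index=ids)
    truth = SimTruth(
        cell_labels=pd.Series(labels, index=ids, name="subpop"),
        is_contaminant=pd.Series(contam, index=ids, name="is_contaminant"),
        contaminant_kind=pd.Series(kinds, index=ids, name="kind"),
        detect_prob=pd.DataFrame({sp.name: sp.detect_prob for sp in cfg.subpops}).T,
        mean_ct=pd.DataFrame({sp.name: sp.mean_ct for sp in cfg.subpops}).T,
    )
    return CtMatrix(ct, meta), truth


# ---------------------------------------------------------------------------
# Convenience configurations
# ---------------------------------------------------------------------------

def heterogeneous_probs(genes: Sequence[str], rng: np.random.Generator,
                        zero_fraction: float = 0.4,
                        beta_a: float = 0.6, beta_b: float = 1.6) -> pd.Series:
    """Per-gene detection probabilities with a realistic frequency spectrum:
    a fraction of genes never detected, the rest Beta-distributed (few
    near-ubiquitous genes, many rare ones)."""
    p = rng.beta(beta_a, beta_b, size=len(genes))
    p[rng.random(len(genes)) < zero_fraction] = 0.0
    return pd.Series(p, index=list(genes))


def smc_like_config(n_cells: int = 60, contamination: float = 0.0,
                    seed: int = 0, panel: GenePanel | None = None) -> SimConfig:
    """A single aortic-SMC-like population with heterogeneous GPCR detection."""
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    analytes = panel.gpcrs(intron_spanning_only=False) + panel.genes_of("function")
    probs = heterogeneous_probs(analytes, rng)
    mean_ct = pd.Series(rng.uniform(16.0, 23.0, size=len(analytes)),
                        index=analytes)
    sp = SubpopulationSpec("SMao", n_cells, "Myh11", probs, mean_ct)
    return SimConfig(panel=panel, subpops=[sp], contamination=contamination,
                     seed=seed + 1)


def clustered_config(sizes: Sequence[int] = (60, 57, 29),
                     n_diff: int = 20, p_high: float = 0.8,
                     p_low: float = 0.2, seed: int = 0,
                     target_marker: str = "Myh11",
                     panel: GenePanel | None = None) -> SimConfig:
    """Three (or more) subpopulations with planted differential genes.

    Each subpopulation gets ``n_diff`` private genes detected at ``p_high``
    versus ``p_low`` elsewhere — a 4-fold planted separation in mean
    expression at the defaults.  Remaining analytes share one heterogeneous
    background profile.  Subpopulations are named ``pop1``, ``pop2``, ...
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    analytes = panel.gpcrs(intron_spanning_only=True)
    if len(analytes) < n_diff * len(sizes):
        raise ValueError("not enough analyzable genes for the requested design")
    base = heterogeneous_probs(analytes, rng, zero_fraction=0.2)
    mean_ct = pd.Series(rng.uniform(16.0, 22.0, size=len(analytes)),
                        index=analytes)
    order = rng.permutation(len(analytes))
    subpops, diff_map = [], {}
    for j, n in enumerate(sizes):
        name = f"pop{j + 1}"
        mine = [analytes[i] for i in order[j * n_diff:(j + 1) * n_diff]]
        diff_map[name] = mine
        probs = base.copy()
        for jj in range(len(sizes)):
            others = [analytes[i]
                      for i in order[jj * n_diff:(jj + 1) * n_diff]]
            probs[others] = p_high if jj == j else p_low
        subpops.append(SubpopulationSpec(name, n, target_marker, probs, mean_ct))
    cfg = SimConfig(panel=panel, subpops=subpops, seed=seed + 1)
    cfg._diff_genes = diff_map  # type: ignore[attr-defined]
    return cfg


def simulate_clustered(sizes: Sequence[int] = (60, 57, 29), n_diff: int = 20,
                       seed: int = 0, **kw) -> tuple[CtMatrix, SimTruth]:
    cfg = clustered_config(sizes=sizes, n_diff=n_diff, seed=seed, **kw)
    m, truth = simulate_ct_matrix(cfg)
    truth.diff_genes = cfg._diff_genes  # type: ignore[attr-defined]
    return m, truth


# ---------------------------------------------------------------------------
# Correlated gene pairs
# ---------------------------------------------------------------------------

def simulate_correlated_pair(n: int, rho_target: float, seed: int = 0,
                             mean_ct: float = 18.0, sigma_ct: float = 2.0,
                             lod_ct: float = 24.0) -> tuple[np.ndarray, np.ndarray]:
    """Two expression vectors with latent (Gaussian-copula) correlation.

    A bivariate normal with correlation ``rho_target`` drives the Ct values
    (higher latent value = earlier amplification); values at/beyond the
    detection limit are censored to 0 exactly as the LoD transform would.
    The Spearman correlation of the output approaches the monotone-
    transform-invariant value (6/pi)*arcsin(rho/2) of the Gaussian copula,
    shrunk slightly by the censoring ties.
    """
    if not (-1 < rho_target < 1):
        raise ValueError("|rho_target| must be < 1")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho_target], [rho_target, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    ct = mean_ct - sigma_ct * z
    vals = np.where((ct > 0) & (ct < lod_ct), np.exp2(lod_ct - ct), 0.0)
    return vals[:, 0], vals[:, 1]


# ---------------------------------------------------------------------------
# Promoters with planted motifs
# ---------------------------------------------------------------------------

def random_pwm(length: int, seed: int = 0, name: str = "PWM",
               total: int = 100, concentration: float = 0.3) -> PWM:
    """A random informative PWM (Dirichlet columns scaled to ``total``)."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([concentration] * 4, size=length).T
    return PWM(tf_name=name, counts=np.rint(probs * total) )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_promoters(n_genes: int, length: int = 1000,
                       motif: PWM | None = None,
                       planted_set: Iterable[str] = (),
                       seed: int = 0,
                       base_freqs: Sequence[float] | None = None,
                       gene_prefix: str = "gene") -> tuple[dict[str, str], dict]:
    """I.i.d. background promoters with one motif instance per planted gene.

    Gene ids are ``{gene_prefix}001``...; genes named in ``planted_set``
    receive one instance sampled from the motif's probability matrix,
    inserted at a uniform position on a uniform strand.  Returns
    (promoters, truth) where truth records the planted (position, strand,
    site) per gene.
    """
    rng = np.random.default_rng(seed)
    bg = np.asarray(base_freqs if base_freqs is not None else [0.25] * 4, float)
    bg = bg / bg.sum()
    planted = set(planted_set)
    names = [f"{gene_prefix}{i + 1:03d}" for i in range(n_genes)]
    unknown = planted - set(names)
    if unknown:
        raise ValueError(f"planted genes outside the generated set: {sorted(unknown)[:5]}")
    if motif is None and planted:
        raise ValueError("a motif is required when planting instances")
    if motif is not None and len(motif) >= length:
        raise ValueError("motif must be shorter than the promoter")

    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    truth: dict[str, dict] = {}
    for name in names:
        seq = "".join(bases[rng.choice(4, size=length, p=bg)])
        if name in planted:
            probs = motif.probabilities()
            site = "".join(bases[[rng.choice(4, p=probs[:, j])
                                  for j in range(len(motif))]])
            strand = "+" if rng.random() < 0.5 else "-"
            insert = site if strand == "+" else reverse_complement(site)
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:pos] + insert + seq[pos + len(motif):]
            truth[name] = {"position": pos, "strand": strand, "site": site}
        promoters[name] = seq
    return promoters, {"planted": truth, "motif": None if motif is None else motif.tf_name}


# ---------------------------------------------------------------------------
# NanoString lanes
# ---------------------------------------------------------------------------

#: Positive-control ladder (counts in an unattenuated lane).
POSITIVE_LADDER = (32.0, 128.0, 512.0, 2048.0, 8192.0, 32768.0)


def simulate_nanostring(factors: Sequence[float], seed: int = 0,
                        n_endogenous: int = 100,
                        background_level: float = 10.0,
                        noise: bool = True,
                        profile: np.ndarray | None = None
                        ) -> tuple[NanoStringLaneSet, dict]:
    """Lanes sharing one endogenous profile, attenuated per lane.

    Lane ``i`` observes ``profile / factors[i]`` (positives from the fixed
    ladder, scaled identically), with Poisson noise unless
    ``noise=False``; its eight negative controls are Poisson around
    ``background_level`` (exactly ``background_level`` when noiseless).

    Spike normalization identifies scale factors only up to the across-lane
    target constant, so the truth dict reports both the requested
    ``factors`` and the ``recoverable_factors``
    (``factors * mean(1/factors)``) that the normalization recovers exactly
    in the noiseless case.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("factors must be > 0")
    rng = np.random.default_rng(seed)
    n_lanes = factors.size
    if profile is None:
        profile = np.exp(rng.uniform(np.log(50.0), np.log(8000.0),
                                     size=n_endogenous))
    profile = np.asarray(profile, dtype=float)

    lanes = {}
    for i, f in enumerate(factors):
        endo = profile / f
        pos = np.asarray(POSITIVE_LADDER) / f
        neg = np.full(8, background_level)
        lane = np.concatenate([endo, pos, neg])
        if noise:
            lane = rng.poisson(lane).astype(float)
        lanes[f"lane{i + 1}"] = lane

    probe_ids = ([f"Endo{j + 1:03d}" for j in range(profile.size)]
                 + [f"POS_{c}" for c in "ABCDEF"[:len(POSITIVE_LADDER)]]
                 + [f"NEG_{c}" for c in "ABCDEFGH"])
    classes = (["endogenous"] * profile.size
               + ["positive"] * len(POSITIVE_LADDER)
               + ["negative"] * 8)
    counts = pd.DataFrame(lanes, index=probe_ids)
    lane_set = NanoStringLaneSet(counts=counts,
                                 probe_class=pd.Series(classes, index=probe_ids))
    truth = {
        "factors": factors,
        "recoverable_factors": factors * np.mean(1.0 / factors),
        "profile": profile,
        "background_level": background_level,
    }
    return lane_set, truth
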