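"""Stage orchestration: gate -> express -> cluster / network (+ optional
TFBS enrichment and NanoString normalization), driven by one flat config.

Every stage writes its outputs in the standard text formats of
:mod:`scgpcr.io` under a run directory, and a manifest records the config
snapshot, input digests, seeds and package version so a rerun with the same
manifest reproduces the deterministic stages byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__, io
from .clustering import (ClusterParams, cluster_marker_genes,
                         correlation_features, kmeans_cluster, tsne_embed)
from .expression import expression_frequency, lod_transform, receptors_per_cell
from .gating import GatingConfig, gate_cells
from .nanostring import normalize_lanes
from .network import build_network
from .tfbs import enrich_gene_sets

logger = logging.getLogger(__name__)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Required config keys: ``ct`` (Ct matrix path), ``panel`` (gene panel
    path), ``target`` ('ec' or 'smc').  Optional: ``lod`` (default 24),
    ``k`` (cluster count or 'auto'), ``seed``, ``network_threshold``,
    ``promoters`` + ``motifs`` + ``gene_sets`` (TFBS stage),
    ``nanostring_counts`` (NanoString stage).

    Returns the manifest (also written to ``manifest.json``).  A stage
    failure raises :class:`StageError` naming the stage; outputs of earlier
    stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dict(config),
        "inputs": {},
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    seed = int(config.get("seed", 0))
    lod = float(config.get("lod", 24.0))

    def stage(name):
        def wrap(fn):
            try:
                t0 = time.time()
                fn()
                manifest["stages"].append({"name": name,
                                           "seconds": round(time.time() - t0, 3)})
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    state: dict = {}

    @stage("qc_gating")
    def _gate():
        for key in ("ct", "panel"):
            if key not in config:
                raise FileNotFoundError(f"qc_gating needs config key {key!r}")
        manifest["inputs"]["ct"] = _digest(config["ct"])
        manifest["inputs"]["panel"] = _digest(config["panel"])
        m = io.read_ct_matrix(config["ct"])
        panel = io.read_gene_panel(config["panel"])
        gcfg = GatingConfig(lod_ct=lod)
        allow = config.get("allow_low")
        if allow:
            marker, thr = str(allow).split(":")
            gcfg.allow_low_cross_marker = (marker, float(thr))
        res = gate_cells(m, panel, gcfg, target=config.get("target", "smc"))
        io.write_ct_matrix(res.retained, out / "retained_ct.csv")
        res.contamination.to_csv(out / "contamination.tsv", sep="\t")
        res.labels.to_csv(out / "gating_labels.csv")
        state["panel"] = panel
        state["retained"] = res.retained

    @stage("expression")
    def _express():
        e = lod_transform(state["retained"], lod_ct=lod)
        e.values.to_csv(out / "expression.csv")
        expression_frequency(e).to_csv(out / "frequency.tsv", sep="\t")
        receptors_per_cell(e, state["panel"]).to_csv(out / "receptors_per_cell.tsv",
                                                     sep="\t")
        state["expr"] = e

    @stage("clustering")
    def _cluster():
        e = state["expr"]
        if e.n_cells < 4:
            logger.warning("too few retained cells for clustering; skipped")
            return
        params = ClusterParams(k=config.get("k", "auto"), seed=seed,
                               tsne_seed=seed)
        feats = correlation_features(e)
        res = kmeans_cluster(feats, params)
        res.labels.to_csv(out / "clusters.csv")
        if not res.degenerate:
            markers = cluster_marker_genes(e, res.labels, params)
            markers.to_csv(out / "cluster_markers.tsv", sep="\t", index=False)
        tsne_embed(feats, params).to_csv(out / "embedding.csv")

    @stage("network")
    def _network():
        e = state["expr"]
        if e.n_cells < 3:
            logger.warning("too few cells for a correlation network; skipped")
            return
        genes = None
        if config.get("network_genes"):
            genes = io.read_gene_set(config["network_genes"])
        net = build_network(e, genes=genes,
                            threshold=float(config.get("network_threshold", 0.3)))
        io.write_edge_list(net, out / "network_edges.tsv")

    if config.get("promoters") and config.get("motifs"):
        @stage("tfbs_enrich")
        def _tfbs():
            from .tfbs import score_promoters, z_transform_table
            manifest["inputs"]["promoters"] = _digest(config["promoters"])
            manifest["inputs"]["motifs"] = _digest(config["motifs"])
            promoters = io.read_promoters(config["promoters"])
            pwms = io.read_jaspar_pfms(config["motifs"])
            scores = score_promoters(promoters, pwms)
            sets = {}
            for item in config.get("gene_sets", []):
                name, path = item.split(":") if ":" in item else (Path(item).stem, item)
                sets[name] = io.read_gene_set(path)
            if sets:
                rows = enrich_gene_sets(scores, sets)
                rows.to_csv(out / "tfbs_enrichment.tsv", sep="\t", index=False)
                z_transform_table(rows).to_csv(out / "tfbs_signed_z.tsv", sep="\t")
            scores.to_csv(out / "tfbs_scores.tsv", sep="\t")

    if config.get("nanostring_counts"):
        @stage("nanostring")
        def _nano():
            manifest["inputs"]["nanostring_counts"] = _digest(config["nanostring_counts"])
            lanes = io.read_nanostring_counts(config["nanostring_counts"])
            norm = normalize_lanes(lanes)
            norm.counts.to_csv(out / "nanostring_normalized.csv")
            report = pd.DataFrame({"scale_factor": norm.scale_factors,
                                   "background": norm.backgrounds})
            report.to_csv(out / "nanostring_lane_report.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
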