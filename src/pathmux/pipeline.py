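"""End-to-end orchestration: one network build, embedding, scoring and CSSPN
per disease feature, driven by a flat declarative config.

A separate network is built for each disease feature (each feature has its
own risk catalog slice and therefore its own prioritization run); pathway
membership links and layers are shared inputs.  Outputs carry the hash of
the resolved config so reruns are auditable; no output file is written
unless its producing stage completed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from pathmux import cerna, io_formats, prioritization
from pathmux.embedding import rwr_all, svd_embed
from pathmux.multiplex import WalkParams, build_network, to_commixture
from pathmux.prioritization import NullModel, score_pathways, select_significant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Flat declarative pipeline configuration; every field has a default.

    Unknown keys in a config document are rejected before any compute.
    Precedence elsewhere: CLI flag > config file > default.
    """

    # inputs
    gene_edges: str = ""
    mirna_edges: str = ""
    targets: str = ""
    lnc_mi: str = ""
    gmt: str = ""
    catalog: str = ""
    snps: str = ""
    outdir: str = "pathmux_out"
    # walk / embedding
    restart_prob: float = 0.7
    delta: float = 0.3
    lam: float = 0.2
    dim: int = 0              # 0 -> min(128, n-1)
    tol: float = 1e-10
    max_iter: int = 10_000
    symmetrize: bool = False
    log1p: bool = False
    # null model / thresholds
    n_perm: int = 199
    seed: int = 0
    ranking_threshold: float = 6.0
    p_threshold: float = 0.05
    feature_strict: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        return cls.from_mapping(doc)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run build -> embed -> score -> select -> CSSPN for every feature.

    Returns a manifest of written output paths.  Raises (and writes no
    partial stage output) on the first stage error.
    """
    for key in ("gene_edges", "mirna_edges", "targets", "gmt", "catalog"):
        p = getattr(config, key)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"required input {key!r} missing: {p!r}")
    params = WalkParams(restart_prob=config.restart_prob,
                        delta=config.delta, lam=config.lam)
    logger.info("resolved config (hash %s): %s", config.config_hash(),
                json.dumps(dataclasses.asdict(config), sort_keys=True))

    gene_edges = io_formats.read_edge_list(config.gene_edges)
    mirna_edges = io_formats.read_edge_list(config.mirna_edges)
    targets = io_formats.read_interactions(config.targets, "miRNA", "mRNA")
    pathways = io_formats.read_gmt(config.gmt)
    catalog = io_formats.read_risk_catalog(config.catalog)
    lnc_mi = (io_formats.read_interactions(config.lnc_mi, "lncRNA", "miRNA")
              if config.lnc_mi else [])
    snps, _diag = (io_formats.read_snp_table(config.snps)
                   if config.snps else ([], []))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "features": {}}
    with open(outdir / "config.resolved.json", "w") as fh:
        json.dump({"hash": config.config_hash(),
                   **dataclasses.asdict(config)}, fh, indent=1, sort_keys=True)

    features = sorted({e.feature for e in catalog})
    for feature in features:
        feat_entries = [e for e in catalog if e.feature == feature]
        risk_molecules = [e.molecule_id for e in feat_entries
                          if e.molecule_type in ("mRNA", "miRNA")]
        net = build_network(gene_edges, mirna_edges, targets, pathways)
        T = to_commixture(net, params)
        P = rwr_all(T, r=params.restart_prob, tol=config.tol,
                    max_iter=config.max_iter)
        emb = svd_embed(P, d=config.dim or None,
                        symmetrize=config.symmetrize, log1p=config.log1p)
        null = NullModel(n_permutations=config.n_perm, seed=config.seed)
        scores = score_pathways(emb, net, risk_molecules, feature, null=null)
        significant = select_significant(
            scores, ranking_threshold=config.ranking_threshold,
            p_threshold=config.p_threshold)

        score_path = outdir / f"scores.{feature}.tsv"
        io_formats.write_scores(scores, score_path)
        sig_path = outdir / f"significant.{feature}.tsv"
        io_formats.write_scores(significant, sig_path)
        feat_manifest = {"scores": str(score_path),
                         "significant": str(sig_path)}

        if lnc_mi:
            regs = []
            by_pathway = {p.pathway_id: p for p in pathways}
            for s in significant:
                regs.extend(cerna.build_cerna_network(
                    by_pathway[s.pathway_id], feature, catalog, lnc_mi,
                    targets, feature_strict=config.feature_strict))
            regs = cerna.annotate_snps(regs, snps)
            node_path = outdir / f"csspn.nodes.{feature}.tsv"
            edge_path = outdir / f"csspn.edges.{feature}.tsv"
            graphml_path = outdir / f"csspn.{feature}.graphml"
            cerna.export_csspn(regs, node_path, edge_path, graphml_path)
            stats = []
            for pid in sorted({r.pathway_id for r in regs}):
                sub = [r for r in regs if r.pathway_id == pid]
                st = cerna.compute_stats(sub)
                stats.append(dataclasses.asdict(st))
            with open(outdir / f"csspn.stats.{feature}.json", "w") as fh:
                json.dump(stats, fh, indent=1, sort_keys=True)
            feat_manifest.update({
                "csspn_nodes": str(node_path),
                "csspn_edges": str(edge_path),
                "csspn_graphml": str(graphml_path),
                "n_regulations": len(regs),
                "n_switch_candidates":
                    len(cerna.find_switch_candidates(regs)),
            })
        manifest["features"][feature] = feat_manifest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
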