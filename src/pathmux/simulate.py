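"""Seeded synthetic input bundles with planted pathway signal.

The generator emulates the full input ecosystem — a weighted gene-gene
layer, a weighted miRNA-miRNA layer, miRNA->mRNA and lncRNA->miRNA
interaction tables, a GMT pathway collection split over two synthetic
source databases, a disease-feature risk catalog, and a classified SNP
table — with one pathway "planted": its members form a densified module in
the gene layer and the risk catalog is drawn preferentially from that
module and from miRNAs targeting at least two module members.  Planting
works through topology (extra module edges), not inflated weights, so
recovering it exercises the random walk rather than trivial weight leakage.

All randomness flows through one numpy Generator (PCG64) seeded from the
config; bundles are byte-identical across runs and platforms for a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from pathmux.io_formats import (
    InteractionRecord,
    PathwayRecord,
    RiskCatalogEntry,
    SnpRecord,
    WeightedEdge,
)

SOURCE_DBS = ("SYNDB_A", "SYNDB_B")

#: edge probability inside the planted module (densification, not weights)
PLANTED_MODULE_EDGE_PROB = 0.8


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-bundle configuration.

    planted_pathway_fraction is the fraction of the risk set drawn from the
    planted pathway's members (mRNAs) and from miRNAs targeting >= 2 of its
    members; the remainder is drawn uniformly.  snp_rate_per_edge is the
    per-eligible-edge probability of emitting a regulatory SNP.
    """

    n_mrna: int = 200
    n_mirna: int = 50
    n_lncrna: int = 10
    n_pathways: int = 20
    pathway_size_range: tuple = (15, 30)
    planted_pathway_fraction: float = 0.7
    background_edge_prob: float = 0.05
    intra_weight_range: tuple = (0.2, 0.9)
    snp_rate_per_edge: float = 0.3
    seed: int = 0
    n_risk_mrna: int = 15
    n_risk_mirna: int = 6
    n_risk_lncrna: int = 4
    feature: str = "inflammation"

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_mirna", "n_lncrna", "n_pathways",
                     "n_risk_mrna", "n_risk_mirna", "n_risk_lncrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.planted_pathway_fraction <= 1:
            raise ValueError("planted_pathway_fraction must be in (0,1]")
        if not 0 <= self.background_edge_prob <= 1:
            raise ValueError("background_edge_prob must be in [0,1]")
        if not 0 <= self.snp_rate_per_edge <= 1:
            raise ValueError("snp_rate_per_edge must be in [0,1]")
        lo, hi = self.pathway_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid pathway_size_range")
        if hi > self.n_mrna:
            raise ValueError("pathway size range exceeds the mRNA layer size")


@dataclass
class Bundle:
    """A complete, self-consistent in-memory input bundle plus ground truth."""

    config: SimConfig
    gene_edges: list
    mirna_edges: list
    target_edges: list          # miRNA->mRNA InteractionRecord
    lnc_mi_edges: list          # lncRNA->miRNA InteractionRecord
    pathways: list              # PathwayRecord
    catalog: list               # RiskCatalogEntry
    snps: list                  # SnpRecord
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> dict:
        """Emit the bundle in exactly the dialects io_formats reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def edge_file(name, edges):
            p = outdir / name
            with open(p, "w") as fh:
                fh.write("source\ttarget\tweight\n")
                for e in edges:
                    fh.write(f"{e.source}\t{e.target}\t{e.weight:.6f}\n")
            return p

        paths["gene_edges"] = edge_file("gene_edges.tsv", self.gene_edges)
        paths["mirna_edges"] = edge_file("mirna_edges.tsv", self.mirna_edges)

        def interaction_file(name, records):
            p = outdir / name
            with open(p, "w") as fh:
                fh.write("regulator\ttarget\tevidence\n")
                for r in records:
                    fh.write(f"{r.regulator}\t{r.target}\t{r.evidence}\n")
            return p

        paths["targets"] = interaction_file("mi_targets.tsv", self.target_edges)
        paths["lnc_mi"] = interaction_file("lnc_mi.tsv", self.lnc_mi_edges)

        paths["gmt"] = outdir / "pathways.gmt"
        with open(paths["gmt"], "w") as fh:
            for p in self.pathways:
                fh.write("\t".join([p.pathway_id, p.source_db,
                                    *sorted(p.members)]) + "\n")

        paths["catalog"] = outdir / "risk_catalog.tsv"
        with open(paths["catalog"], "w") as fh:
            fh.write("molecule_id\tmolecule_type\tfeature\n")
            for e in self.catalog:
                fh.write(f"{e.molecule_id}\t{e.molecule_type}\t{e.feature}\n")

        paths["snps"] = outdir / "snps.tsv"
        with open(paths["snps"], "w") as fh:
            fh.write("rsid\thost_molecule\thost_type\tlocation_class\t"
                     "partner_molecule\n")
            for s in self.snps:
                fh.write(f"{s.rsid}\t{s.host_molecule}\t{s.host_type}\t"
                         f"{s.location_class}\t{s.partner_molecule or ''}\n")

        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump({"config": asdict(self.config), **self.truth}, fh,
                      indent=1, sort_keys=True)
        return paths


def _random_layer(rng, nodes, p, wlo, whi):
    """Erdos-Renyi background with uniform weights; returns canonical edges."""
    n = len(nodes)
    edges = {}
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < p
    weights = rng.uniform(wlo, whi, size=iu.shape[0])
    for i, j, keep, w in zip(iu, ju, mask, weights):
        if keep:
            edges[(nodes[i], nodes[j])] = float(w)
    return edges


def random_multiplex_network(rng, n_mrna=12, n_mirna=6, n_pathways=3, p=0.25):
    """A small random multiplex-heterogeneous network for property checks.

    Deliberately produces degenerate structure alongside the background:
    roughly half the miRNAs get no coupling edges (a missing edge class at
    those columns) and the last pathway is sometimes unlinkable (a dangling
    node that must receive a self-loop).  Used by the verification suite and
    the results script; not a study-condition generator.
    """
    from pathmux.multiplex import build_network

    mrnas = [f"G{i}" for i in range(n_mrna)]
    mirnas = [f"M{i}" for i in range(n_mirna)]
    gene_edges, mirna_edges = [], []
    for pool, out in ((mrnas, gene_edges), (mirnas, mirna_edges)):
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if rng.random() < p:
                    out.append(WeightedEdge(pool[i], pool[j],
                                            float(rng.uniform(0.1, 1.0))))
        # keep every node registered in its layer
        present = {n for e in out for n in (e.source, e.target)}
        for i, node in enumerate(pool):
            if node not in present:
                other = pool[(i + 1) % len(pool)]
                out.append(WeightedEdge.canonical(node, other,
                                                  float(rng.uniform(0.1, 1.0))))
                present.update((node, other))
    targets = []
    for mi in mirnas[: max(1, n_mirna // 2)]:
        for m in mrnas:
            if rng.random() < p:
                targets.append(InteractionRecord(mi, m, "miRNA", "mRNA"))
    pathways = []
    for k in range(n_pathways):
        if k == n_pathways - 1 and rng.random() < 0.5:
            members = frozenset({"UNREGISTERED_GENE"})
        else:
            size = int(rng.integers(2, max(3, n_mrna // 2)))
            members = frozenset(rng.choice(mrnas, size=size, replace=False))
        pathways.append(PathwayRecord(f"P{k}", f"P{k}", "DB", members))
    return build_network(gene_edges, mirna_edges, targets, pathways)


def generate_bundle(cfg: SimConfig) -> Bundle:
    """Generate one fully reproducible bundle with planted pathway signal."""
    rng = np.random.default_rng(cfg.seed)
    wlo, whi = cfg.intra_weight_range
    mrnas = [f"G{i:04d}" for i in range(1, cfg.n_mrna + 1)]
    mirnas = [f"MIR{i:03d}" for i in range(1, cfg.n_mirna + 1)]
    lncrnas = [f"LNC{i:02d}" for i in range(1, cfg.n_lncrna + 1)]

    # pathways: random member sets over mRNAs, alternating source databases
    lo, hi = cfg.pathway_size_range
    pathways = []
    for k in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(mrnas, size=size, replace=False))
        pid = f"PW{k+1:02d}"
        pathways.append(PathwayRecord(pid, pid, SOURCE_DBS[k % len(SOURCE_DBS)],
                                      members))
    planted = pathways[0]
    planted_members = sorted(planted.members)

    # gene layer: background plus densified module over the planted members
    gene_edges = _random_layer(rng, mrnas, cfg.background_edge_prob, wlo, whi)
    for a_i in range(len(planted_members)):
        for b_i in range(a_i + 1, len(planted_members)):
            if rng.random() < PLANTED_MODULE_EDGE_PROB:
                key = (planted_members[a_i], planted_members[b_i])
                w = float(rng.uniform(wlo, whi))
                gene_edges[key] = max(gene_edges.get(key, 0.0), w)
    gene_edge_list = [WeightedEdge(a, b, w)
                      for (a, b), w in sorted(gene_edges.items())]

    # miRNA layer
    mirna_edges = _random_layer(rng, mirnas, cfg.background_edge_prob, wlo, whi)
    # guarantee every miRNA is registered in its layer (chain fallback)
    touched = {n for e in mirna_edges for n in e}
    for i, mi in enumerate(mirnas):
        if mi not in touched:
            other = mirnas[(i + 1) % len(mirnas)]
            key = tuple(sorted((mi, other)))
            mirna_edges[key] = float(rng.uniform(wlo, whi))
            touched.update(key)
    mirna_edge_list = [WeightedEdge(a, b, w)
                       for (a, b), w in sorted(mirna_edges.items())]

    # miRNA -> mRNA couplings: random background plus planted miRNAs that
    # target >= 2 planted-module members
    target_pairs = set()
    n_bg_targets = int(cfg.background_edge_prob * cfg.n_mirna * cfg.n_mrna * 0.5)
    for _ in range(n_bg_targets):
        mi = mirnas[int(rng.integers(cfg.n_mirna))]
        m = mrnas[int(rng.integers(cfg.n_mrna))]
        target_pairs.add((mi, m))
    n_planted_mirna = max(2, int(round(cfg.planted_pathway_fraction
                                       * cfg.n_risk_mirna)))
    planted_mirnas = sorted(rng.choice(mirnas, size=n_planted_mirna,
                                       replace=False))
    for mi in planted_mirnas:
        k = int(rng.integers(2, min(5, len(planted_members)) + 1))
        for m in rng.choice(planted_members, size=k, replace=False):
            target_pairs.add((mi, str(m)))
    target_edges = [InteractionRecord(mi, m, "miRNA", "mRNA", "synthetic")
                    for mi, m in sorted(target_pairs)]

    # lncRNA -> miRNA interactions: each lncRNA sponges a few miRNAs
    lnc_pairs = set()
    for l in lncrnas:
        k = int(rng.integers(2, 7))
        for mi in rng.choice(mirnas, size=min(k, cfg.n_mirna), replace=False):
            lnc_pairs.add((l, str(mi)))
    # make sure planted miRNAs are sponged by at least one lncRNA
    for mi in planted_mirnas:
        if not any(p[1] == mi for p in lnc_pairs):
            lnc_pairs.add((lncrnas[int(rng.integers(cfg.n_lncrna))], mi))
    lnc_mi_edges = [InteractionRecord(l, mi, "lncRNA", "miRNA", "synthetic")
                    for l, mi in sorted(lnc_pairs)]

    # risk catalog: fraction f from the planted module / planted miRNAs
    gene_layer_nodes = {n for e in gene_edge_list for n in (e.source, e.target)}
    module_avail = sorted(set(planted_members) & gene_layer_nodes)
    other_avail = sorted(gene_layer_nodes - set(planted_members))
    k_planted = min(int(round(cfg.planted_pathway_fraction * cfg.n_risk_mrna)),
                    len(module_avail))
    risk_mrnas = sorted(rng.choice(module_avail, size=k_planted, replace=False))
    n_rest = min(cfg.n_risk_mrna - k_planted, len(other_avail))
    if n_rest > 0:
        risk_mrnas += sorted(rng.choice(other_avail, size=n_rest, replace=False))

    k_mi_planted = min(int(round(cfg.planted_pathway_fraction
                                 * cfg.n_risk_mirna)), len(planted_mirnas))
    risk_mirnas = sorted(rng.choice(planted_mirnas, size=k_mi_planted,
                                    replace=False))
    other_mirnas = sorted(set(mirnas) - set(risk_mirnas))
    n_rest = min(cfg.n_risk_mirna - k_mi_planted, len(other_mirnas))
    if n_rest > 0:
        risk_mirnas += sorted(rng.choice(other_mirnas, size=n_rest,
                                         replace=False))

    # admit the lncRNAs that sponge risk miRNAs first, fill uniformly
    sponsoring = sorted({l for l, mi in lnc_pairs if mi in set(risk_mirnas)})
    risk_lncs = sponsoring[: cfg.n_risk_lncrna]
    other_lncs = sorted(set(lncrnas) - set(risk_lncs))
    n_rest = min(cfg.n_risk_lncrna - len(risk_lncs), len(other_lncs))
    if n_rest > 0:
        risk_lncs += sorted(rng.choice(other_lncs, size=n_rest, replace=False))

    catalog = (
        [RiskCatalogEntry(m, "mRNA", cfg.feature) for m in sorted(risk_mrnas)]
        + [RiskCatalogEntry(m, "miRNA", cfg.feature) for m in sorted(risk_mirnas)]
        + [RiskCatalogEntry(l, "lncRNA", cfg.feature) for l in sorted(risk_lncs)]
    )

    # SNPs: per eligible edge across the three regulatory classes, plus a
    # thin sprinkling of host (gene-body / pri-pre-miRNA) SNPs
    snps = []
    rs_counter = 1

    def next_rsid():
        nonlocal rs_counter
        rsid = f"rs9{rs_counter:08d}"
        rs_counter += 1
        return rsid

    for l, mi in sorted(lnc_pairs):
        if rng.random() < cfg.snp_rate_per_edge:
            snps.append(SnpRecord(next_rsid(), l, "lncRNA",
                                  "lnc_binding_site", mi))
    for mi, m in sorted(target_pairs):
        if rng.random() < cfg.snp_rate_per_edge:
            if rng.random() < 0.5:
                snps.append(SnpRecord(next_rsid(), mi, "miRNA", "mirna_seed"))
            else:
                snps.append(SnpRecord(next_rsid(), m, "mRNA", "utr3", mi))
    host_rate = cfg.snp_rate_per_edge / 2
    for l in lncrnas:
        if rng.random() < host_rate:
            snps.append(SnpRecord(next_rsid(), l, "lncRNA", "lnc_gene_body"))
    for mi in mirnas:
        if rng.random() < host_rate:
            snps.append(SnpRecord(next_rsid(), mi, "miRNA", "pri_pre_mirna"))

    truth = {
        "planted_pathway": planted.pathway_id,
        "feature": cfg.feature,
        "planted_mirnas": list(planted_mirnas),
        "risk_mrnas": sorted(risk_mrnas),
        "risk_mirnas": sorted(risk_mirnas),
        "risk_lncrnas": sorted(risk_lncs),
        "n_gene_edges": len(gene_edge_list),
        "n_mirna_edges": len(mirna_edge_list),
        "n_target_edges": len(target_edges),
        "n_lnc_mi_edges": len(lnc_mi_edges),
        "n_snps": len(snps),
        "n_pathways": len(pathways),
    }
    return Bundle(config=cfg, gene_edges=gene_edge_list,
                  mirna_edges=mirna_edge_list, target_edges=target_edges,
                  lnc_mi_edges=lnc_mi_edges, pathways=pathways,
                  catalog=catalog, snps=snps, truth=truth)


def expected_stats(bundle: Bundle, pathway_id: str,
                   feature: str | None = None) -> dict:
    """Brute-force expected CSSPN statistics from the emitted tables.

    Enumerates ceRNA triples by a plain cross-join over the bundle's
    interaction tables and risk catalog (independent of the cerna module's
    indexing), attaches SNPs by direct matching, and recounts the density
    and ratio from their definitions.  Used as an exact oracle downstream.
    """
    feature = feature or bundle.config.feature
    pathway = next(p for p in bundle.pathways if p.pathway_id == pathway_id)
    admitted = {e.molecule_id for e in bundle.catalog if e.feature == feature}
    triples = []
    for lr in bundle.lnc_mi_edges:
        for mr in bundle.target_edges:
            if lr.target != mr.regulator:
                continue
            l, mi, m = lr.regulator, lr.target, mr.target
            if m in pathway.members and {l, mi, m} <= admitted:
                triples.append((l, mi, m))
    triples = sorted(set(triples))
    with_snp = 0
    reg_snps = set()
    for (l, mi, m) in triples:
        edge_snps = set()
        for s in bundle.snps:
            if (s.location_class == "lnc_binding_site"
                    and s.host_molecule == l and s.partner_molecule == mi):
                edge_snps.add(s.rsid)
            elif s.location_class == "mirna_seed" and s.host_molecule == mi:
                edge_snps.add(s.rsid)
            elif (s.location_class == "utr3" and s.host_molecule == m
                  and s.partner_molecule in (None, mi)):
                edge_snps.add(s.rsid)
        if edge_snps:
            with_snp += 1
            reg_snps |= edge_snps
    n = len(triples)
    return {
        "pathway_id": pathway_id,
        "feature": feature,
        "n_regulations": n,
        "n_regulations_with_snp": with_snp,
        "n_regulatory_snps": len(reg_snps),
        "snp_density": (len(reg_snps) / with_snp) if with_snp else None,
        "snp_ratio": (with_snp / n) if n else 0.0,
    }
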