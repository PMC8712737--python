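"""ceRNA-mediated SNP switching pathway network (CSSPN) construction.

For each significant pathway, every lncRNA -> miRNA -> mRNA triple whose
three molecules are all in the admitted risk catalog, whose two edges are
both present in the evidence tables, and whose mRNA belongs to the pathway
is a ceRNA regulation.  Regulatory SNPs — in the mRNA 3'UTR, the
mature-miRNA seed region, or the miRNA binding site on the lncRNA — are
attached to the edge they perturb; SNPs in the lncRNA gene body or the
pri-/pre-miRNA are kept as host annotations.  A "switch candidate" is a
regulation carrying regulatory SNPs on BOTH its lncRNA-miRNA and
miRNA-mRNA edges, optionally restricted to user-supplied upstream genes
(receptor-like genes that gate the whole pathway).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx

from pathmux.io_formats import (
    InteractionRecord,
    PathwayRecord,
    RiskCatalogEntry,
    SnpRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CeRNARegulation:
    """One lncRNA -> miRNA -> mRNA triple within a pathway, with its SNPs.

    lnc_mi_snps sit on the lncRNA-miRNA edge (miRNA binding site on the
    lncRNA); mi_m_snps sit on the miRNA-mRNA edge (miRNA seed region or mRNA
    3'UTR); host_snps are gene-body / pri-pre-miRNA SNPs that do not map to
    a specific edge.
    """

    lncrna: str
    mirna: str
    mrna: str
    pathway_id: str
    feature: str
    lnc_mi_snps: frozenset = field(default_factory=frozenset)
    mi_m_snps: frozenset = field(default_factory=frozenset)
    host_snps: frozenset = field(default_factory=frozenset)

    @property
    def has_snp(self) -> bool:
        """True when any regulatory SNP is attached to either edge."""
        return bool(self.lnc_mi_snps or self.mi_m_snps)

    @property
    def regulatory_snps(self) -> frozenset:
        return self.lnc_mi_snps | self.mi_m_snps


@dataclass(frozen=True)
class CssnStats:
    """Per-pathway CSSPN summary.

    snp_density = distinct regulatory SNPs / regulations containing them
    (undefined, None, when no regulation carries one); snp_ratio =
    regulations containing regulatory SNPs / all regulations.
    """

    pathway_id: str
    feature: str
    n_regulations: int
    n_regulations_with_snp: int
    n_regulatory_snps: int
    snp_density: float | None
    snp_ratio: float


def build_cerna_network(pathway: PathwayRecord, feature: str,
                        catalog: list[RiskCatalogEntry],
                        lnc_mi: list[InteractionRecord],
                        mi_m: list[InteractionRecord],
                        *, feature_strict: bool = True) -> list[CeRNARegulation]:
    """Enumerate the pathway's risk ceRNA triples.

    Returns every (l, mi, m) with l->mi and mi->m in the evidence tables,
    m a pathway member, and all three molecules in the admitted catalog.
    With ``feature_strict`` (default) the catalog is filtered to entries of
    this feature; the permissive mode admits risk molecules of any feature,
    matching analyses where overlapping pathways mix features.  Ordering is
    deterministic (lexicographic on the triple).
    """
    admitted = {e.molecule_id for e in catalog
                if (not feature_strict) or e.feature == feature}
    mi_by_lnc: dict[str, set] = {}
    for rec in lnc_mi:
        if rec.regulator in admitted and rec.target in admitted:
            mi_by_lnc.setdefault(rec.regulator, set()).add(rec.target)
    m_by_mi: dict[str, set] = {}
    for rec in mi_m:
        if rec.regulator in admitted and rec.target in admitted:
            m_by_mi.setdefault(rec.regulator, set()).add(rec.target)
    regs = []
    for l in sorted(mi_by_lnc):
        for mi in sorted(mi_by_lnc[l]):
            for m in sorted(m_by_mi.get(mi, set()) & pathway.members):
                regs.append(CeRNARegulation(
                    lncrna=l, mirna=mi, mrna=m,
                    pathway_id=pathway.pathway_id, feature=feature))
    logger.info("pathway %s (%s): %d ceRNA regulation(s)",
                pathway.pathway_id, feature, len(regs))
    return regs


def annotate_snps(regs: list[CeRNARegulation],
                  snps: list[SnpRecord]) -> list[CeRNARegulation]:
    """Attach each SNP to every regulation whose molecules (and, when named,
    partner miRNA) match.

    * lnc_binding_site on lncRNA l with partner mi -> lnc_mi_snps of
      regulations with that (l, mi) pair;
    * mirna_seed on miRNA mi -> mi_m_snps of every regulation through mi;
    * utr3 on mRNA m -> mi_m_snps of regulations with that mRNA, restricted
      to the named partner miRNA when one is given (no partner attaches to
      all of the mRNA's regulations, a conservative superset);
    * lnc_gene_body / pri_pre_mirna -> host_snps.

    Annotation is idempotent: SNP sets are replaced, not accumulated.
    """
    out = []
    for reg in regs:
        lnc_mi, mi_m, host = set(), set(), set()
        for s in snps:
            if s.location_class == "lnc_binding_site":
                if s.host_molecule == reg.lncrna and s.partner_molecule == reg.mirna:
                    lnc_mi.add(s)
            elif s.location_class == "mirna_seed":
                if s.host_molecule == reg.mirna:
                    mi_m.add(s)
            elif s.location_class == "utr3":
                if s.host_molecule == reg.mrna and (
                        s.partner_molecule is None
                        or s.partner_molecule == reg.mirna):
                    mi_m.add(s)
            elif s.location_class in ("lnc_gene_body", "pri_pre_mirna"):
                if s.host_molecule in (reg.lncrna, reg.mirna):
                    host.add(s)
        out.append(replace(reg, lnc_mi_snps=frozenset(lnc_mi),
                           mi_m_snps=frozenset(mi_m),
                           host_snps=frozenset(host)))
    return out


def compute_stats(regs: list[CeRNARegulation], *,
                  counting: str = "distinct") -> CssnStats:
    """Summarize one pathway's annotated regulations.

    With the default 'distinct' counting an rsID shared by several
    regulations counts once in the SNP-density numerator; 'attachment'
    counts each (SNP, regulation) attachment.  Density is undefined (None,
    with a logged warning) when no regulation carries a regulatory SNP.
    """
    if not regs:
        raise ValueError("cannot compute stats for zero regulations")
    pids = {r.pathway_id for r in regs}
    feats = {r.feature for r in regs}
    if len(pids) != 1 or len(feats) != 1:
        raise ValueError("stats are computed per (pathway, feature) network")
    n = len(regs)
    with_snp = [r for r in regs if r.has_snp]
    if counting == "distinct":
        n_snps = len({s.rsid for r in regs for s in r.regulatory_snps})
    elif counting == "attachment":
        n_snps = sum(len(r.regulatory_snps) for r in regs)
    else:
        raise ValueError(f"unknown counting mode {counting!r}")
    if with_snp:
        density = n_snps / len(with_snp)
    else:
        density = None
        logger.warning("pathway %s: no regulation carries a regulatory SNP; "
                       "density undefined", pids.pop())
    return CssnStats(
        pathway_id=regs[0].pathway_id, feature=regs[0].feature,
        n_regulations=n, n_regulations_with_snp=len(with_snp),
        n_regulatory_snps=n_snps, snp_density=density,
        snp_ratio=len(with_snp) / n,
    )


def find_switch_candidates(regs: list[CeRNARegulation],
                           upstream_genes=None) -> list[CeRNARegulation]:
    """Regulations with regulatory SNPs on BOTH edges.

    An optional upstream-gene list further restricts candidates to
    regulations targeting those mRNAs (the receptor/"switch" positioning of
    a gene within its pathway diagram is supplied by the user, not
    inferred).
    """
    kept = [r for r in regs if r.lnc_mi_snps and r.mi_m_snps]
    if upstream_genes is not None:
        upstream = set(upstream_genes)
        kept = [r for r in kept if r.mrna in upstream]
    return kept


def export_csspn(regs: list[CeRNARegulation], node_path, edge_path,
                 graphml_path=None) -> None:
    """Write node and edge TSV tables (and optionally GraphML).

    The node table carries molecule type and a SNP-presence flag; the edge
    table carries the edge class (lnc_mi or mi_m) and the attached rsIDs.
    The triple structure is recoverable from the edge table.
    """
    nodes: dict[tuple, dict] = {}
    edges: dict[tuple, dict] = {}
    for r in regs:
        for mol, kind, snps in (
            (r.lncrna, "lncRNA", {s for s in r.host_snps
                                  if s.host_molecule == r.lncrna} | r.lnc_mi_snps),
            (r.mirna, "miRNA", {s for s in r.host_snps
                                if s.host_molecule == r.mirna}
             | {s for s in r.mi_m_snps if s.host_molecule == r.mirna}
             | {s for s in r.lnc_mi_snps if s.partner_molecule == r.mirna}),
            (r.mrna, "mRNA", {s for s in r.mi_m_snps
                              if s.host_molecule == r.mrna}),
        ):
            node = nodes.setdefault((mol, kind), {"rsids": set()})
            node["rsids"] |= {s.rsid for s in snps}
        for (a, b, cls, snps) in (
            (r.lncrna, r.mirna, "lnc_mi", r.lnc_mi_snps),
            (r.mirna, r.mrna, "mi_m", r.mi_m_snps),
        ):
            edge = edges.setdefault((a, b, cls), {"rsids": set(),
                                                  "pathways": set(),
                                                  "features": set()})
            edge["rsids"] |= {s.rsid for s in snps}
            edge["pathways"].add(r.pathway_id)
            edge["features"].add(r.feature)

    with open(node_path, "w") as fh:
        fh.write("node\ttype\thas_snp\trsids\n")
        for (mol, kind), attrs in sorted(nodes.items()):
            rs = sorted(attrs["rsids"])
            fh.write(f"{mol}\t{kind}\t{int(bool(rs))}\t{','.join(rs)}\n")
    with open(edge_path, "w") as fh:
        fh.write("source\ttarget\tedge_class\trsids\tpathways\tfeatures\n")
        for (a, b, cls), attrs in sorted(edges.items()):
            fh.write("\t".join([
                a, b, cls, ",".join(sorted(attrs["rsids"])),
                ",".join(sorted(attrs["pathways"])),
                ",".join(sorted(attrs["features"])),
            ]) + "\n")

    if graphml_path is not None:
        G = nx.DiGraph()
        for (mol, kind), attrs in sorted(nodes.items()):
            G.add_node(mol, type=kind, has_snp=int(bool(attrs["rsids"])),
                       rsids=",".join(sorted(attrs["rsids"])))
        for (a, b, cls), attrs in sorted(edges.items()):
            G.add_edge(a, b, edge_class=cls,
                       rsids=",".join(sorted(attrs["rsids"])),
                       pathways=",".join(sorted(attrs["pathways"])),
                       features=",".join(sorted(attrs["features"])))
        nx.write_graphml(G, graphml_path)


def load_csspn_edges(edge_path) -> list[tuple]:
    """Read back an edge table as (source, target, edge_class, rsids) rows."""
    rows = []
    with open(edge_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header[:3] == ["source", "target", "edge_class"]
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rsids = frozenset(x for x in f[3].split(",") if x)
            rows.append((f[0], f[1], f[2], rsids))
    return rows
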