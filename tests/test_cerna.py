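import itertools

import pytest

from pathmux.cerna import (
    annotate_snps,
    build_cerna_network,
    compute_stats,
    export_csspn,
    find_switch_candidates,
    load_csspn_edges,
)
from pathmux.io_formats import (
    InteractionRecord,
    PathwayRecord,
    RiskCatalogEntry,
    SnpRecord,
)


def lnc_mi(l, mi):
    return InteractionRecord(l, mi, "lncRNA", "miRNA")


def mi_m(mi, m):
    return InteractionRecord(mi, m, "miRNA", "mRNA")


def catalog(*entries):
    out = []
    for mol, mtype in entries:
        out.append(RiskCatalogEntry(mol, mtype, "inflammation"))
    return out


BASIC_CATALOG = catalog(("L1", "lncRNA"), ("M1", "miRNA"), ("G1", "mRNA"))


class TestBuildCernaNetwork:
    def test_single_triple(self):
        regs = build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"G1"})),
            "inflammation", BASIC_CATALOG, [lnc_mi("L1", "M1")],
            [mi_m("M1", "G1")])
        assert len(regs) == 1
        assert (regs[0].lncrna, regs[0].mirna, regs[0].mrna) == ("L1", "M1", "G1")

    def test_gene_outside_pathway_excluded(self):
        regs = build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"OTHER"})),
            "inflammation", BASIC_CATALOG, [lnc_mi("L1", "M1")],
            [mi_m("M1", "G1")])
        assert regs == []

    def test_two_lncrnas_one_mirna_two_genes_gives_four(self):
        cat = catalog(("L1", "lncRNA"), ("L2", "lncRNA"), ("M1", "miRNA"),
                      ("G1", "mRNA"), ("G2", "mRNA"))
        regs = build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"G1", "G2"})),
            "inflammation", cat,
            [lnc_mi("L1", "M1"), lnc_mi("L2", "M1")],
            [mi_m("M1", "G1"), mi_m("M1", "G2")])
        assert len(regs) == 4
        assert {(r.lncrna, r.mirna, r.mrna) for r in regs} == set(
            (l, "M1", g) for l, g in itertools.product(["L1", "L2"],
                                                       ["G1", "G2"]))

    def test_feature_strict_vs_permissive(self):
        cat = BASIC_CATALOG + [RiskCatalogEntry("L2", "lncRNA", "remodeling")]
        edges_l = [lnc_mi("L1", "M1"), lnc_mi("L2", "M1")]
        edges_m = [mi_m("M1", "G1")]
        pw = PathwayRecord("P1", "P1", "DB", frozenset({"G1"}))
        strict = build_cerna_network(pw, "inflammation", cat, edges_l, edges_m)
        loose = build_cerna_network(pw, "inflammation", cat, edges_l, edges_m,
                                    feature_strict=False)
        assert {r.lncrna for r in strict} == {"L1"}
        assert {r.lncrna for r in loose} == {"L1", "L2"}

    def test_matches_bruteforce_crossjoin(self, rng):
        lncs = [f"L{i}" for i in range(4)]
        mis = [f"M{i}" for i in range(5)]
        genes = [f"G{i}" for i in range(8)]
        cat = catalog(*[(l, "lncRNA") for l in lncs],
                      *[(m, "miRNA") for m in mis],
                      *[(g, "mRNA") for g in genes[:6]])
        el = [lnc_mi(l, m) for l in lncs for m in mis if rng.random() < 0.4]
        em = [mi_m(m, g) for m in mis for g in genes if rng.random() < 0.4]
        members = frozenset(g for g in genes if rng.random() < 0.6)
        pw = PathwayRecord("P1", "P1", "DB", members or frozenset({"G0"}))
        regs = build_cerna_network(pw, "inflammation", cat, el, em)
        admitted = {e.molecule_id for e in cat}
        expected = {
            (l.regulator, l.target, m.target)
            for l in el for m in em
            if l.target == m.regulator and m.target in pw.members
            and {l.regulator, l.target, m.target} <= admitted
        }
        assert {(r.lncrna, r.mirna, r.mrna) for r in regs} == expected


def _one_reg(**snps):
    regs = build_cerna_network(
        PathwayRecord("P1", "P1", "DB", frozenset({"G1"})),
        "inflammation", BASIC_CATALOG, [lnc_mi("L1", "M1")],
        [mi_m("M1", "G1")])
    return annotate_snps(regs, list(snps.values()))[0]


class TestAnnotateSnps:
    def test_binding_site_snp_on_matching_pair(self):
        reg = _one_reg(s=SnpRecord("rs1", "L1", "lncRNA", "lnc_binding_site",
                                   "M1"))
        assert {s.rsid for s in reg.lnc_mi_snps} == {"rs1"}

    def test_utr3_partner_mismatch_not_attached(self):
        reg = _one_reg(s=SnpRecord("rs2", "G1", "mRNA", "utr3", "M2"))
        assert reg.mi_m_snps == frozenset()

    def test_utr3_without_partner_attaches_to_all(self):
        reg = _one_reg(s=SnpRecord("rs2", "G1", "mRNA", "utr3"))
        assert {s.rsid for s in reg.mi_m_snps} == {"rs2"}

    def test_seed_snp_shared_by_regulations_through_same_mirna(self):
        cat = BASIC_CATALOG + [RiskCatalogEntry("G2", "mRNA", "inflammation")]
        regs = build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"G1", "G2"})),
            "inflammation", cat, [lnc_mi("L1", "M1")],
            [mi_m("M1", "G1"), mi_m("M1", "G2")])
        seed_snp = SnpRecord("rs3", "M1", "miRNA", "mirna_seed")
        regs = annotate_snps(regs, [seed_snp])
        assert all({s.rsid for s in r.mi_m_snps} == {"rs3"} for r in regs)

    def test_host_snps_kept_separately(self):
        reg = _one_reg(a=SnpRecord("rs4", "L1", "lncRNA", "lnc_gene_body"),
                       b=SnpRecord("rs5", "M1", "miRNA", "pri_pre_mirna"))
        assert {s.rsid for s in reg.host_snps} == {"rs4", "rs5"}
        assert not reg.has_snp   # host SNPs are not regulatory

    def test_annotation_is_idempotent(self):
        snps = [SnpRecord("rs1", "L1", "lncRNA", "lnc_binding_site", "M1"),
                SnpRecord("rs2", "G1", "mRNA", "utr3", "M1")]
        regs = build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"G1"})),
            "inflammation", BASIC_CATALOG, [lnc_mi("L1", "M1")],
            [mi_m("M1", "G1")])
        once = annotate_snps(regs, snps)
        twice = annotate_snps(once, snps)
        assert once == twice


def _micro_network():
    """4 regulations, 2 carrying regulatory SNPs, 5 distinct SNPs."""
    cat = catalog(("L1", "lncRNA"), ("L2", "lncRNA"), ("M1", "miRNA"),
                  ("M2", "miRNA"), ("G1", "mRNA"), ("G2", "mRNA"))
    regs = build_cerna_network(
        PathwayRecord("P1", "P1", "DB", frozenset({"G1", "G2"})),
        "inflammation", cat,
        [lnc_mi("L1", "M1"), lnc_mi("L2", "M2")],
        [mi_m("M1", "G1"), mi_m("M1", "G2"), mi_m("M2", "G1"),
         mi_m("M2", "G2")])
    assert len(regs) == 4
    snps = [
        SnpRecord("rs1", "L1", "lncRNA", "lnc_binding_site", "M1"),
        SnpRecord("rs2", "M1", "miRNA", "mirna_seed"),
        SnpRecord("rs3", "G1", "mRNA", "utr3", "M1"),
        SnpRecord("rs4", "G2", "mRNA", "utr3", "M1"),
        SnpRecord("rs5", "L1", "lncRNA", "lnc_binding_site", "M1"),
    ]
    return annotate_snps(regs, snps)


class TestComputeStats:
    def test_density_and_ratio_on_micro_network(self):
        regs = _micro_network()
        st = compute_stats(regs)
        assert st.n_regulations == 4
        assert st.n_regulations_with_snp == 2     # the two through M1
        assert st.n_regulatory_snps == 5
        assert st.snp_density == pytest.approx(2.5)
        assert st.snp_ratio == pytest.approx(0.5)
        # identity: density * with_snp == distinct regulatory SNPs
        assert st.snp_density * st.n_regulations_with_snp == pytest.approx(
            st.n_regulatory_snps)

    def test_no_snps_gives_na_density_and_zero_ratio(self, caplog):
        regs = build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"G1"})),
            "inflammation",
            BASIC_CATALOG + [RiskCatalogEntry("L2", "lncRNA", "inflammation"),
                             RiskCatalogEntry("L3", "lncRNA", "inflammation")],
            [lnc_mi("L1", "M1"), lnc_mi("L2", "M1"), lnc_mi("L3", "M1")],
            [mi_m("M1", "G1")])
        assert len(regs) == 3
        with caplog.at_level("WARNING"):
            st = compute_stats(annotate_snps(regs, []))
        assert st.snp_density is None
        assert st.snp_ratio == 0.0

    def test_shared_snp_counted_once_in_distinct_mode(self):
        cat = catalog(("L1", "lncRNA"), ("M1", "miRNA"), ("G1", "mRNA"),
                      ("G2", "mRNA"))
        regs = build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"G1", "G2"})),
            "inflammation", cat, [lnc_mi("L1", "M1")],
            [mi_m("M1", "G1"), mi_m("M1", "G2")])
        shared = SnpRecord("rs9", "M1", "miRNA", "mirna_seed")
        regs = annotate_snps(regs, [shared])
        st = compute_stats(regs)
        assert st.n_regulations_with_snp == 2
        assert st.n_regulatory_snps == 1
        assert st.snp_density == pytest.approx(0.5)
        st_att = compute_stats(regs, counting="attachment")
        assert st_att.n_regulatory_snps == 2

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_stats([])


class TestSwitchCandidates:
    def test_both_edges_required(self):
        regs = _micro_network()
        kept = find_switch_candidates(regs)
        # only regulations through (L1, M1) carry binding-site SNPs,
        # and both also carry mi_m SNPs
        assert {(r.lncrna, r.mirna) for r in kept} == {("L1", "M1")}
        assert len(kept) == 2

    def test_upstream_gene_restriction(self):
        regs = _micro_network()
        kept = find_switch_candidates(regs, upstream_genes=["G1"])
        assert {r.mrna for r in kept} == {"G1"}

    def test_sponge_triple_with_snps_on_both_edges_is_kept(self):
        """The canonical published switch pattern: a lncRNA sponge with a
        binding-site SNP and its miRNA's target with a 3'UTR SNP."""
        cat = catalog(("MALAT1", "lncRNA"), ("hsa-miR-155", "miRNA"),
                      ("IL13", "mRNA"))
        regs = build_cerna_network(
            PathwayRecord("IL4_IL13", "IL4_IL13", "DB", frozenset({"IL13"})),
            "inflammation", cat, [lnc_mi("MALAT1", "hsa-miR-155")],
            [mi_m("hsa-miR-155", "IL13")])
        snps = [
            SnpRecord("rs765499057", "MALAT1", "lncRNA", "lnc_binding_site",
                      "hsa-miR-155"),
            SnpRecord("rs201185816", "IL13", "mRNA", "utr3", "hsa-miR-155"),
        ]
        regs = annotate_snps(regs, snps)
        kept = find_switch_candidates(regs)
        assert len(kept) == 1
        assert (kept[0].lncrna, kept[0].mirna, kept[0].mrna) == (
            "MALAT1", "hsa-miR-155", "IL13")

    def test_empty_input(self):
        assert find_switch_candidates([]) == []


class TestExport:
    def test_one_regulation_gives_three_nodes_two_edges(self, tmp_path):
        regs = annotate_snps(build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"G1"})),
            "inflammation", BASIC_CATALOG, [lnc_mi("L1", "M1")],
            [mi_m("M1", "G1")]), [])
        export_csspn(regs, tmp_path / "n.tsv", tmp_path / "e.tsv",
                     tmp_path / "g.graphml")
        assert len((tmp_path / "n.tsv").read_text().splitlines()) == 4
        assert len((tmp_path / "e.tsv").read_text().splitlines()) == 3
        import networkx as nx
        G = nx.read_graphml(tmp_path / "g.graphml")
        assert G.number_of_nodes() == 3 and G.number_of_edges() == 2

    def test_edge_table_round_trips_the_regulation_set(self, tmp_path):
        regs = _micro_network()
        export_csspn(regs, tmp_path / "n.tsv", tmp_path / "e.tsv")
        rows = load_csspn_edges(tmp_path / "e.tsv")
        lnc_edges = {(a, b) for a, b, cls, _ in rows if cls == "lnc_mi"}
        mim_edges = {(a, b) for a, b, cls, _ in rows if cls == "mi_m"}
        triples = {
            (l, mi, m)
            for (l, mi) in lnc_edges for (mi2, m) in mim_edges if mi == mi2
        }
        # edge tables are a graph projection; every regulation is recoverable
        assert {(r.lncrna, r.mirna, r.mrna) for r in regs} <= triples

    def test_switch_fixture_graphml_counts(self, tmp_path):
        """11 switch regulations export as 11 marked lnc_mi/mi_m edge pairs."""
        import networkx as nx
        lncs = [f"L{i}" for i in range(11)]
        cat = catalog(*[(l, "lncRNA") for l in lncs], ("M1", "miRNA"),
                      ("G1", "mRNA"))
        regs = build_cerna_network(
            PathwayRecord("P1", "P1", "DB", frozenset({"G1"})),
            "inflammation", cat, [lnc_mi(l, "M1") for l in lncs],
            [mi_m("M1", "G1")])
        snps = [SnpRecord(f"rs{i}", l, "lncRNA", "lnc_binding_site", "M1")
                for i, l in enumerate(lncs)]
        snps.append(SnpRecord("rs99", "G1", "mRNA", "utr3", "M1"))
        regs = annotate_snps(regs, snps)
        switches = find_switch_candidates(regs)
        assert len(switches) == 11
        export_csspn(switches, tmp_path / "n.tsv", tmp_path / "e.tsv",
                     tmp_path / "g.graphml")
        G = nx.read_graphml(tmp_path / "g.graphml")
        marked = [e for e in G.edges(data=True)
                  if e[2]["edge_class"] == "lnc_mi" and e[2]["rsids"]]
        assert len(marked) == 11
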