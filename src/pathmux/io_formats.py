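"""Typed records and TSV/GMT readers and writers.

Every external table the tool touches passes through this module; downstream
modules consume only the record types defined here.  Identifiers are opaque
strings (gene symbols, miRBase names, rsIDs); no identifier mapping is done.

Conventions
-----------
* Undirected edges are canonicalized (endpoints sorted lexicographically) and
  stored once; duplicates are merged keeping the maximum weight, following
  interaction-confidence semantics.
* Self-edges are dropped with a logged warning.
* Each reader logs ``rows_in = records_out + rejected_rows`` accounting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

MOLECULE_TYPES = ("mRNA", "miRNA", "lncRNA")

#: allowed SNP location classes, keyed by required host molecule type
LOCATION_CLASSES = {
    "utr3": "mRNA",
    "mirna_seed": "miRNA",
    "pri_pre_mirna": "miRNA",
    "lnc_binding_site": "lncRNA",
    "lnc_gene_body": "lncRNA",
}

#: location classes that directly perturb ceRNA binding ("regulatory SNPs"):
#: the mRNA 3'UTR, the mature-miRNA seed region, and the miRNA binding site
#: on the lncRNA.
REGULATORY_CLASSES = frozenset({"utr3", "mirna_seed", "lnc_binding_site"})


class ParseError(ValueError):
    """A malformed input file; message names the offending line."""


@dataclass(frozen=True, order=True)
class WeightedEdge:
    """An undirected weighted interaction edge in canonical endpoint order."""

    source: str
    target: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"negative weight {self.weight} on edge "
                             f"({self.source}, {self.target})")
        if self.source == self.target:
            raise ValueError(f"self-edge on {self.source}")

    @staticmethod
    def canonical(source: str, target: str, weight: float) -> "WeightedEdge":
        a, b = sorted((source, target))
        return WeightedEdge(a, b, weight)


@dataclass(frozen=True)
class InteractionRecord:
    """A directed regulator->target interaction (miRNA->mRNA or lncRNA->miRNA)."""

    regulator: str
    target: str
    regulator_type: str
    target_type: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if (self.regulator_type, self.target_type) not in (
            ("miRNA", "mRNA"),
            ("lncRNA", "miRNA"),
        ):
            raise ValueError(
                f"unsupported interaction type pair "
                f"({self.regulator_type}, {self.target_type})"
            )


@dataclass(frozen=True)
class PathwayRecord:
    """A named gene set with its source-database tag."""

    pathway_id: str
    name: str
    source_db: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id} has no members")


@dataclass(frozen=True)
class RiskCatalogEntry:
    """One risk molecule attributed to one disease feature."""

    molecule_id: str
    molecule_type: str
    feature: str

    def __post_init__(self) -> None:
        if self.molecule_type not in MOLECULE_TYPES:
            raise ValueError(f"unknown molecule type {self.molecule_type!r}")


@dataclass(frozen=True)
class SnpRecord:
    """A classified SNP on a host molecule.

    ``partner_molecule`` names the miRNA whose binding the SNP affects; it is
    required for ``lnc_binding_site`` (the site is defined by the miRNA) and
    optional for ``utr3``.
    """

    rsid: str
    host_molecule: str
    host_type: str
    location_class: str
    partner_molecule: str | None = None

    def __post_init__(self) -> None:
        required = LOCATION_CLASSES.get(self.location_class)
        if required is None:
            raise ValueError(f"unknown location class {self.location_class!r}")
        if self.host_type != required:
            raise ValueError(
                f"class/type mismatch: {self.location_class} requires host "
                f"{required}, got {self.host_type}"
            )
        if self.location_class == "lnc_binding_site" and not self.partner_molecule:
            raise ValueError("lnc_binding_site requires a partner miRNA")

    @property
    def is_regulatory(self) -> bool:
        return self.location_class in REGULATORY_CLASSES


@dataclass(frozen=True)
class PathwayScore:
    """Per (feature, pathway) scoring result.

    ``correlation_score`` is the mean cosine between the risk molecules'
    source vectors and the pathway's target vector; ``ranking_score`` is the
    within-database size-normalized rank transform; ``empirical_p`` is the
    add-one permutation p-value.
    """

    feature: str
    pathway_id: str
    source_db: str
    correlation_score: float
    rank_in_db: int | None = None
    ranking_score: float | None = None
    empirical_p: float | None = None
    overlap_count: int | None = None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _open_lines(path) -> list[str]:
    text = Path(path).read_text()
    return text.splitlines()


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_edge_list(path, directed: bool = False) -> list[WeightedEdge]:
    """Read a tab-separated (source, target, weight) edge list.

    A header line is auto-detected by a non-numeric third field.  Duplicate
    undirected edges are merged keeping the maximum weight; self-edges are
    dropped with a logged warning.
    """
    lines = [ln for ln in _open_lines(path) if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty edge-list file")
    start = 0
    first = lines[0].split("\t")
    if len(first) >= 3 and not _is_number(first[2]):
        start = 1
    merged: dict[tuple, float] = {}
    n_self = 0
    n_rows = 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated "
                             f"fields, got {len(fields)}")
        src, tgt = fields[0].strip(), fields[1].strip()
        try:
            w = float(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed weight "
                             f"{fields[2]!r}") from None
        if not math.isfinite(w) or w < 0:
            raise ParseError(f"{path}:{lineno}: weight must be a finite "
                             f"non-negative number, got {fields[2]!r}")
        n_rows += 1
        if src == tgt:
            n_self += 1
            continue
        key = (src, tgt) if directed else tuple(sorted((src, tgt)))
        if key not in merged or w > merged[key]:
            merged[key] = w
    if n_self:
        logger.warning("%s: dropped %d self-edge(s)", path, n_self)
    edges = [WeightedEdge(a, b, w) for (a, b), w in sorted(merged.items())]
    logger.info("%s: %d rows -> %d edges (%d self-edges dropped, %d merged)",
                path, n_rows, len(edges), n_self,
                n_rows - n_self - len(edges))
    if not edges:
        return []
    return edges


def read_gmt(path, source_db_map: dict[str, str] | None = None) -> list[PathwayRecord]:
    """Read a GMT gene-set file: name TAB description TAB member TAB member...

    The source database is taken from the description field unless a side
    mapping pathway_id -> source_db is supplied.
    """
    records: list[PathwayRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields "
                             f"(id, description, members...)")
        pid, desc = fields[0].strip(), fields[1].strip()
        members = frozenset(f.strip() for f in fields[2:] if f.strip())
        if not members:
            raise ParseError(f"{path}:{lineno}: pathway {pid} has an empty "
                             f"member list")
        if pid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate pathway_id {pid}")
        seen.add(pid)
        source_db = (source_db_map or {}).get(pid, desc)
        records.append(PathwayRecord(pid, pid, source_db, members))
    logger.info("%s: read %d pathway records", path, len(records))
    return records


def read_snp_table(path) -> tuple[list[SnpRecord], list[str]]:
    """Read the headered SNP TSV; returns (valid records, rejection diagnostics).

    Rows violating the host-type/location-class invariants are rejected with a
    per-row diagnostic rather than aborting the read.
    """
    lines = _open_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty SNP table")
    header = [h.strip() for h in lines[0].split("\t")]
    expected = ["rsid", "host_molecule", "host_type", "location_class",
                "partner_molecule"]
    if header[: len(expected)] != expected:
        raise ParseError(f"{path}: expected header {expected}, got {header}")
    records: list[SnpRecord] = []
    diagnostics: list[str] = []
    n_rows = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        n_rows += 1
        fields = (line.split("\t") + [""] * 5)[:5]
        rsid, host, htype, lclass, partner = (f.strip() for f in fields)
        try:
            records.append(SnpRecord(rsid, host, htype, lclass, partner or None))
        except ValueError as exc:
            diagnostics.append(f"{path}:{lineno}: {exc}")
    logger.info("%s: %d rows -> %d records, %d rejected",
                path, n_rows, len(records), len(diagnostics))
    for d in diagnostics:
        logger.warning("rejected SNP row: %s", d)
    return records, diagnostics


def read_interactions(path, regulator_type: str, target_type: str) -> list[InteractionRecord]:
    """Read a headered regulator/target interaction TSV of one type pair."""
    lines = _open_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty interaction table")
    start = 1 if lines[0].lower().startswith("regulator") else 0
    seen: set[tuple] = set()
    records: list[InteractionRecord] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 fields")
        reg, tgt = fields[0].strip(), fields[1].strip()
        evidence = fields[2].strip() if len(fields) > 2 else ""
        if (reg, tgt) in seen:
            continue
        seen.add((reg, tgt))
        records.append(InteractionRecord(reg, tgt, regulator_type,
                                         target_type, evidence))
    logger.info("%s: read %d %s->%s interactions",
                path, len(records), regulator_type, target_type)
    return records


def read_risk_catalog(path) -> list[RiskCatalogEntry]:
    """Read the headered risk-molecule catalog TSV.

    Duplicate (molecule_id, feature) pairs are an error: the catalog is a set
    of attributions, not an occurrence list.
    """
    lines = _open_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty risk catalog")
    start = 1 if lines[0].lower().startswith("molecule_id") else 0
    seen: set[tuple] = set()
    entries: list[RiskCatalogEntry] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields "
                             f"(molecule_id, molecule_type, feature)")
        mol, mtype, feat = (f.strip() for f in fields[:3])
        if (mol, feat) in seen:
            raise ParseError(f"{path}:{lineno}: duplicate catalog entry "
                             f"({mol}, {feat})")
        seen.add((mol, feat))
        entries.append(RiskCatalogEntry(mol, mtype, feat))
    logger.info("%s: read %d risk-catalog entries", path, len(entries))
    return entries


# ---------------------------------------------------------------------------
# score-table writer / reader
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("feature", "pathway_id", "source_db", "correlation_score",
                 "rank_in_db", "ranking_score", "empirical_p", "overlap_count")


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, int):
        return str(x)
    return f"{x:.6g}"


def write_scores(scores: Iterable[PathwayScore], path) -> None:
    """Write pathway scores as TSV, sorted by feature then ranking score desc.

    Floats are rendered with 6 significant digits; missing statistics as NA.
    """
    rows = sorted(
        scores,
        key=lambda s: (s.feature,
                       -(s.ranking_score if s.ranking_score is not None
                         else s.correlation_score),
                       s.pathway_id),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for s in rows:
            fh.write("\t".join([
                s.feature, s.pathway_id, s.source_db,
                _fmt(s.correlation_score), _fmt(s.rank_in_db),
                _fmt(s.ranking_score), _fmt(s.empirical_p),
                _fmt(s.overlap_count),
            ]) + "\n")


def read_scores(path) -> list[PathwayScore]:
    """Read back a score table written by :func:`write_scores`."""
    lines = _open_lines(path)
    if not lines or tuple(lines[0].split("\t")) != SCORE_COLUMNS:
        raise ParseError(f"{path}: not a pathmux score table")

    def opt(tok, conv):
        return None if tok == "NA" else conv(tok)

    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(PathwayScore(
            feature=f[0], pathway_id=f[1], source_db=f[2],
            correlation_score=float(f[3]),
            rank_in_db=opt(f[4], int),
            ranking_score=opt(f[5], float),
            empirical_p=opt(f[6], float),
            overlap_count=opt(f[7], int),
        ))
    return out
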