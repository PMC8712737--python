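"""Pathway scoring, ranking-score bias correction, permutation p-values,
and the traditional overlap-enrichment baseline.

A pathway's correlation score against a disease-feature risk set is the mean
cosine, in the embedding space, between each risk molecule's source vector
and the pathway's target vector.  Because pathway collections differ greatly
in size across source databases, raw score ranks are not comparable between
databases; the ranking score

    ranking_score = -log2( rank_in_db / (N_db + 1) )

is a size-normalized transform of the within-database competition rank
(rank 1 of 63 pathways gives exactly 6, i.e. the top 1/64 of any database).
The significance convention keeps pathways with ranking score >= 6 AND
empirical permutation p <= 0.05.  NOTE: the exact size-correction formula
used by the original method is not public; this monotone, size-normalized
form is this package's documented reconstruction of it (see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from pathmux.embedding import EmbeddingSpace, cosine
from pathmux.io_formats import PathwayRecord, PathwayScore
from pathmux.multiplex import MultiplexHeterogeneousNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullModel:
    """Permutation null: random molecule sets matching type composition.

    Each draw replaces the risk set by a uniform random set of network
    molecules with the same number of mRNAs and miRNAs.  ``n_permutations``
    should be >= 100 for reported p-values.
    """

    n_permutations: int = 199
    seed: int = 0
    matching: str = "type_composition"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.matching != "type_composition":
            raise ValueError(f"unknown null matching {self.matching!r}")


def _effective_risk_set(emb: EmbeddingSpace, risk_set) -> list:
    present = [m for m in risk_set if m in emb]
    dropped = len(list(risk_set)) - len(present)
    if dropped:
        logger.info("dropped %d risk molecule(s) absent from the embedding",
                    dropped)
    if not present:
        raise ValueError("no risk molecule is present in the embedding")
    return present


def correlation_score(emb: EmbeddingSpace, risk_set, pathway: str,
                      aggregate: str = "mean") -> float:
    """Aggregate cosine similarity between a risk set and one pathway node.

    Default aggregation is the arithmetic mean over risk molecules; 'max'
    and 'sum' are available alternatives.
    """
    present = _effective_risk_set(emb, risk_set)
    t = emb.target_vector(pathway)
    sims = [cosine(emb.source_vector(m), t) for m in sorted(present)]
    if aggregate == "mean":
        return float(np.mean(sims))
    if aggregate == "max":
        return float(np.max(sims))
    if aggregate == "sum":
        return float(np.sum(sims))
    raise ValueError(f"unknown aggregation {aggregate!r}")


def rank_and_score(scores: list[PathwayScore]) -> list[PathwayScore]:
    """Fill rank_in_db and ranking_score within each (feature, source_db).

    Ranks are competition ranks on descending correlation score (ties share
    the minimum rank); ranking_score = -log2(rank / (N_db + 1)).
    """
    out: list[PathwayScore] = []
    groups: dict[tuple, list[PathwayScore]] = {}
    for s in scores:
        groups.setdefault((s.feature, s.source_db), []).append(s)
    for group in groups.values():
        n_db = len(group)
        ordered = sorted(group, key=lambda s: -s.correlation_score)
        ranks: dict[int, int] = {}
        for pos, s in enumerate(ordered, start=1):
            # competition ("min") rank: ties share the smallest position
            if pos > 1 and s.correlation_score == ordered[pos - 2].correlation_score:
                ranks[id(s)] = ranks[id(ordered[pos - 2])]
            else:
                ranks[id(s)] = pos
        for s in group:
            rank = ranks[id(s)]
            out.append(PathwayScore(
                feature=s.feature, pathway_id=s.pathway_id,
                source_db=s.source_db,
                correlation_score=s.correlation_score,
                rank_in_db=rank,
                ranking_score=-math.log2(rank / (n_db + 1)),
                empirical_p=s.empirical_p,
                overlap_count=s.overlap_count,
            ))
    return out


def _null_scores(emb: EmbeddingSpace, net: MultiplexHeterogeneousNetwork,
                 n_mrna: int, n_mirna: int, pathway: str, null: NullModel,
                 aggregate: str = "mean") -> np.ndarray:
    """Null correlation-score distribution for one pathway.

    Cosines between every pool molecule and the pathway are precomputed once
    (through the same :func:`cosine` as the observed score), so each
    permutation only aggregates a random subset.  The draw stream is seeded
    per pathway (CRC32 of the pathway id mixed into the null seed) so
    different pathways see different null sets deterministically.
    """
    import zlib

    rng = np.random.default_rng(
        (null.seed + zlib.crc32(pathway.encode())) % (2 ** 31))
    mrna_pool = [m for m in net.mrna_nodes if m in emb]
    mirna_pool = [m for m in net.mirna_nodes if m in emb]
    if n_mrna > len(mrna_pool) or n_mirna > len(mirna_pool):
        raise ValueError("risk set larger than the available molecule pool")
    t = emb.target_vector(pathway)
    cos_mrna = np.array([cosine(emb.source_vector(m), t) for m in mrna_pool])
    cos_mirna = np.array([cosine(emb.source_vector(m), t) for m in mirna_pool])
    agg = {"mean": np.mean, "max": np.max, "sum": np.sum}.get(aggregate)
    if agg is None:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    vals = np.empty(null.n_permutations)
    for b in range(null.n_permutations):
        sims = []
        if n_mrna:
            sims.append(cos_mrna[rng.choice(len(cos_mrna), size=n_mrna,
                                            replace=False)])
        if n_mirna:
            sims.append(cos_mirna[rng.choice(len(cos_mirna), size=n_mirna,
                                             replace=False)])
        vals[b] = agg(np.concatenate(sims))
    return vals


def empirical_pvalue(emb: EmbeddingSpace, net: MultiplexHeterogeneousNetwork,
                     risk_set, pathway: str, null: NullModel,
                     aggregate: str = "mean",
                     null_scores: np.ndarray | None = None) -> float:
    """Add-one permutation p-value for one pathway's correlation score.

    p = (1 + #{null >= observed}) / (1 + N); with the add-one correction the
    p-value is never 0.  ``null_scores`` allows reuse of a precomputed null
    distribution (the null does not depend on the observed set's identity,
    only its type composition).
    """
    present = _effective_risk_set(emb, risk_set)
    observed = correlation_score(emb, present, pathway, aggregate=aggregate)
    if null_scores is None:
        n_mrna = sum(1 for m in present if net.node_kind(m) == "mRNA")
        n_mirna = sum(1 for m in present if net.node_kind(m) == "miRNA")
        null_scores = _null_scores(emb, net, n_mrna, n_mirna, pathway, null,
                                   aggregate=aggregate)
    b = int(np.sum(null_scores >= observed))
    return (1 + b) / (1 + len(null_scores))


def select_significant(scores: list[PathwayScore],
                       ranking_threshold: float = 6.0,
                       p_threshold: float = 0.05) -> list[PathwayScore]:
    """Keep scores with ranking_score >= threshold AND empirical_p <= threshold.

    Both boundaries are inclusive.  Output is stably sorted by feature, then
    empirical p ascending, then ranking score descending.
    """
    kept = [s for s in scores
            if s.ranking_score is not None and s.empirical_p is not None
            and s.ranking_score >= ranking_threshold
            and s.empirical_p <= p_threshold]
    return sorted(kept, key=lambda s: (s.feature, s.empirical_p,
                                       -s.ranking_score, s.pathway_id))


def overlap_enrichment(risk_genes, pathway: PathwayRecord, universe) -> float:
    """One-sided hypergeometric overlap enrichment p-value.

    P(X >= observed overlap) with population |universe|, successes
    |members ∩ universe|, draws |risk ∩ universe|.  This is the traditional
    pathway-enrichment baseline the embedding method is compared against.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    members = set(pathway.members)
    if not members <= universe:
        logger.warning("pathway %s: %d member(s) outside the universe trimmed",
                       pathway.pathway_id, len(members - universe))
        members &= universe
    risk = set(risk_genes) & universe
    k = len(risk & members)
    return float(hypergeom.sf(k - 1, len(universe), len(members), len(risk)))


def score_pathways(emb: EmbeddingSpace, net: MultiplexHeterogeneousNetwork,
                   risk_set, feature: str, null: NullModel | None = None,
                   aggregate: str = "mean") -> list[PathwayScore]:
    """Score every pathway of the network against one feature's risk set.

    Computes correlation scores, within-database ranks and ranking scores,
    and (when a null model is given) empirical p-values sharing one null
    distribution per (type composition, pathway).
    """
    present = _effective_risk_set(emb, risk_set)
    n_mrna = sum(1 for m in present if net.node_kind(m) == "mRNA")
    n_mirna = sum(1 for m in present if net.node_kind(m) == "miRNA")
    risk_gene_set = set(present)
    raw = []
    for p in sorted(net.pathways, key=lambda p: p.pathway_id):
        cs = correlation_score(emb, present, p.pathway_id, aggregate=aggregate)
        raw.append(PathwayScore(
            feature=feature, pathway_id=p.pathway_id, source_db=p.source_db,
            correlation_score=cs,
            overlap_count=len(p.members & risk_gene_set),
        ))
    ranked = rank_and_score(raw)
    if null is None:
        return sorted(ranked, key=lambda s: (s.feature, s.pathway_id))
    out = []
    for s in sorted(ranked, key=lambda s: s.pathway_id):
        nulls = _null_scores(emb, net, n_mrna, n_mirna, s.pathway_id, null,
                             aggregate=aggregate)
        b = int(np.sum(nulls >= s.correlation_score))
        out.append(PathwayScore(
            feature=s.feature, pathway_id=s.pathway_id, source_db=s.source_db,
            correlation_score=s.correlation_score, rank_in_db=s.rank_in_db,
            ranking_score=s.ranking_score,
            empirical_p=(1 + b) / (1 + null.n_permutations),
            overlap_count=s.overlap_count,
        ))
    return out
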