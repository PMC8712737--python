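# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open — in enough detail that a maintainer can
change any of them deliberately.

## Network model and commixture construction

The multiplex-heterogeneous network has three node types. mRNAs and miRNAs
each carry a weighted undirected intra-layer network (interaction
confidences are used as-is; no rescaling). miRNA↔mRNA target couplings are
treated as undirected unit-weight edges, as are pathway↔member links.
Node identity is positional and deterministic: sorted mRNAs, then sorted
miRNAs, then sorted pathway ids, so rebuilding from shuffled input rows
yields the identical matrix.

The transition ("commixture") matrix is assembled column-wise. For a
molecule column the outgoing mass is split by edge class — λ to pathway
links, δ to couplings, 1−δ−λ to intra-layer edges, each distributed
weight-proportionally within its class. When a class is absent at a node
its share is renormalized over the present classes (a gene with no pathway
membership and no targeting miRNA walks purely within its layer). Pathway
columns send all mass to member molecules. Nodes with no edges at all
(typically a pathway none of whose members is in the gene layer) receive a
unit self-loop: this keeps the matrix exactly column-stochastic without
introducing global teleportation, which the walk model does not otherwise
contain. Normalization happens once, over the full node set, after all
blocks are attached.

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| r (restart) | 0.7 | probability of restarting at the seed each step; common practice for RWR on biological networks, keeps the walk local |
| δ (coupling jump) | 0.3 | share of a molecule's mass crossing the miRNA↔mRNA bipartite coupling |
| λ (pathway jump) | 0.2 | share flowing into pathway membership links |
| d (embedding dim) | min(128, n−1) | truncation rank of the SVD |

δ + λ < 1 is enforced so intra-layer movement always keeps positive share.
All four live in `WalkParams` / the run config, so alternatives are one
config edit away. By default pathways link only to member mRNAs; an
optional rule (`link_mirna_pathways`, off by default, threshold 3) also
links a pathway to miRNAs with at least that many member targets, since
miRNAs relate to pathways only through their targets.

## Random walk and embedding

The RWR fixed point p = r(I − (1−r)T)^{-1} p0 is computed by a direct dense
solve for n ≤ 2000 (one factorization yields all seeds at once) and by
power iteration above, with L1 convergence (tol 1e−10, max 10,000
iterations); non-convergence raises rather than silently truncating, and
the two paths agree to < 1e−8 by construction (tested against each other —
the solve is the independent oracle for the iteration).

The proximity matrix (row i = walk from node i) is factorized by truncated
SVD. The Σ^{1/2} split between the row factor ("source") and column factor
("target") balances the norms of the two roles; dot(source_i, target_j)
reconstructs the proximity P_ij exactly at full rank. Sign indeterminacy is
resolved by making the largest-magnitude component of each left singular
vector positive, so embeddings are identical across runs and platforms.
A molecule's relevance to a pathway is cos(source(molecule),
target(pathway)) — the walk is read "from molecule toward pathway". A
`symmetrize` flag averages P with its transpose before the SVD for users
who prefer role-free vectors, and a `log1p` flag embeds log(1+P); both are
off by default (the raw proximity is the modelled quantity). Cosine with a
zero vector is defined as 0 with a logged warning.

## Scoring, ranking score, and the null model

A pathway's correlation score against a feature's risk set is the
arithmetic mean of the per-molecule cosines (max and sum are available via
the `aggregate` option; the mean is the default because it is insensitive
to risk-set size).

**The ranking score is a reconstruction.** The original method defines a
within-database rank transform whose purpose is to correct the size bias of
pathway collections from different databases, and a significance convention
of "ranking score ≥ 6" — but not the formula, which is not public. We use

    ranking_score = −log2(rank_in_db / (N_db + 1))

with competition ("min") ranks on descending correlation score. This form
is monotone in the rank, size-normalized (the score of a given quantile is
the same in any database), and calibrates the conventional threshold of 6
to exactly the top 1/64 ≈ 1.6 % of a database — rank 1 of 63 scores 6.0.
Its direct consequence: a database of fewer than 63 pathways can never
produce a "significant" pathway at threshold 6. That is intended behaviour
for real collections (KEGG/Reactome-scale databases hold hundreds of
sets), but at toy collection sizes the threshold must be read against
log2(N_db+1), the best attainable value.

The empirical p-value permutes *molecules*: N random sets drawn uniformly
from the network's molecule nodes, matched to the risk set's mRNA/miRNA
composition (degree-matched nulls are not implemented; type matching was
chosen as the minimal null that respects the blended-set structure). The
add-one estimator p = (1 + b)/(1 + N) never returns 0. Draws are seeded
per pathway (CRC32 of the pathway id mixed into the null seed), so p-values
are reproducible and pathways do not share null sets. Selection keeps
pathways passing both thresholds (ranking ≥ 6, p ≤ 0.05, boundaries
inclusive). No multiplicity correction is applied beyond these two
thresholds — a deliberate mirror of the method's convention, and a known
limitation.

The traditional baseline is the one-sided hypergeometric tail
P(X ≥ overlap) via `scipy.stats.hypergeom`; tests verify it against direct
tail summation.

## ceRNA/SNP statistics

A ceRNA regulation is a triple (lncRNA, miRNA, mRNA) with both edges
present in the evidence tables, the mRNA in the pathway, and all three
molecules in the admitted risk catalog. Admission is feature-strict by
default; a permissive flag admits risk molecules of any feature, matching
analyses where overlapping pathways mix features.

SNP attachment rules: a binding-site SNP on lncRNA l with partner miRNA mi
attaches to the l–mi edge of regulations with that pair; a seed-region SNP
on mi attaches to the mi–mRNA edge of every regulation through mi; a 3′UTR
SNP on mRNA m attaches to regulations with that mRNA, restricted to the
named partner miRNA when one is given (without a partner it attaches to all
of m's regulations — a conservative superset). Gene-body and
pri-/pre-miRNA SNPs are carried as host annotations and are *not*
regulatory: they do not enter density/ratio numerators or the switch
filter.

For one pathway network: **ratio** = regulations carrying ≥ 1 regulatory
SNP / all regulations; **density** = distinct regulatory SNPs /
regulations carrying them (undefined when the denominator is 0, reported
as NA). "Distinct" counting (an rsID shared by several regulations counts
once) is the default reading of "number ratio of SNPs to the regulations
containing them"; per-attachment counting is available via
`counting="attachment"`. The identity density × regulations-with-SNP =
distinct-SNP-count holds exactly and is tested. Switch candidates are
regulations with regulatory SNPs on *both* edges; the upstream/"receptor"
positioning of a gene within its pathway diagram is a manual judgement, so
the filter accepts an optional user-supplied upstream-gene list instead of
inferring topology.

## Synthetic data

The generator emulates the input ecosystem, not any specific database's
weight distribution. Defaults (one bundle): 200 mRNAs, 50 miRNAs,
10 lncRNAs, 20 pathways of 15–30 members split over two synthetic source
databases, Erdős–Rényi background layers at edge probability 0.05 with
weights uniform on [0.2, 0.9], a risk catalog of 15 mRNAs + 6 miRNAs +
4 lncRNAs, planted fraction 0.7, and a regulatory-SNP rate of 0.3 per
eligible edge. Planting densifies the planted pathway's member module
(intra-module edge probability 0.8) and draws the risk catalog from that
module and from miRNAs given ≥ 2 module targets — topology, not weights,
carries the signal, so recovery tests the walk rather than weight leakage.
Risk-set sizes and the feature label are generator parameters because a
bundle is not usable without them; the sizes are desk-scale analogues of
literature-curated catalogs (tens of molecules per feature).

All randomness flows through a single `numpy.random.default_rng(seed)`
(PCG64) per bundle; emitted files are byte-identical across runs. A
brute-force recount oracle (`expected_stats`) recomputes the CSSPN
statistics from the emitted tables by plain cross-join enumeration,
independent of the package's indexed construction, and the two are asserted
equal over 100 seeded bundles.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic degree distributions and edge-weight
structure (STRING confidences are highly non-uniform), identifier
ambiguity, database version skew, literature-curation biases in risk
catalogs, and linkage between SNPs. Recovery rates on planted bundles
measure the method's internal consistency, not its sensitivity on real
cohorts.

## Numerical and degenerate-input choices

* Column sums of the commixture matrix are asserted to 1e−9 at build time;
  the property tests verify 1e−12 over seeded builds.
* Duplicate undirected edges merge keeping the maximum weight
  (confidence semantics); self-edges are dropped with a logged count.
* Rank ties share the minimum (competition) rank, so tied top scores share
  the top ranking score.
* Readers reject invariant-violating rows with per-row diagnostics and
  assert rows_in = records_out + rejected.
* Score tables render floats at 6 significant digits; round-trip tests
  hold to that precision.
* Problem sizes in the test-suite and acceptance script (bundles of
  ~270 nodes, 20 recovery replicates, 200 calibration replicates, N = 199
  permutations) are desk-scale choices: large enough for stable rates,
  small enough that the direct dense RWR solve applies throughout.

## Known limitations

* The ranking-score formula is a reconstruction (above); absolute
  ranking-score values are comparable across databases by construction but
  not guaranteed to match the original implementation's values.
* The null permutes molecule sets; permuting edges or pathway labels are
  plausible alternative nulls and would give different p-values.
* No FDR control across pathways or features.
* No identifier mapping: inputs must share one namespace.
* Pathway→miRNA links are off by default; with them on, λ mass at a
  pathway spreads over member mRNAs *and* qualifying miRNAs.
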