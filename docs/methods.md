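# Methods

## Model

The package scores agent pairs on a disease-specific background network:
an undirected, unweighted graph of gene nodes.  The working assumptions
are (1) the network's important nodes (hubs, bottlenecks) are the
effective attack points for modulating the disease state; (2) two agents
can only couple synergistically through the network if their gene
footprints are mutually close; and (3) agents with *independent*
mechanisms that treat *similar* diseases are the better synergy
candidates.  The first two assumptions are captured by the Topology
Score, the third by the Agent Score weight, and the independence caveat
by the validity band on the product score.

### Node importance

IP(v) integrates three centralities:

- shortest-path betweenness, normalized by (n−1)(n−2)/2;
- harmonic closeness (mean inverse distance to the other nodes,
  unreachable pairs contributing 0) — chosen over classic closeness
  because real background networks are frequently disconnected and
  harmonic closeness remains well defined there;
- PageRank with damping 0.85 (the canonical default) on the undirected
  graph, iterated to an L1 tolerance of 1e−12 so scores are converged far
  below the precision any downstream comparison relies on.

Each column is z-scored (correlation-matrix PCA: the three measures have
incommensurate scales), the matrix is decomposed by SVD, and the raw
importance is the projection on the first principal component.  PCA
leaves the component's sign arbitrary, so it is fixed by requiring a
positive inner product with the row sums of the standardized matrix —
importance increases with overall centrality.  Scores are min–max scaled
to [0, 1].  Degree can be added as a fourth column
(`compute_centralities(..., include_degree=True)`) for users who want
the raw-connectivity axis included.

Degenerate inputs: a constant centrality column standardizes to zeros; if
all three are constant, IP is all-zero with explained variance reported
as 1.0 by convention and a warning.

### Topology Score

TS = ½ [Σᵢ IP(i)·e^(−r·dᵢ) / Σᵢ IP(i) + Σⱼ IP(j)·e^(−r·dⱼ) / Σⱼ IP(j)],
where dᵢ is the hop distance from gene i of one agent to the nearest
mapped gene of the other, and r is the decay rate (default 1.0 per hop,
configurable).  Normalizing each dual term by its Σ IP makes the term an
importance-weighted mean in [0, 1]; averaging the two terms keeps the
score symmetric and bounded.  Conventions:

- d = 0 for a shared gene (e⁰ = 1, maximal coupling);
- unreachable partner genes contribute e^(−∞) = 0 — genes in different
  components cannot couple through the network;
- agent genes absent from the background network are excluded from the
  sums but counted and reported, so mapping failures are visible rather
  than silent;
- an agent whose mapped genes all carry zero importance has its dual
  term set to 0 with a warning (the weighted mean is undefined).

`topology_score_matrix` runs one multi-source BFS per agent (distance of
every node to that agent's nearest gene), so all n(n−1)/2 pair scores
reuse n traversals.

### Agent Score and synergy score

AS is the mean similarity over the full cross product of the two agents'
phenotype sets.  The similarity matrix is consumed as input (values in
[0, 1], symmetric, unit diagonal); phenotypes missing from it are dropped
with a warning.  An agent with no covered phenotypes gets the neutral
weight AS = 1.0 and a flag, so S degrades to TS instead of zeroing pairs
for which disease annotation happens to be unavailable.

S = TS × AS.  Pairs with S > 0.9 are flagged invalid: a near-maximal
score means near-coincident gene sets, which contradicts the
Bliss-independence assumption underlying the whole construction.  Invalid
pairs are reported but excluded from rank positions.  Ranking sorts by
descending S with deterministic tie-breaks (descending TS, then partner
id).

### Baselines and the experimental readout

meet/min = |G₁∩G₂| / min(|G₁|,|G₂|) is the network-free overlap
baseline; it dominates the Jaccard index for every pair.  The GO
Union–Intersection score pools each agent's gene annotations into one
term set and takes intersection over union.  Bliss additivity is
IR₁+IR₂−IR₁·IR₂ for inhibition fractions, and MIIR is the maximum excess
of the observed combination over that expectation across dose rows; a
variant restricts the maximum to rows whose combination inhibition
strictly exceeds 70% (the effectiveness convention for low-dose
combinations), default unrestricted.  Percentage-scale input tables are
auto-detected (any rate > 1) and converted with a warning.

### Robustness protocol

Perturb, re-score all pairs, and compare rankings by SRCC against the
unperturbed baseline; aggregate mean ± sd over repetitions (default 100
for gene perturbations, 20 for edge perturbations).  Gene perturbations
add/remove round(f·|genes|) genes per agent (half-away-from-zero
rounding, minimum 1 when f > 0; additions drawn from the network node
set) and keep node importance fixed; edge perturbations recompute
centralities and importance on the perturbed network.  All agents are
perturbed simultaneously per repetition (a per-agent mode is available
behind `ScoringContext.perturb_mode`).  A master seed spawns independent
child generators per (fraction, repetition), so reports are exactly
reproducible.  Besides uniform-random removal, `gene_strategy="top_ip"`
removes each agent's highest-importance genes — the targeted probe
showing that rankings tolerate random loss but degrade quickly when the
key genes go.

## Synthetic data

The generator emulates the input ecosystem with planted, verifiable
structure:

- **Network**: Barabási–Albert preferential attachment by default
  (m = 3), matching the scale-free character of disease gene networks;
  Erdős–Rényi and lattice topologies are available as contrasts.
- **Agents**: gene counts drawn uniformly from 10–108 by default, the
  range typical of manually curated agent gene sets.  Designed
  synergistic pairs are placed as compact BFS balls around two *adjacent*
  hubs; designed null pairs around two mutually distant low-degree
  (bottom-half) nodes; remaining agents uniformly at random.
- **Phenotypes**: a block similarity matrix (0.8 within a disease block,
  0.1 between, unit diagonal); synergistic pairs share a block, null
  pairs straddle blocks.
- **Dose–response**: monotone saturating single-agent curves with
  plateaus below 0.5 (leaving headroom for a super-additive bump), a
  combination equal to the Bliss expectation plus the planted MIIR at one
  dose (applied at every dose when negative, so recovery stays exact),
  and optional Gaussian noise.

What the generator does *not* emulate: literature-derived edge noise and
ascertainment bias, correlated annotation errors between agents and
network, realistic OMIM-derived similarity distributions, or
pharmacokinetics.  Passing tests therefore demonstrate the machinery is
correct and the planted signal is recoverable under idealized conditions,
not that the score is accurate on any particular curated data set.

## Problem sizes and numerical choices

The validation suite runs at desk scale, chosen to exercise each claim on
the smallest data that can show it: oracle equivalence on 200 random
networks of ≤ 30 nodes against literal brute-force evaluations;
planted-synergy recovery on 100 scenarios of 200 nodes with 4 agents and
10–20 genes per agent (the 10–108 default trimmed to keep hub and
peripheral placements disjoint at 200 nodes); robustness on one 500-node,
10-agent scenario with 20 repetitions per condition.  Tolerances: exact
equality where the arithmetic is exact (closed-form TS, S = TS·AS,
MIIR of noiseless tables), 1e−10/1e−12 for oracle agreement, 1e−8 for
centralities against independently converged brute-force oracles.

## Known limitations

- Synergy and antagonism are not distinguished; S ranks candidate
  synergy strength under an independence assumption and the > 0.9 band
  only flags where that assumption fails.
- The network is undirected and unweighted; directed centralities and
  weighted distance decay are out of scope.
- More than two agents are supported only by pooling a mixture's genes
  into one agent profile.
- The exact magnitude of TS depends on unstated conventions of the
  original formulation (IP scaling, decay rate); rankings are the
  meaningful output, and the decay rate is exposed for sensitivity
  analysis.
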