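"""Synthetic benchmark generator with planted synergy structure.

Real inputs to network-target synergy scoring — a disease gene network,
per-agent gene sets, a phenotype-similarity resource, GO annotations and
dose–response assays — are curated and not redistributable, so every stage
is exercised on synthetic counterparts with controllable, *known* planted
structure:

* a scale-free (preferential-attachment) background network, the topology
  class disease gene networks resemble and the one whose robust-to-random /
  fragile-to-hub-deletion behaviour the robustness protocol probes;
* agent gene sets placed either around adjacent hub modules (designed
  synergistic pairs: important, mutually close genes) or on distant
  peripheral nodes (designed null pairs), with gene counts drawn from the
  10–108 range typical of curated agents;
* a block-structured phenotype-similarity matrix (within-disease-block
  similarity high, between-block low) with synergistic pairs sharing a
  block and null pairs split across blocks;
* GO annotations and Bliss dose–response tables with a planted MIIR.

Everything is reproducible: one scenario seed determines every artifact.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import yaml

from .bliss_synergy import DoseResponseTable, bliss_additive
from .network_model import (
    AgentProfile,
    BackgroundNetwork,
    PhenotypeSimilarity,
    save_agents,
    save_network,
)

__all__ = [
    "SyntheticScenario",
    "ScenarioData",
    "generate_scenario",
    "write_scenario",
    "generate_dose_response",
]


@dataclass
class SyntheticScenario:
    """Declarative description of one synthetic benchmark.

    The first ``2·n_synergistic_pairs`` agents form designed-synergistic
    pairs (hub-adjacent placement, adjacent modules, shared phenotype
    block); the next ``2·n_null_pairs`` agents form designed-null pairs
    (peripheral placement, distant anchors, different phenotype blocks);
    any remaining agents are placed uniformly at random.
    """

    model: str = "scale-free"  # scale-free | random | lattice
    n_nodes: int = 500
    attachment: int = 3  # preferential-attachment edges per new node
    edge_prob: float = 0.02  # for the random (Erdős–Rényi) model
    n_agents: int = 10
    genes_per_agent: tuple[int, int] = (10, 108)
    n_synergistic_pairs: int = 1
    n_null_pairs: int = 1
    n_phenotypes: int = 8
    n_blocks: int = 2
    within_block_sim: float = 0.8
    between_block_sim: float = 0.1
    phenotypes_per_agent: int = 2
    n_go_terms: int = 20
    seed: int = 0


@dataclass
class ScenarioData:
    """All artifacts of one generated scenario plus the planted truth."""

    network: BackgroundNetwork
    agents: list[AgentProfile]
    similarity: PhenotypeSimilarity
    go_annotations: dict[str, frozenset[str]]
    manifest: dict = field(default_factory=dict)


def _generate_graph(spec: SyntheticScenario) -> nx.Graph:
    if spec.model == "scale-free":
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=spec.seed)
    elif spec.model == "random":
        g = nx.gnp_random_graph(spec.n_nodes, spec.edge_prob, seed=spec.seed)
    elif spec.model == "lattice":
        side = int(np.ceil(np.sqrt(spec.n_nodes)))
        g = nx.grid_2d_graph(side, side)
        g = nx.convert_node_labels_to_integers(g)
        g = g.subgraph(range(spec.n_nodes)).copy()
    else:
        raise ValueError(f"unknown network model {spec.model!r}")
    width = len(str(spec.n_nodes))
    return nx.relabel_nodes(g, {i: f"g{i:0{width}d}" for i in g.nodes})


def _bfs_layers(g: nx.Graph, anchor: str) -> list[list[str]]:
    dist = {anchor: 0}
    layers: list[list[str]] = [[anchor]]
    queue = deque([anchor])
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                while len(layers) <= dist[v]:
                    layers.append([])
                layers[dist[v]].append(v)
                queue.append(v)
    return layers


def _place_genes(
    g: nx.Graph,
    anchor: str,
    n_genes: int,
    rng: np.random.Generator,
    allowed: set[str] | None = None,
) -> frozenset[str]:
    """Pick ``n_genes`` nodes by growing a BFS ball around the anchor.

    Nodes are taken layer by layer (shuffled within a layer) so the gene
    set is a compact module around the anchor.  ``allowed`` restricts the
    candidate pool (e.g. to low-degree nodes); the restriction is relaxed
    to the whole graph if the pool runs out.
    """
    layers = _bfs_layers(g, anchor)
    chosen: list[str] = []
    for restrict in (allowed, None):
        for layer in layers:
            pool = sorted(
                v
                for v in layer
                if v not in chosen and (restrict is None or v in restrict or v == anchor)
            )
            rng.shuffle(pool)
            for v in pool:
                chosen.append(v)
                if len(chosen) == n_genes:
                    return frozenset(chosen)
    raise ValueError(
        f"cannot place {n_genes} genes around {anchor!r}: only "
        f"{len(chosen)} reachable nodes"
    )


def _farthest_from(g: nx.Graph, sources: Iterable[str], within: set[str]) -> str:
    """Node of ``within`` at maximal hop distance from the nearest source."""
    dist: dict[str, int] = {}
    queue: deque[str] = deque()
    for s in sources:
        dist[s] = 0
        queue.append(s)
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    candidates = sorted(within, key=lambda v: (-dist.get(v, len(g)), v))
    return candidates[0]


def generate_scenario(spec: SyntheticScenario) -> ScenarioData:
    """Generate a full scenario: network, agents, similarities, annotations.

    The manifest records the planted truth — which agent pairs were
    designed synergistic (adjacent hub modules, same phenotype block) and
    which designed null (distant peripheral modules, different blocks) —
    along with each agent's anchor node and mean degree percentile.
    """
    needed = 2 * (spec.n_synergistic_pairs + spec.n_null_pairs)
    if spec.n_agents < needed:
        raise ValueError(
            f"{spec.n_agents} agents cannot host {spec.n_synergistic_pairs} "
            f"synergistic and {spec.n_null_pairs} null pairs ({needed} needed)"
        )
    lo, hi = spec.genes_per_agent
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid genes_per_agent range {spec.genes_per_agent}")
    if hi > spec.n_nodes:
        raise ValueError("genes_per_agent upper bound exceeds node count")

    g = _generate_graph(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    degrees = dict(g.degree())
    by_degree = sorted(g.nodes, key=lambda v: (-degrees[v], v))
    degree_rank = {v: i for i, v in enumerate(by_degree)}
    n = len(by_degree)
    peripheral_pool = set(by_degree[n // 2:])  # bottom half by degree

    agents: list[AgentProfile] = []
    anchors: dict[str, str] = {}
    placements: dict[str, str] = {}
    synergistic_pairs: list[tuple[str, str]] = []
    null_pairs: list[tuple[str, str]] = []

    def n_genes() -> int:
        return int(rng.integers(lo, hi + 1))

    # designed-synergistic pairs: two agents on adjacent hub modules
    hub_cursor = 0
    for k in range(spec.n_synergistic_pairs):
        hub1 = by_degree[hub_cursor]
        hub_cursor += 1
        neighbors = sorted(g[hub1], key=lambda v: (-degrees[v], v))
        if not neighbors:
            raise ValueError(f"hub {hub1!r} is isolated; cannot plant a pair")
        hub2 = neighbors[0]
        id1, id2 = f"SYN{2 * k + 1}", f"SYN{2 * k + 2}"
        agents.append(
            AgentProfile(id1, _place_genes(g, hub1, n_genes(), rng), description="hub-adjacent")
        )
        agents.append(
            AgentProfile(id2, _place_genes(g, hub2, n_genes(), rng), description="hub-adjacent")
        )
        anchors[id1], anchors[id2] = hub1, hub2
        placements[id1] = placements[id2] = "hub-adjacent"
        synergistic_pairs.append((id1, id2))

    # designed-null pairs: two agents on distant peripheral modules
    hub_anchors = [anchors[a] for a, _ in synergistic_pairs] or [by_degree[0]]
    for k in range(spec.n_null_pairs):
        a1 = _farthest_from(g, hub_anchors, peripheral_pool)
        a2 = _farthest_from(g, hub_anchors + [a1], peripheral_pool - {a1})
        id1, id2 = f"NULL{2 * k + 1}", f"NULL{2 * k + 2}"
        agents.append(
            AgentProfile(id1, _place_genes(g, a1, n_genes(), rng, allowed=peripheral_pool),
                         description="peripheral")
        )
        agents.append(
            AgentProfile(id2, _place_genes(g, a2, n_genes(), rng, allowed=peripheral_pool),
                         description="peripheral")
        )
        anchors[id1], anchors[id2] = a1, a2
        placements[id1] = placements[id2] = "peripheral"
        null_pairs.append((id1, id2))
        hub_anchors.extend([a1, a2])

    # remaining agents: uniform random placement
    for k in range(spec.n_agents - needed):
        aid = f"RND{k + 1}"
        genes = frozenset(
            str(v) for v in rng.choice(sorted(g.nodes), size=min(n_genes(), n), replace=False)
        )
        agents.append(AgentProfile(aid, genes, description="random"))
        placements[aid] = "random"

    # phenotype similarity: block structure
    ph_ids = [f"PH{i + 1}" for i in range(spec.n_phenotypes)]
    block_of = {p: i * spec.n_blocks // spec.n_phenotypes for i, p in enumerate(ph_ids)}
    mat = np.full((spec.n_phenotypes, spec.n_phenotypes), spec.between_block_sim)
    for i, p in enumerate(ph_ids):
        for j, q in enumerate(ph_ids):
            if block_of[p] == block_of[q]:
                mat[i, j] = spec.within_block_sim
        mat[i, i] = 1.0
    similarity = PhenotypeSimilarity(ph_ids, mat)

    blocks: dict[int, list[str]] = {}
    for p in ph_ids:
        blocks.setdefault(block_of[p], []).append(p)

    def sample_block(block: int) -> frozenset[str]:
        pool = blocks[block % spec.n_blocks]
        k = min(spec.phenotypes_per_agent, len(pool))
        return frozenset(str(p) for p in rng.choice(pool, size=k, replace=False))

    with_phenos: list[AgentProfile] = []
    for a in agents:
        if a.agent_id.startswith("SYN"):
            pair_idx = (int(a.agent_id[3:]) - 1) // 2
            phenos = sample_block(pair_idx)  # both members share a block
        elif a.agent_id.startswith("NULL"):
            member = (int(a.agent_id[4:]) - 1) % 2
            phenos = sample_block(member)  # members land in different blocks
        else:
            phenos = frozenset(
                str(p)
                for p in rng.choice(
                    ph_ids, size=min(spec.phenotypes_per_agent, len(ph_ids)),
                    replace=False,
                )
            )
        with_phenos.append(a.with_phenotypes(phenos))
    agents = with_phenos

    # GO annotations: 1-3 terms per gene from a shared pool
    terms = [f"GO:{i + 1:07d}" for i in range(spec.n_go_terms)]
    go_annotations = {
        v: frozenset(
            str(t) for t in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False)
        )
        for v in sorted(g.nodes)
    }

    pct = {
        a.agent_id: float(
            np.mean([1.0 - degree_rank[v] / (n - 1) for v in sorted(a.genes)])
        )
        for a in agents
    }
    manifest = {
        "seed": spec.seed,
        "model": spec.model,
        "n_nodes": spec.n_nodes,
        "n_edges": g.number_of_edges(),
        "planted_synergistic_pairs": [list(p) for p in synergistic_pairs],
        "planted_null_pairs": [list(p) for p in null_pairs],
        "agents": {
            a.agent_id: {
                "n_genes": len(a.genes),
                "placement": placements[a.agent_id],
                "anchor": anchors.get(a.agent_id),
                "mean_degree_percentile": round(pct[a.agent_id], 4),
                "phenotypes": sorted(a.phenotypes),
            }
            for a in agents
        },
    }

    net = BackgroundNetwork(g.edges, nodes=g.nodes, name=f"synthetic-{spec.model}")
    return ScenarioData(net, agents, similarity, go_annotations, manifest)


def write_scenario(data: ScenarioData, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario in the standard exchange formats.

    Emits ``network.tsv`` (edge list), ``agents.gmt``, ``phenotypes.tsv``
    (agent→phenotype membership), ``phenotype_similarity.tsv``,
    ``go_annotations.tsv`` and ``manifest.yaml``; outputs are sorted so the
    same scenario always produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "agents": outdir / "agents.gmt",
        "phenotypes": outdir / "phenotypes.tsv",
        "similarity": outdir / "phenotype_similarity.tsv",
        "go": outdir / "go_annotations.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    save_network(data.network, paths["network"])
    save_agents(data.agents, paths["agents"])
    with open(paths["phenotypes"], "w") as fh:
        for a in data.agents:
            for p in sorted(a.phenotypes):
                fh.write(f"{a.agent_id}\t{p}\n")
    with open(paths["similarity"], "w") as fh:
        ids = data.similarity.phenotype_ids
        fh.write("\t" + "\t".join(ids) + "\n")
        for i, p in enumerate(ids):
            row = "\t".join(f"{v:.6g}" for v in data.similarity.matrix[i])
            fh.write(f"{p}\t{row}\n")
    with open(paths["go"], "w") as fh:
        for gene in sorted(data.go_annotations):
            for term in sorted(data.go_annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(data.manifest, fh, sort_keys=True)
    return paths


def generate_dose_response(
    n_doses: int = 8,
    planted_miir: float = 0.15,
    noise_sd: float = 0.0,
    seed: int | None = None,
    peak_index: int | None = None,
) -> DoseResponseTable:
    """Dose–response table with a planted Bliss excess of ``planted_miir``.

    Single-agent curves are monotone saturating (Hill-type, plateaus below
    0.5 each so the Bliss expectation leaves headroom for the bump); the
    combination equals the Bliss additive curve plus ``planted_miir`` at
    the designated peak dose (for a negative planted value the offset is
    applied at every dose, making the combination uniformly sub-additive),
    plus optional Gaussian noise, clipped to [0, 1].
    """
    if not -1 <= planted_miir <= 1:
        raise ValueError("planted_miir must lie in [-1, 1]")
    if n_doses < 1:
        raise ValueError("need at least one dose")
    rng = np.random.default_rng(seed)
    dose1 = np.geomspace(0.25, 8.0, n_doses)
    dose2 = dose1 * 2.0  # fixed IC50-ratio design
    ir1 = 0.5 * dose1 / (dose1 + 1.0)
    ir2 = 0.5 * dose2 / (dose2 + 2.0)
    add = bliss_additive(ir1, ir2)
    combo = np.atleast_1d(add).astype(float).copy()
    if peak_index is None:
        peak_index = n_doses // 2
    if not 0 <= peak_index < n_doses:
        raise ValueError("peak_index out of range")
    if planted_miir >= 0:
        combo[peak_index] += planted_miir
    else:
        combo += planted_miir
    if noise_sd > 0:
        combo = combo + rng.normal(0.0, noise_sd, size=n_doses)
    combo = np.clip(combo, 0.0, 1.0)
    return DoseResponseTable(dose1, dose2, ir1, ir2, combo)
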