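"""Background-network and agent/phenotype input handling.

The background network is the disease-specific gene network against which
agent pairs are scored: an undirected, unweighted graph whose nodes are gene
identifiers.  Agents are gene sets (their footprint on the network) with an
optional set of disease phenotypes.  This module loads and validates those
inputs and provides the shortest-path services the scoring layers build on.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BackgroundNetwork",
    "AgentProfile",
    "PhenotypeSimilarity",
    "InputFormatError",
    "load_network",
    "save_network",
    "load_agents",
    "load_phenotype_membership",
    "load_phenotype_similarity",
    "merge_node_groups",
    "min_distance",
    "distances_to_set",
    "extract_pair_subnetwork",
]

INFINITE_DISTANCE = float("inf")


class InputFormatError(ValueError):
    """Raised when an input file violates its expected format."""


class BackgroundNetwork:
    """Undirected, unweighted gene network.

    Self-loops are dropped on construction (with a warning) and parallel
    edges collapse, so the edge set is a set of unordered node pairs.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` node-id pairs.
    nodes
        Extra isolated nodes to include beyond edge endpoints.
    name
        Label used in reports and file headers.
    member_map
        For networks produced by :func:`merge_node_groups`: mapping from
        each (group) node to the set of original member genes.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        name: str = "network",
        member_map: Mapping[str, frozenset[str]] | None = None,
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_self_loops = 0
        for u, v in edges:
            if u == v:
                n_self_loops += 1
                g.add_node(u)
            else:
                g.add_edge(u, v)
        if n_self_loops:
            warnings.warn(
                f"dropped {n_self_loops} self-loop(s) while building '{name}'",
                stacklevel=2,
            )
        self.graph = g
        self.name = name
        self.member_map = dict(member_map) if member_map else None

    # -- basic views ------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as sorted unordered pairs."""
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def copy(self) -> "BackgroundNetwork":
        return BackgroundNetwork(self.edges, self.nodes, self.name, self.member_map)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BackgroundNetwork(name={self.name!r}, "
            f"n_nodes={self.n_nodes}, n_edges={self.n_edges})"
        )


@dataclass(frozen=True)
class AgentProfile:
    """An agent's gene footprint plus its known disease phenotypes."""

    agent_id: str
    genes: frozenset[str]
    phenotypes: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "phenotypes", frozenset(self.phenotypes))

    def mapped_genes(self, net: BackgroundNetwork) -> frozenset[str]:
        """Genes present in the background network."""
        return frozenset(g for g in self.genes if net.has_node(g))

    def with_genes(self, genes: Iterable[str]) -> "AgentProfile":
        return AgentProfile(self.agent_id, frozenset(genes), self.phenotypes, self.description)

    def with_phenotypes(self, phenotypes: Iterable[str]) -> "AgentProfile":
        return AgentProfile(self.agent_id, self.genes, frozenset(phenotypes), self.description)


class PhenotypeSimilarity:
    """Symmetric phenotype-similarity matrix with values in [0, 1].

    Wraps a square matrix indexed by phenotype ids.  The similarity between
    two disease phenotypes quantifies how alike their clinical descriptions
    are; it is consumed as an input, never recomputed here.
    """

    #: symmetry tolerance beyond which the matrix is rejected
    SYMMETRY_TOL = 1e-8

    def __init__(self, phenotype_ids: Iterable[str], matrix: np.ndarray) -> None:
        ids = list(phenotype_ids)
        mat = np.asarray(matrix, dtype=float)
        if mat.shape != (len(ids), len(ids)):
            raise InputFormatError(
                f"similarity matrix shape {mat.shape} does not match "
                f"{len(ids)} phenotype ids"
            )
        if np.max(np.abs(mat - mat.T)) > self.SYMMETRY_TOL:
            raise InputFormatError("phenotype similarity matrix is not symmetric")
        if mat.size and (mat.min() < -1e-12 or mat.max() > 1 + 1e-12):
            raise InputFormatError("similarity values must lie in [0, 1]")
        if mat.size and np.max(np.abs(np.diag(mat) - 1.0)) > 1e-9:
            raise InputFormatError("similarity matrix diagonal must be 1")
        self.phenotype_ids = ids
        self.matrix = (mat + mat.T) / 2.0
        self._index = {p: i for i, p in enumerate(ids)}

    def covers(self, phenotype: str) -> bool:
        return phenotype in self._index

    def similarity(self, p: str, q: str) -> float:
        return float(self.matrix[self._index[p], self._index[q]])

    def __len__(self) -> int:
        return len(self.phenotype_ids)


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def load_network(path: str | Path, format: str = "auto") -> BackgroundNetwork:
    """Load an undirected network from a TSV edge list or SIF file.

    Edge list lines hold two whitespace/tab-separated node ids; SIF lines
    hold ``nodeA relation nodeB`` (the relation is ignored).  Lines starting
    with ``#`` are comments.  Self-loops are dropped with a warning and
    duplicate edges are collapsed.
    """
    path = Path(path)
    if format == "auto":
        format = "sif" if path.suffix.lower() == ".sif" else "tsv-edgelist"
    if format not in {"tsv-edgelist", "sif"}:
        raise InputFormatError(f"unknown network format {format!r}")

    edges: list[tuple[str, str]] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "tsv-edgelist":
                if len(fields) < 2:
                    raise InputFormatError(
                        f"{path}:{lineno}: expected two node ids, got {line!r}"
                    )
                u, v = fields[0], fields[1]
            else:  # sif
                if len(fields) == 2:
                    u, v = fields
                elif len(fields) >= 3:
                    u, v = fields[0], fields[2]
                else:
                    raise InputFormatError(
                        f"{path}:{lineno}: malformed SIF line {line!r}"
                    )
            edges.append((u, v))
    if n_lines == 0:
        raise InputFormatError(f"{path}: no edges found")
    return BackgroundNetwork(edges, name=path.stem)


def save_network(net: BackgroundNetwork, path: str | Path, header: str | None = None) -> None:
    """Write a network as a 2-column TSV edge list (sorted, reproducible)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def load_agents(path: str | Path) -> list[AgentProfile]:
    """Load agent gene sets from a GMT file.

    Each line: ``agent_id<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate genes within a line are collapsed; a duplicate agent id
    across lines or a line without genes is an error.
    """
    path = Path(path)
    agents: list[AgentProfile] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}:{lineno}: GMT line needs id, description and ≥1 gene"
                )
            agent_id, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise InputFormatError(f"{path}:{lineno}: agent {agent_id!r} has no genes")
            if agent_id in seen:
                raise InputFormatError(f"{path}:{lineno}: duplicate agent id {agent_id!r}")
            seen.add(agent_id)
            agents.append(AgentProfile(agent_id, genes, description=description))
    if not agents:
        raise InputFormatError(f"{path}: no agents found")
    return agents


def save_agents(agents: Iterable[AgentProfile], path: str | Path) -> None:
    """Write agent gene sets as GMT (genes sorted for reproducibility)."""
    with open(path, "w") as fh:
        for a in agents:
            genes = "\t".join(sorted(a.genes))
            fh.write(f"{a.agent_id}\t{a.description or '-'}\t{genes}\n")


def load_phenotype_membership(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a 2-column TSV of (agent_id, phenotype_id) memberships."""
    path = Path(path)
    membership: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise InputFormatError(
                    f"{path}:{lineno}: expected agent_id and phenotype_id"
                )
            membership.setdefault(fields[0], set()).add(fields[1])
    return {a: frozenset(p) for a, p in membership.items()}


def load_phenotype_similarity(path: str | Path) -> PhenotypeSimilarity:
    """Load a square phenotype-similarity TSV with id header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if list(df.index) != list(df.columns):
        raise InputFormatError(
            f"{path}: header row and column phenotype ids differ"
        )
    return PhenotypeSimilarity([str(p) for p in df.index], df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# graph operations
# ---------------------------------------------------------------------------

def merge_node_groups(
    net: BackgroundNetwork,
    groups: Mapping[str, Iterable[str]],
    mode: str = "keep",
) -> BackgroundNetwork:
    """Collapse node groups (e.g. pathway ortholog groups) into single nodes.

    Two conventions for groups that share member genes:

    * ``keep`` — every group becomes its own node with its member list kept
      as-is (overlapping groups remain distinct nodes).
    * ``merge`` — groups sharing at least one member are unioned into a
      single node.

    In either mode an edge joins two new nodes iff some cross-pair of their
    member genes was adjacent in the input network.  The new network's
    ``member_map`` records the gene content of every node.
    """
    if mode not in {"keep", "merge"}:
        raise ValueError(f"mode must be 'keep' or 'merge', got {mode!r}")

    cleaned: dict[str, frozenset[str]] = {}
    for gid, members in groups.items():
        members = set(members)
        if not members:
            raise InputFormatError(f"group {gid!r} is empty")
        known = {m for m in members if net.has_node(m)}
        unknown = members - known
        if unknown:
            warnings.warn(
                f"group {gid!r}: skipping {len(unknown)} unknown member(s)",
                stacklevel=2,
            )
        if not known:
            raise InputFormatError(f"group {gid!r} has no members in the network")
        cleaned[gid] = frozenset(known)

    if mode == "merge":
        # union-find over groups sharing at least one member
        parent = {gid: gid for gid in cleaned}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        owner: dict[str, str] = {}
        for gid, members in sorted(cleaned.items()):
            for m in sorted(members):
                if m in owner:
                    ra, rb = find(owner[m]), find(gid)
                    if ra != rb:
                        parent[rb] = ra
                else:
                    owner[m] = gid
        merged: dict[str, set[str]] = {}
        for gid, members in cleaned.items():
            merged.setdefault(find(gid), set()).update(members)
        cleaned = {
            "+".join(sorted(g for g in cleaned if find(g) == root)): frozenset(members)
            for root, members in merged.items()
        }

    adjacency = net.graph
    new_edges: list[tuple[str, str]] = []
    ids = sorted(cleaned)
    for i, g1 in enumerate(ids):
        for g2 in ids[i + 1:]:
            m1, m2 = cleaned[g1], cleaned[g2]
            if any(adjacency.has_edge(u, v) for u in m1 for v in m2 if u != v):
                new_edges.append((g1, g2))
    return BackgroundNetwork(
        new_edges, nodes=ids, name=f"{net.name}:{mode}", member_map=cleaned
    )


def _bfs_from(graph: nx.Graph, sources: Iterable[str]) -> dict[str, int]:
    """Hop distances from the nearest of ``sources`` to every reachable node."""
    dist: dict[str, int] = {}
    queue: deque[str] = deque()
    for s in sources:
        if s in graph and s not in dist:
            dist[s] = 0
            queue.append(s)
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in graph[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def distances_to_set(net: BackgroundNetwork, targets: Iterable[str]) -> dict[str, float]:
    """Hop distance from every node to the nearest member of ``targets``.

    Unreachable nodes are absent from the result (treat as infinite).
    """
    return {k: float(v) for k, v in _bfs_from(net.graph, targets).items()}


def min_distance(net: BackgroundNetwork, source: str, targets: Iterable[str]) -> float:
    """Minimum shortest-path length from ``source`` to any member of ``targets``.

    Returns 0 when the source belongs to the target set and ``inf`` when no
    target is reachable.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("targets must be non-empty")
    if not net.has_node(source):
        raise KeyError(f"gene {source!r} is not in the network")
    if source in targets:
        return 0.0
    dist = _bfs_from(net.graph, [source])
    best = INFINITE_DISTANCE
    for t in targets:
        d = dist.get(t)
        if d is not None and d < best:
            best = float(d)
    return best


def extract_pair_subnetwork(
    net: BackgroundNetwork, genes1: Iterable[str], genes2: Iterable[str]
) -> BackgroundNetwork:
    """Union of shortest paths linking each agent's genes to the partner's nearest genes.

    For every mapped gene of one set, all shortest paths to its nearest
    gene(s) in the other set are collected (and vice versa).  The returned
    subnetwork is the mechanistic core two agents act on together.
    """
    g1 = {g for g in genes1 if net.has_node(g)}
    g2 = {g for g in genes2 if net.has_node(g)}
    if not g1 and not g2:
        raise ValueError("neither gene set maps into the network")

    nodes: set[str] = set(g1) | set(g2)
    edges: set[tuple[str, str]] = set()

    def _collect(sources: set[str], targets: set[str]) -> None:
        for s in sources:
            if s in targets:
                continue
            dist = _bfs_from(net.graph, [s])
            reachable = {t: dist[t] for t in targets if t in dist}
            if not reachable:
                continue
            dmin = min(reachable.values())
            for t, d in reachable.items():
                if d != dmin:
                    continue
                for path in nx.all_shortest_paths(net.graph, s, t):
                    nodes.update(path)
                    edges.update(
                        tuple(sorted((path[i], path[i + 1])))
                        for i in range(len(path) - 1)
                    )

    _collect(g1, g2)
    _collect(g2, g1)
    return BackgroundNetwork(edges, nodes=nodes, name=f"{net.name}:pair-subnet")
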