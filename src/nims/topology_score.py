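"""Topology Score (TS) for agent pairs.

TS couples two ideas: important network nodes are the better attack points
for a disease network, and two agents can only act synergistically through
the network if their gene footprints are close.  For agents 1 and 2 with
mapped gene sets G1, G2 and node importance IP, the score is the average of
two dual terms,

    TS = 1/2 [ Σ_{i∈G1} IP(i)·e^{−min_j d(i,j)} / Σ_{i∈G1} IP(i)
             + Σ_{j∈G2} IP(j)·e^{−min_i d(j,i)} / Σ_{j∈G2} IP(j) ],

where min_j d(i,j) is the hop distance from gene i to the nearest gene of
the partner set.  Each term is an importance-weighted mean of exponentially
decayed proximities, so TS lies in [0, 1]: 1 when the gene sets coincide
(all distances 0), 0 when the agents sit in different components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_model import AgentProfile, BackgroundNetwork, distances_to_set
from .node_importance import NodeImportance

__all__ = ["TopologyScore", "topology_score", "topology_score_matrix"]


@dataclass
class TopologyScore:
    """TS for one agent pair with per-gene contributions for inspection."""

    agent1: str
    agent2: str
    ts: float
    contributions: pd.DataFrame  # columns: agent, gene, ip, min_distance
    mapped_counts: dict[str, int] = field(default_factory=dict)
    unmapped_counts: dict[str, int] = field(default_factory=dict)

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.agent1, self.agent2)))


def _dual_term(
    genes: list[str],
    ip_values: dict[str, float],
    dist_to_partner: dict[str, float],
    decay_rate: float,
    agent_id: str,
) -> tuple[float, list[tuple[str, float, float]]]:
    rows = []
    num = 0.0
    den = 0.0
    for g in genes:
        w = ip_values[g]
        d = dist_to_partner.get(g, math.inf)
        rows.append((g, w, d))
        den += w
        if math.isfinite(d):
            num += w * math.exp(-decay_rate * d)
    if den == 0.0:
        warnings.warn(
            f"agent {agent_id!r}: all mapped genes have zero importance; "
            "its dual term is 0",
            stacklevel=3,
        )
        return 0.0, rows
    return num / den, rows


def topology_score(
    net: BackgroundNetwork,
    ip: NodeImportance,
    a1: AgentProfile,
    a2: AgentProfile,
    decay_rate: float = 1.0,
) -> TopologyScore:
    """Compute TS for one agent pair.

    Agent genes absent from the background network are excluded from the
    sums but counted in ``unmapped_counts``.  An agent with no mapped gene
    at all is an error.

    ``decay_rate`` is the rate constant of the exponential distance decay
    (contribution ``exp(-rate * d)``); the default couples adjacent genes
    at weight e⁻¹ per hop.
    """
    mapped1 = sorted(a1.mapped_genes(net))
    mapped2 = sorted(a2.mapped_genes(net))
    for agent, mapped in ((a1, mapped1), (a2, mapped2)):
        if not mapped:
            raise ValueError(
                f"agent {agent.agent_id!r} maps no genes into network {net.name!r}"
            )

    ip_values = ip.as_dict()
    d_to_2 = distances_to_set(net, mapped2)
    d_to_1 = distances_to_set(net, mapped1)

    term1, rows1 = _dual_term(mapped1, ip_values, d_to_2, decay_rate, a1.agent_id)
    term2, rows2 = _dual_term(mapped2, ip_values, d_to_1, decay_rate, a2.agent_id)
    ts = 0.5 * (term1 + term2)

    contrib = pd.DataFrame(
        [(a1.agent_id, g, w, d) for g, w, d in rows1]
        + [(a2.agent_id, g, w, d) for g, w, d in rows2],
        columns=["agent", "gene", "ip", "min_distance"],
    )
    return TopologyScore(
        agent1=a1.agent_id,
        agent2=a2.agent_id,
        ts=float(ts),
        contributions=contrib,
        mapped_counts={a1.agent_id: len(mapped1), a2.agent_id: len(mapped2)},
        unmapped_counts={
            a1.agent_id: len(a1.genes) - len(mapped1),
            a2.agent_id: len(a2.genes) - len(mapped2),
        },
    )


def topology_score_matrix(
    net: BackgroundNetwork,
    ip: NodeImportance,
    agents: list[AgentProfile],
    decay_rate: float = 1.0,
) -> pd.DataFrame:
    """Symmetric TS matrix over all unordered agent pairs.

    One multi-source BFS per agent supplies the distance of every node to
    that agent's nearest mapped gene, so the n·(n−1)/2 pair scores reuse n
    traversals.  The diagonal is 1 (an agent shares all genes with itself).
    """
    if len(agents) < 2:
        raise ValueError("need at least 2 agents")
    ids = [a.agent_id for a in agents]
    ip_values = ip.as_dict()

    mapped = {}
    dists = {}
    for a in agents:
        m = sorted(a.mapped_genes(net))
        if not m:
            raise ValueError(
                f"agent {a.agent_id!r} maps no genes into network {net.name!r}"
            )
        mapped[a.agent_id] = m
        dists[a.agent_id] = distances_to_set(net, m)

    def term(genes: list[str], partner: str, agent_id: str) -> float:
        t, _ = _dual_term(genes, ip_values, dists[partner], decay_rate, agent_id)
        return t

    mat = np.ones((len(agents), len(agents)))
    for i, a in enumerate(agents):
        for j in range(i + 1, len(agents)):
            b = agents[j]
            ts = 0.5 * (
                term(mapped[a.agent_id], b.agent_id, a.agent_id)
                + term(mapped[b.agent_id], a.agent_id, b.agent_id)
            )
            mat[i, j] = mat[j, i] = ts
    return pd.DataFrame(mat, index=ids, columns=ids)
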