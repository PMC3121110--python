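"""Agent Score (AS): mean phenotype similarity between two agents.

Agents that act through independent mechanisms but treat similar diseases
are the better synergy candidates, so the topology score is weighted by how
alike the two agents' disease phenotypes are.  AS is the mean similarity
over all cross pairs of the two phenotype sets:

    AS = Σ_{i∈ph1, j∈ph2} P(i, j) / N,   N = |ph1| · |ph2|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .network_model import AgentProfile, PhenotypeSimilarity

__all__ = ["AgentScore", "agent_score", "derive_agent_phenotypes"]


@dataclass
class AgentScore:
    """AS for one agent pair."""

    agent1: str
    agent2: str
    as_value: float
    n_pairs: int
    missing_phenotypes: dict[str, bool]

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.agent1, self.agent2)))


def agent_score(
    a1: AgentProfile, a2: AgentProfile, sim: PhenotypeSimilarity
) -> AgentScore:
    """Mean phenotype similarity over all cross pairs of the two agents.

    Phenotypes absent from the similarity matrix are dropped with a
    warning.  If either agent ends up with no covered phenotype, AS falls
    back to the neutral value 1.0 (flagged), so the synergy score degrades
    gracefully to the topology score alone.
    """
    covered: dict[str, list[str]] = {}
    missing: dict[str, bool] = {}
    for agent in (a1, a2):
        ph = sorted(p for p in agent.phenotypes if sim.covers(p))
        dropped = len(agent.phenotypes) - len(ph)
        if dropped:
            warnings.warn(
                f"agent {agent.agent_id!r}: {dropped} phenotype(s) missing from "
                "the similarity matrix were dropped",
                stacklevel=2,
            )
        covered[agent.agent_id] = ph
        missing[agent.agent_id] = len(ph) == 0

    ph1, ph2 = covered[a1.agent_id], covered[a2.agent_id]
    if not ph1 or not ph2:
        return AgentScore(a1.agent_id, a2.agent_id, 1.0, 0, missing)

    total = sum(sim.similarity(p, q) for p in ph1 for q in ph2)
    n = len(ph1) * len(ph2)
    return AgentScore(a1.agent_id, a2.agent_id, total / n, n, missing)


def derive_agent_phenotypes(
    a: AgentProfile, phenotype_gene_sets: Mapping[str, Iterable[str]]
) -> frozenset[str]:
    """Phenotypes whose gene sets intersect the agent's genes.

    This is how an agent acquires its phenotypes from a phenotype→genes
    catalogue: any phenotype sharing at least one gene with the agent's
    footprint counts as an agent phenotype.
    """
    return frozenset(
        ph for ph, genes in phenotype_gene_sets.items() if a.genes & set(genes)
    )
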