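"""Permutation-robustness protocol for network-target synergy rankings.

Robustness is probed by perturbing the inputs — adding/removing a fraction
of each agent's genes, or adding/removing a fraction of background-network
edges — re-scoring all agent pairs, and summarizing agreement with the
unperturbed ranking by the Spearman rank correlation coefficient (SRCC).
Gene perturbations default to 100 repetitions per fraction and edge
perturbations to 20, aggregated as mean ± sd.

Besides uniform-random gene removal, a targeted mode removes each agent's
highest-importance genes, which probes the finding that rankings collapse
when the key genes go while tolerating random loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .agent_score import agent_score
from .network_model import AgentProfile, BackgroundNetwork, PhenotypeSimilarity
from .node_importance import NodeImportance, compute_centralities, integrate_ip
from .topology_score import topology_score_matrix

__all__ = [
    "PerturbationPlan",
    "ScoringContext",
    "RobustnessReport",
    "perturb_agent_genes",
    "perturb_edges",
    "run_robustness",
]

PerturbTarget = Literal["agent_genes_add", "agent_genes_remove", "edges_add", "edges_remove"]

DEFAULT_GENE_REPS = 100
DEFAULT_EDGE_REPS = 20


@dataclass
class PerturbationPlan:
    """What to perturb, by how much, and how often."""

    target: PerturbTarget
    fractions: list[float]  # percentages, e.g. [10, 30, 50]
    repetitions: int | None = None  # None -> protocol default per target
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.fractions:
            if f < 0 or f > 100:
                raise ValueError(f"fraction {f} outside [0, 100]")
        if self.repetitions is None:
            self.repetitions = (
                DEFAULT_EDGE_REPS if self.target.startswith("edges") else DEFAULT_GENE_REPS
            )
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class ScoringContext:
    """Everything needed to score all agent pairs: network, agents, similarity."""

    net: BackgroundNetwork
    agents: list[AgentProfile]
    sim: PhenotypeSimilarity | None = None
    decay_rate: float = 1.0
    gene_strategy: Literal["random", "top_ip"] = "random"
    perturb_mode: Literal["all_agents", "per_agent"] = "all_agents"


@dataclass
class RobustnessReport:
    """Mean ± sd SRCC per (target, fraction)."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["target", "fraction", "mean_srcc", "sd_srcc", "n_reps"]
        )


def _n_changed(fraction_pct: float, count: int) -> int:
    """round(fraction·count) half-away-from-zero, at least 1 when fraction > 0."""
    if fraction_pct == 0:
        return 0
    k = math.floor(fraction_pct / 100.0 * count + 0.5)
    return max(k, 1)


def perturb_agent_genes(
    a: AgentProfile,
    fraction: float,
    direction: Literal["add", "remove"],
    gene_pool: set[str],
    rng: np.random.Generator,
    strategy: Literal["random", "top_ip"] = "random",
    ip: NodeImportance | None = None,
) -> AgentProfile:
    """Add or remove a fraction of an agent's genes.

    Additions are drawn uniformly from ``gene_pool`` minus the current
    genes (the pool is normally the background-network node set).  Removal
    is uniform at random, or — with ``strategy='top_ip'`` — targets the
    agent's highest-importance genes.  Removing every gene is an error.
    """
    genes = sorted(a.genes)
    k = _n_changed(fraction, len(genes))
    if k == 0:
        return a
    if direction == "remove":
        if len(genes) - k < 1:
            raise ValueError(
                f"removing {k} gene(s) would empty agent {a.agent_id!r}"
            )
        if strategy == "top_ip":
            if ip is None:
                raise ValueError("strategy='top_ip' requires node importance")
            ip_map = ip.as_dict()
            ranked = sorted(genes, key=lambda g: (-ip_map.get(g, 0.0), g))
            removed = set(ranked[:k])
        else:
            removed = set(rng.choice(genes, size=k, replace=False))
        return a.with_genes(set(genes) - removed)
    if direction == "add":
        candidates = sorted(set(gene_pool) - set(genes))
        if k > len(candidates):
            raise ValueError(
                f"cannot add {k} gene(s) to agent {a.agent_id!r}: "
                f"only {len(candidates)} available in the pool"
            )
        added = set(rng.choice(candidates, size=k, replace=False))
        return a.with_genes(set(genes) | added)
    raise ValueError(f"direction must be 'add' or 'remove', got {direction!r}")


def perturb_edges(
    net: BackgroundNetwork,
    fraction: float,
    direction: Literal["add", "remove"],
    rng: np.random.Generator,
) -> BackgroundNetwork:
    """Remove or add a fraction of edges; the node set is unchanged.

    Added edges are drawn uniformly from the absent non-self node pairs.
    """
    edges = sorted(net.edges)
    k = _n_changed(fraction, len(edges))
    if k == 0:
        return net.copy()
    if direction == "remove":
        if len(edges) - k < 1:
            raise ValueError(f"removing {k} edge(s) would leave no edges")
        idx = rng.choice(len(edges), size=k, replace=False)
        keep = [e for i, e in enumerate(edges) if i not in set(idx.tolist())]
        return BackgroundNetwork(keep, nodes=net.nodes, name=net.name)
    if direction == "add":
        nodes = sorted(net.nodes)
        present = set(edges)
        absent = [
            (u, v)
            for i, u in enumerate(nodes)
            for v in nodes[i + 1:]
            if (u, v) not in present
        ]
        if k > len(absent):
            raise ValueError(
                f"cannot add {k} edge(s): only {len(absent)} absent pairs exist"
            )
        idx = rng.choice(len(absent), size=k, replace=False)
        new = edges + [absent[i] for i in idx.tolist()]
        return BackgroundNetwork(new, nodes=net.nodes, name=net.name)
    raise ValueError(f"direction must be 'add' or 'remove', got {direction!r}")


def _pair_scores(
    net: BackgroundNetwork,
    ip: NodeImportance,
    agents: list[AgentProfile],
    sim: PhenotypeSimilarity | None,
    decay_rate: float,
) -> np.ndarray:
    """Vector of S (or TS when no similarity given) over all unordered pairs."""
    ts = topology_score_matrix(net, ip, agents, decay_rate=decay_rate)
    scores = []
    for i, a in enumerate(agents):
        for j in range(i + 1, len(agents)):
            b = agents[j]
            s = float(ts.iloc[i, j])
            if sim is not None:
                s *= agent_score(a, b, sim).as_value
            scores.append(s)
    return np.array(scores)


def _importance(net: BackgroundNetwork) -> NodeImportance:
    return integrate_ip(compute_centralities(net))


def run_robustness(plan: PerturbationPlan, context: ScoringContext) -> RobustnessReport:
    """Execute a perturbation plan and report SRCC against the baseline ranking.

    Gene perturbations keep the background network (and hence node
    importance) fixed and re-score the pairs; edge perturbations rebuild
    centralities and importance on the perturbed network.  A single master
    seed spawns one child generator per repetition, so runs are exactly
    reproducible and repetitions are independent.
    """
    baseline_ip = _importance(context.net)
    baseline = _pair_scores(
        context.net, baseline_ip, context.agents, context.sim, context.decay_rate
    )
    if len(baseline) < 3:
        raise ValueError("need at least 3 agent pairs for a rank correlation")

    on_genes = plan.target.startswith("agent_genes")
    direction = "add" if plan.target.endswith("add") else "remove"
    gene_pool = context.net.nodes

    report = RobustnessReport()
    for fraction in plan.fractions:
        srccs = []
        for rep in range(plan.repetitions):
            rng = np.random.default_rng(
                np.random.SeedSequence([plan.seed, int(fraction * 100), rep])
            )
            if on_genes:
                def _perturbed(a: AgentProfile) -> AgentProfile:
                    return perturb_agent_genes(
                        a,
                        fraction,
                        direction,
                        gene_pool,
                        rng,
                        strategy=context.gene_strategy,
                        ip=baseline_ip,
                    )

                if context.perturb_mode == "per_agent":
                    # perturb one agent per repetition, cycling through agents
                    target_idx = rep % len(context.agents)
                    agents = [
                        _perturbed(a) if i == target_idx else a
                        for i, a in enumerate(context.agents)
                    ]
                else:
                    agents = [_perturbed(a) for a in context.agents]
                scores = _pair_scores(
                    context.net, baseline_ip, agents, context.sim, context.decay_rate
                )
            else:
                net = perturb_edges(context.net, fraction, direction, rng)
                ip = _importance(net) if fraction > 0 else baseline_ip
                scores = _pair_scores(
                    net, ip, context.agents, context.sim, context.decay_rate
                )
            if np.array_equal(scores, baseline):
                srccs.append(1.0)
            else:
                srccs.append(float(stats.spearmanr(baseline, scores).statistic))
        arr = np.array(srccs)
        report.rows.append(
            {
                "target": plan.target,
                "fraction": fraction,
                "mean_srcc": float(arr.mean()),
                "sd_srcc": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "n_reps": len(arr),
            }
        )
    return report
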