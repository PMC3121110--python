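"""Synergy score S = TS × AS, partner ranking, and network-free baselines.

The synergy score multiplies network proximity/importance (TS) by disease
similarity (AS).  Because the underlying independence assumption (Bliss)
breaks down when two agents hit essentially the same gene set, scores above
0.9 are flagged invalid: such pairs most likely act on the same targets and
cannot be ranked as independent-mechanism synergy candidates.

Baselines: the meet/min overlap coefficient (a purely set-based similarity
that ignores the network) and the Union–Intersection GO similarity of the
two agents' pooled annotation term sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .agent_score import AgentScore, agent_score
from .network_model import AgentProfile, BackgroundNetwork, PhenotypeSimilarity
from .node_importance import NodeImportance
from .topology_score import TopologyScore, topology_score

__all__ = [
    "VALIDITY_THRESHOLD",
    "SynergyResult",
    "RankingResult",
    "synergy_score",
    "rank_partners",
    "meet_min",
    "go_ui_score",
    "correlate_scores",
]

#: scores above this act on overlapping gene sets, violating independence
VALIDITY_THRESHOLD = 0.9


@dataclass
class SynergyResult:
    """Scored agent pair: S = TS × AS with validity flag and rank."""

    agent1: str
    agent2: str
    ts: float
    as_value: float
    s: float
    valid: bool
    rank: int | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.agent1, self.agent2)))


@dataclass
class RankingResult:
    """Ranked valid candidates for a seed agent, invalid pairs kept aside."""

    seed: str
    ranked: list[SynergyResult] = field(default_factory=list)
    invalid: list[SynergyResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": r.rank,
                "seed": self.seed,
                "partner": r.agent2 if r.agent1 == self.seed else r.agent1,
                "ts": r.ts,
                "as": r.as_value,
                "s": r.s,
                "valid": r.valid,
            }
            for r in self.ranked + self.invalid
        ]
        return pd.DataFrame(rows)


def synergy_score(
    ts: TopologyScore, as_: AgentScore, threshold: float = VALIDITY_THRESHOLD
) -> SynergyResult:
    """Combine TS and AS for one pair; flag scores above the validity band."""
    if ts.pair != as_.pair:
        raise ValueError(
            f"pair mismatch: TS is for {ts.pair}, AS is for {as_.pair}"
        )
    s = ts.ts * as_.as_value
    return SynergyResult(
        agent1=ts.agent1,
        agent2=ts.agent2,
        ts=ts.ts,
        as_value=as_.as_value,
        s=s,
        valid=s <= threshold,
    )


def rank_partners(
    seed: str,
    agents: list[AgentProfile],
    net: BackgroundNetwork,
    ip: NodeImportance,
    sim: PhenotypeSimilarity | None = None,
    decay_rate: float = 1.0,
    threshold: float = VALIDITY_THRESHOLD,
) -> RankingResult:
    """Score a seed agent against every other agent and rank the valid pairs.

    Sorting is by descending S, ties broken by descending TS then by
    partner id, so rankings are deterministic.  Pairs above the validity
    threshold are reported separately and receive no rank.
    """
    by_id = {a.agent_id: a for a in agents}
    if seed not in by_id:
        raise KeyError(f"seed agent {seed!r} not among the given agents")
    others = [a for a in agents if a.agent_id != seed]
    if not others:
        raise ValueError("need at least one candidate partner")

    seed_agent = by_id[seed]
    results: list[SynergyResult] = []
    for other in others:
        ts = topology_score(net, ip, seed_agent, other, decay_rate=decay_rate)
        if sim is not None:
            as_ = agent_score(seed_agent, other, sim)
        else:
            as_ = AgentScore(seed, other.agent_id, 1.0, 0, {})
        results.append(synergy_score(ts, as_, threshold=threshold))

    def partner_id(r: SynergyResult) -> str:
        return r.agent2 if r.agent1 == seed else r.agent1

    results.sort(key=lambda r: (-r.s, -r.ts, partner_id(r)))
    out = RankingResult(seed=seed)
    for r in results:
        if r.valid:
            out.ranked.append(r)
        else:
            out.invalid.append(r)
    for pos, r in enumerate(out.ranked, start=1):
        r.rank = pos
    return out


def meet_min(g1: Iterable[str], g2: Iterable[str]) -> float:
    """Overlap coefficient |G1 ∩ G2| / min(|G1|, |G2|).

    A network-free gene-set similarity: 1 whenever one set is a subset of
    the other, 0 for disjoint sets.
    """
    s1, s2 = set(g1), set(g2)
    if not s1 or not s2:
        raise ValueError("meet/min requires two non-empty gene sets")
    return len(s1 & s2) / min(len(s1), len(s2))


def go_ui_score(
    genes1: Iterable[str],
    genes2: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
) -> float:
    """Union–Intersection GO similarity of two agents' pooled term sets.

    Each agent's term set is the union of GO terms over its genes; the
    score is |terms1 ∩ terms2| / |terms1 ∪ terms2|, or 0 (with a warning)
    when neither agent has any annotation.
    """
    t1: set[str] = set()
    t2: set[str] = set()
    for g in genes1:
        t1.update(annotations.get(g, ()))
    for g in genes2:
        t2.update(annotations.get(g, ()))
    union = t1 | t2
    if not union:
        warnings.warn("no GO annotations for either gene set; UI score is 0", stacklevel=2)
        return 0.0
    return len(t1 & t2) / len(union)


def correlate_scores(x: list[float], y: list[float]) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
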