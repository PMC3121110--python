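"""Permutation robustness: how stable are synergy rankings under noise?

Perturbs agent gene sets (random vs targeted removal of each agent's most
important genes) and background-network edges, then reports the Spearman
rank correlation (SRCC) between perturbed and original pair rankings.
"""

from nims import (
    PerturbationPlan,
    ScoringContext,
    SyntheticScenario,
    generate_scenario,
    run_robustness,
)

data = generate_scenario(
    SyntheticScenario(n_nodes=300, n_agents=8, genes_per_agent=(8, 20), seed=3)
)
ctx = ScoringContext(data.network, data.agents, sim=data.similarity)

gene_plan = PerturbationPlan("agent_genes_remove", [10, 30], repetitions=10, seed=1)
print("random gene removal:")
print(run_robustness(gene_plan, ctx).to_frame().to_string(index=False))

targeted = ScoringContext(
    data.network, data.agents, sim=data.similarity, gene_strategy="top_ip"
)
print("\ntargeted (highest-IP) gene removal:")
print(run_robustness(gene_plan, targeted).to_frame().to_string(index=False))

edge_plan = PerturbationPlan("edges_remove", [50], repetitions=5, seed=1)
print("\nedge removal:")
print(run_robustness(edge_plan, ctx).to_frame().to_string(index=False))

print(
    "\nSRCC stays near 1 under random gene loss and even 50% edge removal,"
    "\nbut drops faster when each agent's key (highest-IP) genes are removed:"
    "\nthe ranking is carried by a few important genes, as expected on"
    "\nscale-free networks (robust to random deletion, fragile at hubs)."
)
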