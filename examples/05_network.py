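"""Co-occurrence networks and anti-interference robustness.

Builds Spearman networks (|r| > 0.5, p < 0.05) for a community with a
block of mutually dependent taxa and for an independent community, then
compares their natural-connectivity robustness under random node removal.
"""
from enterodyn import network as nw
from enterodyn.synth import simulate_correlated_community

for label, strength in (("dependent-block", 1.5), ("independent", 0.0)):
    counts = simulate_correlated_community(strength=strength, seed=4)
    net = nw.spearman_edges(counts)
    _, summary = nw.degree_stats(net)
    curve = nw.robustness_curve(net, strategy="random", n_reps=50, seed=0)
    print(f"{label}: {summary['n_nodes']} nodes, {summary['n_edges']} edges, "
          f"natural connectivity {nw.natural_connectivity(net):.3f}, "
          f"robustness AUC {curve.auc:.3f}")

print("\nThe community whose taxa co-vary through a shared factor forms a "
      "dense network whose connectivity survives node removal; the "
      "independent community yields few or no significant edges.")
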