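"""Build an RMT-thresholded co-occurrence network from a planted-module table.

Two groups of taxa ride separate latent environmental factors; the
eigenvalue spacing scan finds the correlation cutoff at which the spectrum
turns Poisson-like (noise removed, modules separated), and the resulting
positive-interaction network is exported as GraphML for Gephi.
"""

from collections import Counter

import ecoassembly as ea

scenario = ea.NetworkScenario(n_taxa=80, n_modules=2, rho=0.9, n_samples=150,
                              seed=7)
table = ea.simulate_cooccurrence(scenario)
corr = ea.correlation_matrix(table, transform="none")

s_star, scan = ea.rmt_threshold(corr)
print(f"RMT-selected threshold s* = {s_star:.2f} "
      f"(scanned {len(scan)} grid values)")

network = ea.build_network(corr, s_star, positive_only=True)
print(f"network: {len(network.nodes)} nodes, {network.n_edges} edges")

module_of = dict(zip(table.taxon_ids, scenario.module_of))
within = sum(1 for a, b, _ in network.edges if module_of[a] == module_of[b])
print(f"within-module edge precision: {within / network.n_edges:.3f} "
      "(planted modules recovered)")

degrees = Counter(network.degrees)
print("5 highest-degree taxa (hub candidates):",
      degrees.most_common(5))

ea.write_graphml(network, "cooccurrence.graphml")
print("wrote cooccurrence.graphml (node size by degree in Gephi)")
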