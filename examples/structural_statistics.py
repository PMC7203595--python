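"""Generate synthetic osteon networks and print their structural statistics.

Builds one ordinary osteon and one osteon-in-osteon at the reference
densities (canalicular length density ~0.08 µm/µm³, mean node degree ~3.6)
and prints the six structural parameters of each.  The numbers to watch:
the nested osteon's mean shortest path to the Haversian canal is far longer
than the ordinary osteon's, because its outer network reaches the canal
only through a few bridges across the low-density annular gap.
"""

import osteoflow as of

for label, params in [
    ("ordinary osteon", of.ordinary_params(seed=1)),
    ("osteon-in-osteon", of.osteon_in_osteon_params(seed=1)),
]:
    net = of.generate_osteon(params)
    s = of.structural_summary(net)
    print(f"\n{label} (seed {params.seed}): {net.n_nodes} nodes, {net.n_edges} canaliculi")
    print(f"  node density              {s.node_density:.4f}  1/µm³")
    print(f"  canalicular number density{s.canalicular_number_density:10.4f}  1/µm³")
    print(f"  canalicular length density{s.canalicular_length_density:10.4f}  µm/µm³")
    print(f"  mean node degree          {s.mean_node_degree:.2f}")
    print(f"  mean weighted node degree {s.mean_weighted_node_degree:.1f}  µm")
    print(f"  mean shortest path to canal {s.mean_shortest_path_to_canal:.1f}  µm")
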