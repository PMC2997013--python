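"""Median-joining networks separate recent bursts from old expansions.

A family that expanded very recently condenses to a star: one abundant
central haplotype with many one-step satellites.  An old expansion shows
deeply separated lineages and no dominant hub.  The star statistic is the
fraction of nodes adjacent to the modal haplotype.
"""

from mitekit.evolution import mj_network, star_statistic
from mitekit.simulate import burst_haplotypes, two_epoch_haplotypes

recent = mj_network(burst_haplotypes(n=40, length=200, seed=11))
old = mj_network(two_epoch_haplotypes(n=40, length=200, seed=11))

for name, net in (("recent burst", recent), ("old expansion", old)):
    n_nodes = net.graph.number_of_nodes()
    print(f"{name}: {n_nodes} haplotype nodes, "
          f"{net.graph.number_of_edges()} edges, "
          f"{len(net.median_vectors)} median vectors, "
          f"star statistic {star_statistic(net):.2f}")
print("(star statistic near 1 indicates a single-source recent expansion; "
      "low values indicate old, structured expansion)")
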