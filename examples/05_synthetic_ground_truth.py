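"""Synthetic nets with known answers: the test bed for every pipeline stage.

Planted-cycle nets have minimal t-invariants known by construction;
planted-cluster matrices have a partition that correlation clustering must
recover; random SPNs exercise I/O and simulation with realistic token and
rate regimes.
"""

from spnkit import compute_mct_sets, incidence_matrix, minimal_t_invariants
from spnkit.clustering import cut, pearson_similarity, similarity_to_distance, upgma
from spnkit.synthetic import (
    PlantedNetSpec,
    planted_cluster_invariants,
    planted_cycle_net,
    random_spn,
)

net, expected = planted_cycle_net(PlantedNetSpec((2, 3, 4)))
invs = minimal_t_invariants(incidence_matrix(net), net.transitions)
print(f"planted 3 cycles -> {len(invs)} minimal invariants "
      f"(match: {set(invs.supports) == set(expected.supports)})")

X, labels = planted_cluster_invariants(3, 8, 24, separation=6.0, seed=0)
tree = upgma(similarity_to_distance(pearson_similarity(X)))
cl = cut(tree, 3)
groups = {}
for i, c in enumerate(cl.assignment):
    groups.setdefault(c, set()).add(int(labels[i]))
print(f"planted 3 clusters recovered exactly: {all(len(v) == 1 for v in groups.values())}")

rnet, marking, rates = random_spn(8, 10, seed=42)
print(f"random SPN: {rnet.n_places}p/{rnet.n_transitions}t, "
      f"{len(rnet.arcs)} arcs, total tokens {marking.total()}")
mct = compute_mct_sets(minimal_t_invariants(incidence_matrix(rnet), rnet.transitions))
print(f"its transitions fall into {len(mct)} MCT sets")
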