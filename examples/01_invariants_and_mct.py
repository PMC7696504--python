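"""Minimal t-invariants and MCT sets of the bundled IL-18 model.

Builds the 56-place / 70-transition IL-18 atherosclerosis net, enumerates
its minimal t-invariants (self-contained subprocesses), checks coverage,
and partitions the transitions into maximal common transition (MCT) sets.
"""

from spnkit import compute_mct_sets, coverage, incidence_matrix, minimal_t_invariants
from spnkit.models import build_il18_model

bundle = build_il18_model()
net = bundle.net
print(f"net: {net.n_places} places, {net.n_transitions} transitions, "
      f"{len(net.arcs)} arcs")

invs = minimal_t_invariants(incidence_matrix(net), net.transitions)
covered, uncovered = coverage(net.transitions, invs)
print(f"minimal t-invariants: {len(invs)}   covered: {covered}")

mct = compute_mct_sets(invs)
nontrivial = [m for m in mct if not m.is_trivial]
print(f"non-trivial MCT sets: {len(nontrivial)}")
for i, m in enumerate(nontrivial, 1):
    ts = ",".join(sorted(m.transitions, key=lambda t: int(t[1:])))
    print(f"  m{i}: {ts}")

# Each invariant is a multiset of transition firings returning every place
# to its starting token count; an MCT set groups transitions that always
# fire in exactly the same subprocesses, i.e. one functional unit.
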