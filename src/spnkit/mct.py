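"""Maximal common transition (MCT) sets.

Two transitions belong to the same MCT set iff they occur in the supports of
exactly the same t-invariants.  MCT sets therefore partition the transition
set, and every invariant support is a union of whole MCT sets.  Non-trivial
sets (more than one transition) typically delimit functional subunits of the
modelled system.
"""

from __future__ import annotations

from dataclasses import dataclass

from .invariants import InvariantSet

__all__ = ["MCTSet", "compute_mct_sets"]


@dataclass(frozen=True)
class MCTSet:
    """A maximal group of transitions sharing one invariant-membership signature."""

    transitions: tuple[str, ...]
    signature: frozenset[int]  # indices of invariants containing these transitions

    @property
    def is_trivial(self) -> bool:
        return len(self.transitions) == 1

    def __len__(self) -> int:
        return len(self.transitions)


def compute_mct_sets(invs: InvariantSet, transitions: tuple[str, ...] | None = None) -> list[MCTSet]:
    """Partition transitions by identical t-invariant support membership.

    Transitions occurring in no invariant all share the empty signature but
    are emitted as individual trivial sets, keeping the output a partition
    with meaningful granularity on uncovered nets.

    Output is sorted by descending size, then lexicographically by member
    ids, matching the conventional m1..mk numbering (largest set first).
    """
    if transitions is None:
        transitions = invs.transitions
    if set(transitions) != set(invs.transitions):
        raise ValueError("transition list does not match the invariant set")

    sig: dict[str, set[int]] = {t: set() for t in transitions}
    for i, supp in enumerate(invs.supports):
        for t in supp:
            sig[t].add(i)

    groups: dict[frozenset[int], list[str]] = {}
    singles: list[str] = []
    for t in transitions:
        s = frozenset(sig[t])
        if not s:
            singles.append(t)
            continue
        groups.setdefault(s, []).append(t)

    sets = [MCTSet(tuple(members), signature) for signature, members in groups.items()]
    sets.extend(MCTSet((t,), frozenset()) for t in singles)
    sets.sort(key=lambda m: (-len(m.transitions), m.transitions))
    return sets
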