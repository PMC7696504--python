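import itertools
from math import gcd

import numpy as np
import pytest

from spnkit import Arc, Marking, PetriNet


def brute_force_semiflows(M, max_coeff=3):
    """Exhaustive minimal-semiflow oracle: test every coefficient vector.

    Enumerates all nonnegative integer vectors with entries <= max_coeff,
    keeps exact kernel members, gcd-normalises, and filters to minimal
    supports.  Only valid when the true minimal semiflows have entries
    within the bound; callers use it on tiny nets where that holds.
    """
    M = np.asarray(M, dtype=object)
    n, m = M.shape
    sols = set()
    for v in itertools.product(range(max_coeff + 1), repeat=m):
        if not any(v):
            continue
        if all(sum(M[i][j] * v[j] for j in range(m)) == 0 for i in range(n)):
            g = 0
            for x in v:
                g = gcd(g, x)
            sols.add(tuple(x // g for x in v))
    out = []
    for s in sols:
        supp = frozenset(i for i, x in enumerate(s) if x)
        if not any(
            frozenset(i for i, x in enumerate(o) if x) < supp for o in sols
        ):
            out.append(s)
    return sorted(set(out), key=lambda s: (tuple(i for i, x in enumerate(s) if x), s))


@pytest.fixture
def two_cycle():
    """p0 -> t0 -> p1 -> t1 -> p0 (one token circulating)."""
    net = PetriNet(
        ("p0", "p1"),
        ("t0", "t1"),
        (Arc("p0", "t0"), Arc("t0", "p1"), Arc("p1", "t1"), Arc("t1", "p0")),
    )
    return net, Marking({"p0": 1, "p1": 0})


@pytest.fixture
def chain_net():
    """Source t_in -> p0 -> t0 -> p1 -> t_out (open chain)."""
    net = PetriNet(
        ("p0", "p1"),
        ("t_in", "t0", "t_out"),
        (
            Arc("t_in", "p0"),
            Arc("p0", "t0"),
            Arc("t0", "p1"),
            Arc("p1", "t_out"),
        ),
    )
    return net, Marking({"p0": 0, "p1": 0})


def random_net(rng, n_places=4, n_transitions=4, max_weight=2, p_arc=0.4):
    """Small random bipartite net (possibly disconnected) for property tests."""
    places = tuple(f"p{i}" for i in range(n_places))
    transitions = tuple(f"t{j}" for j in range(n_transitions))
    arcs = []
    for p in places:
        for t in transitions:
            if rng.random() < p_arc / 2:
                arcs.append(Arc(p, t, int(rng.integers(1, max_weight + 1))))
            if rng.random() < p_arc / 2:
                arcs.append(Arc(t, p, int(rng.integers(1, max_weight + 1))))
    if not arcs:
        arcs = [Arc(places[0], transitions[0])]
    return PetriNet(places, transitions, tuple(arcs))
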