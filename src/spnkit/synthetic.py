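"""Synthetic nets and invariant matrices with known-by-construction truth.

Three generators support end-to-end testing of the analysis pipeline
without any hand-transcribed model:

* :func:`planted_cycle_net` — nets made of elementary token cycles whose
  minimal t-invariants are known exactly;
* :func:`random_spn` — reproducible random bipartite nets with markings and
  rates drawn from the value regime typical of signalling models
  (tokens in {0, 10, 100, 1000}, rate constants spanning 1/s to 1/500 s);
* :func:`planted_cluster_invariants` — nonnegative integer vectors with a
  planted partition whose within-cluster Pearson correlation dominates the
  between-cluster correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .invariants import InvariantSet, TInvariant
from .net import Arc, Marking, PetriNet
from .simulate import StochasticRates

__all__ = [
    "PlantedNetSpec",
    "planted_cycle_net",
    "random_spn",
    "planted_cluster_invariants",
]

_TOKEN_LEVELS = (0, 10, 100, 1000)
_RATE_LEVELS = (1.0, 0.025, 0.01, 0.005, 0.002)


@dataclass(frozen=True)
class PlantedNetSpec:
    """Cycle sizes to plant, optional shared places between cycle pairs."""

    cycle_sizes: tuple[int, ...]
    shared_places: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cycle_sizes or any(s < 2 for s in self.cycle_sizes):
            raise ValueError("every planted cycle needs size >= 2")
        k = len(self.cycle_sizes)
        for a, b in self.shared_places:
            if not (0 <= a < k and 0 <= b < k and a != b):
                raise ValueError(f"invalid shared-place pair ({a}, {b})")


def planted_cycle_net(spec: PlantedNetSpec) -> tuple[PetriNet, InvariantSet]:
    """Build a net of planted elementary cycles and its expected invariants.

    Each cycle of size s alternates s places and s transitions
    (p -> t -> p -> ... -> p).  Disjoint cycles give exactly one minimal
    t-invariant per cycle (all coefficients 1 on the cycle's transitions).
    ``shared_places`` glue the first place of one cycle onto another
    cycle's first place; token flow through a shared place still balances
    cycle-by-cycle, so the planted invariants remain exactly the minimal
    ones (verified against the exhaustive oracle in the test suite).
    """
    places: list[str] = []
    transitions: list[str] = []
    arcs: list[Arc] = []
    cycle_places: list[list[str]] = []
    cycle_transitions: list[list[str]] = []
    for ci, size in enumerate(spec.cycle_sizes):
        ps = [f"p{ci}_{i}" for i in range(size)]
        ts = [f"t{ci}_{i}" for i in range(size)]
        cycle_places.append(ps)
        cycle_transitions.append(ts)
        places.extend(ps)
        transitions.extend(ts)
        for i in range(size):
            arcs.append(Arc(ps[i], ts[i]))
            arcs.append(Arc(ts[i], ps[(i + 1) % size]))

    # merge shared places: cycle b's first place becomes cycle a's first place
    alias: dict[str, str] = {}
    for a, b in spec.shared_places:
        alias[cycle_places[b][0]] = cycle_places[a][0]
    if alias:
        def res(x: str) -> str:
            while x in alias:
                x = alias[x]
            return x
        places = [p for p in places if p not in alias]
        merged: dict[tuple[str, str], int] = {}
        for arc in arcs:
            key = (res(arc.source), res(arc.target))
            merged[key] = max(merged.get(key, 0), arc.weight)
        arcs = [Arc(s, t, w) for (s, t), w in merged.items()]

    net = PetriNet(tuple(places), tuple(transitions), tuple(arcs))
    tindex = {t: j for j, t in enumerate(net.transitions)}
    invs = []
    for ts in cycle_transitions:
        coeffs = [0] * len(net.transitions)
        for t in ts:
            coeffs[tindex[t]] = 1
        invs.append(TInvariant(tuple(coeffs)))
    order = sorted(range(len(invs)), key=lambda i: invs[i].support)
    return net, InvariantSet(net.transitions, tuple(invs[i] for i in order))


def random_spn(n_places: int, n_transitions: int, arc_density: float = 0.15,
               weight2_fraction: float = 0.0, seed: int = 0
               ) -> tuple[PetriNet, Marking, StochasticRates]:
    """Reproducible random connected bipartite net with marking and rates.

    A spanning alternating backbone guarantees weak connectivity; extra
    arcs are added with probability ``arc_density`` per (node, node) pair,
    and a ``weight2_fraction`` of all arcs is upgraded to weight 2.
    Markings are drawn from {0, 10, 100, 1000} and rate constants from the
    discrete ladder {1, 1/40, 1/100, 1/200, 1/500} (1/s).
    """
    if n_places < 1 or n_transitions < 1:
        raise ValueError("need at least one place and one transition")
    if not 0 < arc_density <= 1:
        raise ValueError("arc density must be in (0, 1]")
    if not 0 <= weight2_fraction <= 1:
        raise ValueError("weight-2 fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    places = tuple(f"p{i}" for i in range(n_places))
    transitions = tuple(f"t{j}" for j in range(n_transitions))
    arcset: set[tuple[str, str]] = set()
    # backbone: weave all nodes into one alternating walk
    nodes_p = list(places)
    nodes_t = list(transitions)
    rng.shuffle(nodes_p)
    rng.shuffle(nodes_t)
    L = max(len(nodes_p), len(nodes_t))
    for i in range(L):
        p = nodes_p[i % len(nodes_p)]
        t = nodes_t[i % len(nodes_t)]
        arcset.add((p, t))
        t2 = nodes_t[(i + 1) % len(nodes_t)]
        arcset.add((t2, p))
    for p in places:
        for t in transitions:
            if rng.random() < arc_density / 2:
                arcset.add((p, t))
            if rng.random() < arc_density / 2:
                arcset.add((t, p))
    ordered = sorted(arcset)
    weights = np.ones(len(ordered), dtype=int)
    n_w2 = int(round(weight2_fraction * len(ordered)))
    if n_w2:
        weights[rng.choice(len(ordered), size=n_w2, replace=False)] = 2
    arcs = tuple(Arc(s, t, int(w)) for (s, t), w in zip(ordered, weights))
    net = PetriNet(places, transitions, arcs)
    marking = Marking({p: int(rng.choice(_TOKEN_LEVELS)) for p in places})
    rates = StochasticRates({t: float(rng.choice(_RATE_LEVELS)) for t in transitions})
    return net, marking, rates


def planted_cluster_invariants(k_clusters: int, per_cluster: int, length: int,
                               separation: float = 5.0, seed: int = 0,
                               max_tries: int = 50
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Integer vectors with a planted partition recoverable by correlation.

    Each cluster has a disjoint block of coordinates carrying a large
    common pattern; vectors within a cluster share the block up to small
    integer noise of magnitude ``~ amplitude / separation``.  Returns
    ``(vectors, labels)`` with labels 1..k.  Raises after ``max_tries``
    attempts if the requested margin cannot be realised.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if k_clusters < 1 or per_cluster < 1:
        raise ValueError("need at least one cluster and one vector per cluster")
    if length < 2 * k_clusters:
        raise ValueError("length must be at least 2 * k_clusters")
    rng = np.random.default_rng(seed)
    amplitude = 20
    noise = max(1, int(round(amplitude / separation)))
    block = length // k_clusters
    for _ in range(max_tries):
        X = np.zeros((k_clusters * per_cluster, length), dtype=np.int64)
        labels = np.zeros(k_clusters * per_cluster, dtype=np.int64)
        for c in range(k_clusters):
            lo, hi = c * block, (c + 1) * block if c < k_clusters - 1 else length
            base = rng.integers(amplitude // 2, amplitude + 1, size=hi - lo)
            for i in range(per_cluster):
                row = c * per_cluster + i
                labels[row] = c + 1
                X[row, lo:hi] = base + rng.integers(0, noise + 1, size=hi - lo)
        # verify the planted margin on the realised correlations
        from .clustering import pearson_similarity
        if k_clusters == 1 or per_cluster == 1:
            return X, labels
        R = pearson_similarity(X)
        within, between = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                (within if labels[i] == labels[j] else between).append(R[i, j])
        if min(within) > max(between):
            return X, labels
    raise RuntimeError(
        f"could not realise separation {separation} in {max_tries} attempts")
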