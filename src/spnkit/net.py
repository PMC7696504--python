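"""Petri net structure, markings and firing semantics.

A Petri net is a weighted directed bipartite graph: *places* (passive
components, holding nonnegative integer token counts) and *transitions*
(active components).  An arc always connects a place to a transition or a
transition to a place, never two nodes of the same kind.  A transition is
enabled when every pre-place holds at least the connecting arc's weight in
tokens; firing consumes tokens from pre-places and produces tokens in
post-places according to the arc weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Arc",
    "PetriNet",
    "Marking",
    "StructuralReport",
    "incidence_matrix",
    "is_enabled",
    "fire",
    "structural_report",
]


class NetValidationError(ValueError):
    """The net (or an argument referring to it) violates a structural rule."""


class UnknownIdError(KeyError):
    """A place or transition identifier does not exist in the net."""


class FiringError(RuntimeError):
    """Attempt to fire a transition that is not enabled."""


@dataclass(frozen=True, order=True)
class Arc:
    """A weighted arc from ``source`` to ``target`` (one place, one transition)."""

    source: str
    target: str
    weight: int = 1


@dataclass(frozen=True)
class PetriNet:
    """Immutable Petri net structure ``(P, T, F, W)``.

    Parameters
    ----------
    places, transitions
        Ordered identifier lists; order fixes row/column order of the
        incidence matrix and of every downstream report.
    arcs
        Arc records; at most one arc per (source, target) pair.
    labels
        Optional map from identifier to a human-readable name.
    """

    places: tuple[str, ...]
    transitions: tuple[str, ...]
    arcs: tuple[Arc, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pset, tset = set(self.places), set(self.transitions)
        if len(pset) != len(self.places) or len(tset) != len(self.transitions):
            raise NetValidationError("duplicate place or transition identifiers")
        if pset & tset:
            raise NetValidationError(f"ids used as both place and transition: {sorted(pset & tset)}")
        if not (pset | tset):
            raise NetValidationError("net must contain at least one node")
        seen: set[tuple[str, str]] = set()
        for a in self.arcs:
            if a.weight < 1:
                raise NetValidationError(f"arc {a.source}->{a.target} has weight {a.weight} < 1")
            p2t = a.source in pset and a.target in tset
            t2p = a.source in tset and a.target in pset
            if not (p2t or t2p):
                raise NetValidationError(f"arc {a.source}->{a.target} is not bipartite")
            key = (a.source, a.target)
            if key in seen:
                raise NetValidationError(f"duplicate arc {a.source}->{a.target}")
            seen.add(key)
        # Pre-computed adjacency, keyed by transition / place id.
        pre_t: dict[str, dict[str, int]] = {t: {} for t in self.transitions}
        post_t: dict[str, dict[str, int]] = {t: {} for t in self.transitions}
        pre_p: dict[str, dict[str, int]] = {p: {} for p in self.places}
        post_p: dict[str, dict[str, int]] = {p: {} for p in self.places}
        for a in self.arcs:
            if a.source in pset:  # place -> transition
                pre_t[a.target][a.source] = a.weight
                post_p[a.source][a.target] = a.weight
            else:  # transition -> place
                post_t[a.source][a.target] = a.weight
                pre_p[a.target][a.source] = a.weight
        object.__setattr__(self, "_pre_t", pre_t)
        object.__setattr__(self, "_post_t", post_t)
        object.__setattr__(self, "_pre_p", pre_p)
        object.__setattr__(self, "_post_p", post_p)

    # -- adjacency queries -------------------------------------------------
    def pre(self, t: str) -> dict[str, int]:
        """Pre-places of transition ``t`` with arc weights."""
        self._check_transition(t)
        return dict(self._pre_t[t])

    def post(self, t: str) -> dict[str, int]:
        """Post-places of transition ``t`` with arc weights."""
        self._check_transition(t)
        return dict(self._post_t[t])

    def producers(self, p: str) -> dict[str, int]:
        """Transitions with an arc into place ``p``."""
        self._check_place(p)
        return dict(self._pre_p[p])

    def consumers(self, p: str) -> dict[str, int]:
        """Transitions with an arc out of place ``p``."""
        self._check_place(p)
        return dict(self._post_p[p])

    def _check_transition(self, t: str) -> None:
        if t not in self._pre_t:
            raise UnknownIdError(f"unknown transition {t!r}")

    def _check_place(self, p: str) -> None:
        if p not in self._pre_p:
            raise UnknownIdError(f"unknown place {p!r}")

    @property
    def n_places(self) -> int:
        return len(self.places)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def label(self, node: str) -> str:
        return self.labels.get(node, node)


@dataclass(frozen=True)
class Marking:
    """Immutable token assignment, defined for every place of its net."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {p: c for p, c in self.counts.items() if c < 0}
        if bad:
            raise NetValidationError(f"negative token counts: {bad}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, place: str) -> int:
        return self.counts[place]

    def vector(self, places: Iterable[str]) -> np.ndarray:
        return np.array([self.counts[p] for p in places], dtype=np.int64)

    def total(self) -> int:
        return sum(self.counts.values())

    @staticmethod
    def for_net(net: PetriNet, counts: Mapping[str, int] | None = None) -> "Marking":
        full = {p: 0 for p in net.places}
        if counts:
            unknown = set(counts) - set(net.places)
            if unknown:
                raise UnknownIdError(f"marking refers to unknown places {sorted(unknown)}")
            full.update(counts)
        return Marking(full)


def incidence_matrix(net: PetriNet) -> np.ndarray:
    """Incidence matrix A, shape (|P|, |T|), exact integer entries.

    ``A[i, j]`` is the net token change in place ``i`` when transition ``j``
    fires: (weight of the t->p arc, or 0) minus (weight of the p->t arc, or 0).
    """
    pidx = {p: i for i, p in enumerate(net.places)}
    A = np.zeros((net.n_places, net.n_transitions), dtype=np.int64)
    for j, t in enumerate(net.transitions):
        for p, w in net._pre_t[t].items():
            A[pidx[p], j] -= w
        for p, w in net._post_t[t].items():
            A[pidx[p], j] += w
    return A


def is_enabled(net: PetriNet, m: Marking, t: str) -> bool:
    """True iff every pre-place of ``t`` holds at least the arc weight in tokens.

    An input transition (empty pre-set) is always enabled.
    """
    net._check_transition(t)
    return all(m.counts[p] >= w for p, w in net._pre_t[t].items())


def fire(net: PetriNet, m: Marking, t: str) -> Marking:
    """Fire enabled transition ``t``, returning the successor marking."""
    if not is_enabled(net, m, t):
        raise FiringError(f"transition {t!r} is not enabled")
    counts = dict(m.counts)
    for p, w in net._pre_t[t].items():
        counts[p] -= w
    for p, w in net._post_t[t].items():
        counts[p] = counts.get(p, 0) + w
    return Marking(counts)


@dataclass(frozen=True)
class StructuralReport:
    """Static properties of the net's bipartite graph."""

    is_pure: bool
    is_ordinary: bool
    weighted_arc_count: int
    is_connected: bool
    is_strongly_connected: bool
    is_structurally_conflict_free: bool
    input_transitions: tuple[str, ...]
    output_transitions: tuple[str, ...]
    input_places: tuple[str, ...]
    output_places: tuple[str, ...]


def structural_report(net: PetriNet) -> StructuralReport:
    """Compute the standard static classification of a Petri net.

    *Pure*: no place is both pre- and post-place of the same transition (no
    read arcs / self-loops).  *Ordinary*: all arc weights are 1.
    *Structurally conflict-free*: no two transitions share a pre-place.
    Input/output nodes have empty pre-/post-sets respectively.
    """
    is_pure = all(
        not (set(net._pre_t[t]) & set(net._post_t[t])) for t in net.transitions
    )
    weighted = sum(1 for a in net.arcs if a.weight > 1)
    g = nx.DiGraph()
    g.add_nodes_from(net.places)
    g.add_nodes_from(net.transitions)
    g.add_edges_from((a.source, a.target) for a in net.arcs)
    conflict_free = all(len(net._post_p[p]) <= 1 for p in net.places)
    return StructuralReport(
        is_pure=is_pure,
        is_ordinary=weighted == 0,
        weighted_arc_count=weighted,
        is_connected=nx.is_weakly_connected(g),
        is_strongly_connected=nx.is_strongly_connected(g),
        is_structurally_conflict_free=conflict_free,
        input_transitions=tuple(t for t in net.transitions if not net._pre_t[t]),
        output_transitions=tuple(t for t in net.transitions if not net._post_t[t]),
        input_places=tuple(p for p in net.places if not net._pre_p[p]),
        output_places=tuple(p for p in net.places if not net._post_p[p]),
    )
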