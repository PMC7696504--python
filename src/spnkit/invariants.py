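"""Minimal t- and p-invariant enumeration.

A t-invariant of a net with incidence matrix ``A`` (places x transitions) is
a nonnegative integer vector ``x`` with ``A @ x == 0``: a multiset of
transition firings that returns every place to its starting token count — a
self-contained subprocess.  A p-invariant is the transposed notion,
``A.T @ y == 0``: a weighted token sum conserved by every firing.

Enumeration uses the classical Fourier–Motzkin / Farkas tableau: append an
identity to the transposed matrix and eliminate one place (column) at a time
by forming all positive combinations of rows with opposite signs, pruning
non-minimal-support rows after every step.  All arithmetic is on exact
Python integers; coefficients are gcd-normalised.  The method is worst-case
exponential, so a configurable cap aborts pathological intermediate growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from typing import Sequence

import numpy as np

__all__ = [
    "TInvariant",
    "InvariantSet",
    "minimal_t_invariants",
    "minimal_p_invariants",
    "minimal_semiflows",
    "coverage",
    "EnumerationSizeError",
]


class EnumerationSizeError(RuntimeError):
    """Intermediate tableau exceeded the configured row cap."""


@dataclass(frozen=True)
class TInvariant:
    """A gcd-normalised nonnegative integer kernel vector (one invariant)."""

    coefficients: tuple[int, ...]

    def __post_init__(self) -> None:
        if not any(self.coefficients):
            raise ValueError("invariant must have at least one positive entry")
        if any(c < 0 for c in self.coefficients):
            raise ValueError("invariant coefficients must be nonnegative")

    @property
    def support(self) -> tuple[int, ...]:
        """Indices with positive coefficient, ascending."""
        return tuple(i for i, c in enumerate(self.coefficients) if c)


# p-invariants share structure and canonical form with t-invariants.
PInvariant = TInvariant


@dataclass(frozen=True)
class InvariantSet:
    """Complete set of minimal invariants, in canonical (support-lex) order."""

    transitions: tuple[str, ...]
    invariants: tuple[TInvariant, ...]

    @property
    def supports(self) -> tuple[frozenset[str], ...]:
        return tuple(
            frozenset(self.transitions[i] for i in inv.support)
            for inv in self.invariants
        )

    def support_indices(self) -> tuple[tuple[int, ...], ...]:
        return tuple(inv.support for inv in self.invariants)

    def matrix(self) -> np.ndarray:
        """Invariants as rows of an integer matrix (k x m)."""
        return np.array([inv.coefficients for inv in self.invariants], dtype=np.int64)

    def containing(self, transition: str) -> tuple[int, ...]:
        """Indices of invariants whose support contains ``transition``."""
        j = self.transitions.index(transition)
        return tuple(i for i, inv in enumerate(self.invariants) if inv.coefficients[j])

    def __len__(self) -> int:
        return len(self.invariants)

    def __iter__(self):
        return iter(self.invariants)


def _normalise(row: list[int]) -> tuple[int, ...]:
    g = 0
    for v in row:
        g = gcd(g, v)
    if g > 1:
        return tuple(v // g for v in row)
    return tuple(row)


def _prune_minimal(rows: list[tuple[tuple[int, ...], tuple[int, ...]]]):
    """Drop rows whose invariant-part support strictly contains another's.

    Rows are (vector, support) pairs; duplicates (same vector) collapse.
    Sorting by support size lets a single forward scan find all strict
    superset relations.
    """
    uniq: dict[tuple[int, ...], tuple[int, ...]] = {}
    for vec, supp in rows:
        uniq[vec] = supp
    items = sorted(uniq.items(), key=lambda kv: len(kv[1]))
    kept: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    kept_sets: list[frozenset[int]] = []
    for vec, supp in items:
        s = frozenset(supp)
        # strict-superset pruning only: equal supports with distinct vectors
        # may both still be needed in later elimination steps
        if any(k < s for k in kept_sets):
            continue
        kept.append((vec, supp))
        kept_sets.append(s)
    return kept


def minimal_semiflows(matrix: Sequence[Sequence[int]], *, max_rows: int = 10**6) -> list[tuple[int, ...]]:
    """Minimal-support nonnegative integer solutions of ``matrix @ x == 0``.

    Parameters
    ----------
    matrix
        Integer matrix with ``len(x) == n_columns``.
    max_rows
        Abort with :class:`EnumerationSizeError` if an elimination step
        would produce more than this many tableau rows.

    Returns
    -------
    list of gcd-normalised coefficient tuples, sorted lexicographically by
    support (as ascending index tuples), then by coefficients.
    """
    M = [[int(v) for v in row] for row in matrix]
    n_rows = len(M)
    n_cols = len(M[0]) if n_rows else 0
    if n_cols == 0:
        return []
    # Tableau rows: one per column j of M -> (column j of M, unit vector e_j).
    rows: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    for j in range(n_cols):
        left = [M[i][j] for i in range(n_rows)]
        right = [0] * n_cols
        right[j] = 1
        vec = _normalise(left + right)
        rows.append((vec, (j,)))

    for col in range(n_rows):
        pos = [r for r in rows if r[0][col] > 0]
        neg = [r for r in rows if r[0][col] < 0]
        zero = [r for r in rows if r[0][col] == 0]
        if len(zero) + len(pos) * len(neg) > max_rows:
            raise EnumerationSizeError(
                f"elimination of row {col} would produce up to "
                f"{len(zero) + len(pos) * len(neg)} tableau rows (cap {max_rows})"
            )
        new_rows = list(zero)
        for pvec, _ in pos:
            a = pvec[col]
            for nvec, _ in neg:
                b = -nvec[col]
                combo = [b * x + a * y for x, y in zip(pvec, nvec)]
                vec = _normalise(combo)
                supp = tuple(
                    i for i in range(n_cols) if vec[n_rows + i]
                )
                new_rows.append((vec, supp))
        rows = _prune_minimal(new_rows)

    out = set()
    for vec, supp in rows:
        coeffs = _normalise(list(vec[n_rows:]))
        if any(coeffs):
            out.add((supp, coeffs))
    return [coeffs for _, coeffs in sorted(out)]


def minimal_t_invariants(A: np.ndarray, transitions: Sequence[str] | None = None,
                         *, max_rows: int = 10**6) -> InvariantSet:
    """All minimal t-invariants of incidence matrix ``A`` (places x transitions)."""
    A = np.asarray(A)
    if transitions is None:
        transitions = tuple(f"t{j}" for j in range(A.shape[1]))
    if len(transitions) != A.shape[1]:
        raise ValueError("transition list length must match the column count")
    flows = minimal_semiflows(A.tolist(), max_rows=max_rows)
    return InvariantSet(tuple(transitions), tuple(TInvariant(f) for f in flows))


def minimal_p_invariants(A: np.ndarray, places: Sequence[str] | None = None,
                         *, max_rows: int = 10**6) -> InvariantSet:
    """All minimal p-invariants: minimal semiflows of the transposed matrix."""
    A = np.asarray(A)
    if places is None:
        places = tuple(f"p{i}" for i in range(A.shape[0]))
    if len(places) != A.shape[0]:
        raise ValueError("place list length must match the row count")
    flows = minimal_semiflows(A.T.tolist(), max_rows=max_rows)
    return InvariantSet(tuple(places), tuple(TInvariant(f) for f in flows))


def coverage(transitions: Sequence[str], invs: InvariantSet) -> tuple[bool, frozenset[str]]:
    """Whether every transition lies in the support of some invariant.

    Returns ``(covered, uncovered_ids)``.
    """
    if tuple(transitions) != invs.transitions:
        if set(transitions) != set(invs.transitions):
            raise ValueError("transition list does not match the invariant set")
    in_support: set[str] = set()
    for supp in invs.supports:
        in_support.update(supp)
    uncovered = frozenset(t for t in transitions if t not in in_support)
    return (not uncovered, uncovered)
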