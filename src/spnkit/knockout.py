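"""t-invariant-based knockout analysis.

Knocking out a set of transitions discards every minimal t-invariant whose
support meets the set; the surviving invariants describe the subprocesses
the system can still complete.  Transitions left in no surviving support
are *dependent-disabled*: structurally silenced although not themselves
removed.  Impact is summarised as the percentage of invariants lost and
the percentage of transitions affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .invariants import InvariantSet
from .net import PetriNet, UnknownIdError

__all__ = [
    "KnockoutSpec",
    "KnockoutResult",
    "invariant_knockout",
    "place_knockout_spec",
    "impact_table",
]


def _round2(x: float) -> float:
    """Two-decimal half-up rounding (report formatting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class KnockoutSpec:
    """Transitions to remove, with a free-text provenance label."""

    knocked: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.knocked:
            raise ValueError("knockout spec must name at least one transition")

    def validate(self, net: PetriNet) -> None:
        unknown = self.knocked - set(net.transitions)
        if unknown:
            raise UnknownIdError(f"unknown transitions in knockout spec: {sorted(unknown)}")


@dataclass(frozen=True)
class KnockoutResult:
    """Outcome of a t-invariant-based knockout."""

    spec: KnockoutSpec
    remaining: InvariantSet
    removed_count: int
    uncovered: frozenset[str]      # transitions in no remaining support
    dependent: frozenset[str]      # uncovered minus the knocked set itself
    covered: bool
    counts_for: dict = field(default_factory=dict, compare=False)

    @property
    def total(self) -> int:
        return self.removed_count + len(self.remaining)

    @property
    def impact_invariants_pct(self) -> float:
        """Percentage of invariants destroyed by the knockout."""
        return _round2(100.0 * self.removed_count / self.total) if self.total else 0.0

    @property
    def impact_transitions_pct(self) -> float:
        """Percentage of all transitions left uncovered (knocked included)."""
        m = len(self.remaining.transitions)
        return _round2(100.0 * len(self.uncovered) / m) if m else 0.0

    @property
    def impact_transitions_dependent_pct(self) -> float:
        """Variant excluding the knocked transitions themselves."""
        m = len(self.remaining.transitions)
        return _round2(100.0 * len(self.dependent) / m) if m else 0.0


def invariant_knockout(invs: InvariantSet, spec: KnockoutSpec,
                       net: PetriNet | None = None,
                       *, track: tuple[str, ...] = ()) -> KnockoutResult:
    """Remove invariants whose support meets ``spec.knocked``.

    Parameters
    ----------
    invs
        Full minimal t-invariant set of the intact net.
    spec
        Transitions to knock out (validated against ``net`` when given).
    track
        Optional transition ids for which per-transition survival counts
        ``{t: (surviving, original)}`` are reported.
    """
    if net is not None:
        spec.validate(net)
    else:
        unknown = spec.knocked - set(invs.transitions)
        if unknown:
            raise UnknownIdError(f"unknown transitions in knockout spec: {sorted(unknown)}")

    keep = [
        inv for inv, supp in zip(invs.invariants, invs.supports)
        if not (supp & spec.knocked)
    ]
    remaining = InvariantSet(invs.transitions, tuple(keep))
    covered_ids: set[str] = set()
    for supp in remaining.supports:
        covered_ids.update(supp)
    uncovered = frozenset(t for t in invs.transitions if t not in covered_ids)
    counts_for = {
        t: (len(remaining.containing(t)), len(invs.containing(t))) for t in track
    }
    return KnockoutResult(
        spec=spec,
        remaining=remaining,
        removed_count=len(invs) - len(remaining),
        uncovered=uncovered,
        dependent=uncovered - spec.knocked,
        covered=not uncovered,
        counts_for=counts_for,
    )


def place_knockout_spec(net: PetriNet, place: str, label: str | None = None) -> KnockoutSpec:
    """Knockout spec that stops all token production into ``place``.

    The knocked set is the place's producer transitions; a place with no
    producers cannot be silenced this way and raises ``ValueError``.
    """
    producers = sorted(net.producers(place))
    if not producers:
        raise ValueError(f"place {place!r} has no producer transitions")
    return KnockoutSpec(frozenset(producers), label or f"producers of {place}")


def impact_table(invs: InvariantSet, net: PetriNet,
                 targets: list[KnockoutSpec]) -> pd.DataFrame:
    """Ranked knockout impact table, one row per target.

    Sorted by descending transition impact, then invariant impact.  Both
    transition-impact conventions are reported: ``impact_transitions_pct``
    counts every uncovered transition, ``impact_transitions_dependent_pct``
    excludes the knocked set itself.
    """
    rows = []
    for spec in targets:
        res = invariant_knockout(invs, spec, net)
        rows.append({
            "target": ",".join(sorted(spec.knocked)),
            "label": spec.label,
            "impact_transitions_pct": res.impact_transitions_pct,
            "impact_transitions_dependent_pct": res.impact_transitions_dependent_pct,
            "impact_invariants_pct": res.impact_invariants_pct,
            "remaining": len(res.remaining),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["impact_transitions_pct", "impact_invariants_pct"],
        ascending=False, kind="mergesort",
    ).reset_index(drop=True)
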