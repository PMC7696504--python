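"""The IL-18 / atherosclerosis stochastic Petri net model.

A 56-place, 70-transition mass-action SPN describing the involvement of
interleukin 18 in atherosclerotic plaque formation: classical macrophage
activation, pro-IL-18 processing by caspase 1, IL-18 receptor signalling
through MyD88 to NF-kB, the LPS/TLR4 route, JAK/STAT signalling by IFN-g,
TNF and TNFR1 signalling, apoptosis via caspases 8/3, oxidative-stress
driven foam-cell formation, and their clinical endpoints.

The place/transition catalogue, initial marking and rate constants are
printed model data; the arc structure is a reconstruction from the model's
published structural and invariant properties (see the bundled JSON and
the package methods note), validated claim-by-claim by
:func:`validate_recorded_claims`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

from ..clustering import cut, pearson_similarity, similarity_to_distance, upgma
from ..invariants import InvariantSet, coverage, minimal_t_invariants
from ..io import read_model
from ..knockout import KnockoutSpec, invariant_knockout, place_knockout_spec
from ..mct import compute_mct_sets
from ..net import Marking, PetriNet, incidence_matrix, structural_report
from ..simulate import StochasticRates

__all__ = ["ModelBundle", "build_il18_model", "validate_recorded_claims", "Check"]


class ModelBuildError(RuntimeError):
    """The bundled model data failed an internal consistency check."""


@dataclass(frozen=True)
class ModelBundle:
    """The IL-18 model with marking, rates and derived metadata."""

    net: PetriNet
    initial_marking: Marking
    rates: StochasticRates
    durations: Mapping[str, float]  # per-transition time-scale (1 / rate constant)

    def incidence(self):
        return incidence_matrix(self.net)


_EXPECTED_RATE_SET = {1.0, 0.025, 0.01, 0.005, 0.002}
_EXPECTED_TOKEN_SET = {0, 10, 100, 1000}


def _data_path(name: str):
    return resources.files("spnkit.models").joinpath("data", name)


def build_il18_model() -> ModelBundle:
    """Load and verify the bundled IL-18 model.

    Raises :class:`ModelBuildError` listing every violated internal check
    (node counts, rate-constant value set, marking value set).
    """
    with resources.as_file(_data_path("il18.json")) as p:
        net, marking, rates = read_model(p, format="json")
    problems = []
    if net.n_places != 56:
        problems.append(f"expected 56 places, found {net.n_places}")
    if net.n_transitions != 70:
        problems.append(f"expected 70 transitions, found {net.n_transitions}")
    if rates is None:
        problems.append("model file carries no rate constants")
    else:
        bad = set(rates.rate_constants.values()) - _EXPECTED_RATE_SET
        if bad:
            problems.append(f"rate constants outside the model's value ladder: {sorted(bad)}")
    bad_tokens = set(marking.counts.values()) - _EXPECTED_TOKEN_SET
    if bad_tokens:
        problems.append(f"marking values outside {{0,10,100,1000}}: {sorted(bad_tokens)}")
    if problems:
        raise ModelBuildError("; ".join(problems))
    durations = {t: 1.0 / c if c else float("inf")
                 for t, c in rates.rate_constants.items()}
    return ModelBundle(net, marking, rates, durations)


@dataclass(frozen=True)
class Check:
    """One validated claim: expected vs observed."""

    name: str
    expected: object
    observed: object

    @property
    def passed(self) -> bool:
        return self.expected == self.observed


def _knockout_numbers(invs: InvariantSet, net: PetriNet, knocked, track=("t11", "t28")):
    res = invariant_knockout(invs, KnockoutSpec(frozenset(knocked)), net, track=track)
    return res


def validate_recorded_claims(bundle: ModelBundle | None = None) -> list[Check]:
    """Recompute every recorded headline claim about the model.

    Runs the full structural pipeline (structural report, minimal
    t-invariants, MCT sets, t-clusters, knockout battery) and compares each
    quantity with the value recorded in the bundled claims file.  Returns
    one :class:`Check` per claim; failures are entries, not exceptions, so
    a transcription error is pinpointed rather than fatal.
    """
    if bundle is None:
        bundle = build_il18_model()
    with resources.as_file(_data_path("il18_claims.yaml")) as p:
        claims = yaml.safe_load(p.read_text())

    checks: list[Check] = []
    net = bundle.net
    rep = structural_report(net)
    weight2 = sum(1 for a in net.arcs if a.weight == 2)
    for name, observed in [
        ("n_places", net.n_places),
        ("n_transitions", net.n_transitions),
        ("weight2_arcs", weight2),
        ("is_pure", rep.is_pure),
        ("is_ordinary", rep.is_ordinary),
        ("is_connected", rep.is_connected),
        ("is_strongly_connected", rep.is_strongly_connected),
        ("is_structurally_conflict_free", rep.is_structurally_conflict_free),
        ("has_input_places", bool(rep.input_places)),
        ("has_output_places", bool(rep.output_places)),
        ("has_input_transitions", bool(rep.input_transitions)),
        ("has_output_transitions", bool(rep.output_transitions)),
    ]:
        if name in claims:
            checks.append(Check(name, claims[name], observed))

    invs = minimal_t_invariants(bundle.incidence(), net.transitions)
    covered, _ = coverage(net.transitions, invs)
    checks.append(Check("n_t_invariants", claims["n_t_invariants"], len(invs)))
    checks.append(Check("covered_by_t_invariants", claims["covered_by_t_invariants"], covered))

    mct = compute_mct_sets(invs)
    nontrivial = [sorted(m.transitions, key=lambda t: int(t[1:])) for m in mct if not m.is_trivial]
    checks.append(Check("n_nontrivial_mct_sets", claims["n_nontrivial_mct_sets"], len(nontrivial)))
    expected_mct = [sorted(s, key=lambda t: int(t[1:])) for s in claims["nontrivial_mct_sets"]]
    for s in expected_mct:
        checks.append(Check(f"mct_set_{'_'.join(s[:2])}", True,
                            s in nontrivial))

    for t, expected in claims["invariants_containing"].items():
        checks.append(Check(f"invariants_containing_{t}", expected,
                            len(invs.containing(t))))
    both = set(invs.containing("t11")) & set(invs.containing("t28"))
    checks.append(Check("invariants_containing_both_t11_t28",
                        claims["invariants_containing_both_t11_t28"], len(both)))

    for sc in claims["knockouts"]:
        knocked = sc["knock"]
        res = _knockout_numbers(invs, net, knocked)
        tag = "+".join(knocked)
        checks.append(Check(f"knockout_{tag}_remaining", sc["remaining"], len(res.remaining)))
        if "covered" in sc:
            checks.append(Check(f"knockout_{tag}_covered", sc["covered"], res.covered))
        if "t11_remaining" in sc:
            checks.append(Check(f"knockout_{tag}_t11", sc["t11_remaining"],
                                res.counts_for["t11"][0]))
        if "t28_remaining" in sc:
            checks.append(Check(f"knockout_{tag}_t28", sc["t28_remaining"],
                                res.counts_for["t28"][0]))

    if "p3_producer_knockout_remaining" in claims:
        spec = place_knockout_spec(net, "p3")
        res = invariant_knockout(invs, spec, net)
        checks.append(Check("p3_producer_knockout_remaining",
                            claims["p3_producer_knockout_remaining"], len(res.remaining)))

    if "cluster_sizes_k6" in claims and len(invs) >= 6:
        X = invs.matrix()
        tree = upgma(similarity_to_distance(pearson_similarity(X)))
        sizes = sorted(cut(tree, 6).sizes(), reverse=True)
        checks.append(Check("cluster_sizes_k6", sorted(claims["cluster_sizes_k6"], reverse=True),
                            sizes))
    return checks
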