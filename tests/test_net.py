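import numpy as np
import pytest

from spnkit import (
    Arc,
    Marking,
    PetriNet,
    fire,
    incidence_matrix,
    is_enabled,
    structural_report,
)
from spnkit.net import FiringError, NetValidationError, UnknownIdError

from conftest import random_net


class TestStructureValidation:
    def test_rejects_place_place_arc(self):
        with pytest.raises(NetValidationError, match="bipartite"):
            PetriNet(("p0", "p1"), ("t0",), (Arc("p0", "p1"),))

    def test_rejects_duplicate_arc_and_zero_weight(self):
        with pytest.raises(NetValidationError, match="duplicate"):
            PetriNet(("p0",), ("t0",), (Arc("p0", "t0"), Arc("p0", "t0", 2)))
        with pytest.raises(NetValidationError, match="weight"):
            PetriNet(("p0",), ("t0",), (Arc("p0", "t0", 0),))

    def test_rejects_overlapping_ids(self):
        with pytest.raises(NetValidationError):
            PetriNet(("x",), ("x",), ())

    def test_marking_rejects_negative(self):
        with pytest.raises(NetValidationError):
            Marking({"p0": -1})


class TestIncidence:
    def test_chain_column(self, chain_net):
        net, _ = chain_net
        A = incidence_matrix(net)
        j = net.transitions.index("t0")
        assert A[net.places.index("p0"), j] == -1
        assert A[net.places.index("p1"), j] == 1

    def test_weighted_entry(self):
        net = PetriNet(("p0",), ("t0",), (Arc("p0", "t0", 2),))
        assert incidence_matrix(net)[0, 0] == -2

    def test_shape(self, two_cycle):
        net, _ = two_cycle
        assert incidence_matrix(net).shape == (2, 2)


class TestFiring:
    def test_enabled_by_weight(self):
        net = PetriNet(("p0",), ("t0",), (Arc("p0", "t0", 2),))
        assert is_enabled(net, Marking({"p0": 3}), "t0")
        assert not is_enabled(net, Marking({"p0": 1}), "t0")

    def test_input_transition_always_enabled(self, chain_net):
        net, m = chain_net
        assert is_enabled(net, m, "t_in")

    def test_fire_moves_tokens_and_is_pure_functional(self, two_cycle):
        net, m = two_cycle
        m2 = fire(net, m, "t0")
        assert (m2["p0"], m2["p1"]) == (0, 1)
        assert (m["p0"], m["p1"]) == (1, 0)  # original untouched

    def test_fire_disabled_raises(self, two_cycle):
        net, m = two_cycle
        with pytest.raises(FiringError):
            fire(net, m, "t1")

    def test_unknown_transition(self, two_cycle):
        net, m = two_cycle
        with pytest.raises(UnknownIdError):
            is_enabled(net, m, "t99")

    def test_output_transition_sinks_tokens(self):
        net = PetriNet(("p0",), ("t0",), (Arc("p0", "t0"),))
        m2 = fire(net, Marking({"p0": 1}), "t0")
        assert m2.total() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_fire_equals_incidence_column_on_pure_nets(self, seed):
        """For pure nets, m' - m equals the fired transition's column of A."""
        rng = np.random.default_rng(seed)
        net = random_net(rng)
        rep = structural_report(net)
        if not rep.is_pure:
            pytest.skip("random net not pure")
        A = incidence_matrix(net)
        m = Marking({p: 5 for p in net.places})
        for j, t in enumerate(net.transitions):
            if is_enabled(net, m, t):
                m2 = fire(net, m, t)
                delta = m2.vector(net.places) - m.vector(net.places)
                assert np.array_equal(delta, A[:, j])

    @pytest.mark.parametrize("seed", range(5))
    def test_tokens_never_negative_along_random_walks(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_net(rng)
        m = Marking({p: int(rng.integers(0, 4)) for p in net.places})
        for _ in range(50):
            enabled = [t for t in net.transitions if is_enabled(net, m, t)]
            if not enabled:
                break
            m = fire(net, m, enabled[int(rng.integers(len(enabled)))])
            assert all(c >= 0 for c in m.counts.values())


class TestStructuralReport:
    def test_isolated_transition_net(self):
        net = PetriNet((), ("t0",), ())
        rep = structural_report(net)
        assert rep.is_pure and rep.is_ordinary and rep.is_connected

    def test_impure_detection(self):
        net = PetriNet(("p0",), ("t0",), (Arc("p0", "t0"), Arc("t0", "p0")))
        assert not structural_report(net).is_pure

    def test_conflict_detection(self):
        net = PetriNet(
            ("p0",), ("t0", "t1"), (Arc("p0", "t0"), Arc("p0", "t1"))
        )
        rep = structural_report(net)
        assert not rep.is_structurally_conflict_free

    def test_weighted_arc_count_and_ordinary_consistency(self):
        net = PetriNet(("p0", "p1"), ("t0",), (Arc("p0", "t0", 2), Arc("t0", "p1")))
        rep = structural_report(net)
        assert rep.weighted_arc_count == 1
        assert not rep.is_ordinary

    def test_input_output_classification(self, chain_net):
        net, _ = chain_net
        rep = structural_report(net)
        assert rep.input_transitions == ("t_in",)
        assert rep.output_transitions == ("t_out",)
        assert rep.input_places == () and rep.output_places == ()
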