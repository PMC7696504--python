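import numpy as np
import pytest

from spnkit import (
    Arc,
    KnockoutSpec,
    Marking,
    PetriNet,
    StochasticRates,
    apply_knockout,
    gillespie_run,
    hazard,
    run_ensemble,
)
from spnkit.net import UnknownIdError


@pytest.fixture
def birth_net():
    """Poisson source: t_in -> p at rate c (mean c*t tokens at time t)."""
    net = PetriNet(("p",), ("t_in",), (Arc("t_in", "p"),))
    return net, Marking({"p": 0}), StochasticRates({"t_in": 2.0})


@pytest.fixture
def decay_net():
    """Linear death process: p -> sink at per-capita rate c."""
    net = PetriNet(("p",), ("t_out",), (Arc("p", "t_out"),))
    return net, Marking({"p": 100}), StochasticRates({"t_out": 0.5})


class TestHazard:
    def test_linear_mass_action(self):
        net = PetriNet(("p",), ("t",), (Arc("p", "t"),))
        a = hazard(net, StochasticRates({"t": 0.005}), Marking({"p": 100}), "t")
        assert a == pytest.approx(0.5)

    def test_empty_preplace_gives_zero(self):
        net = PetriNet(("p",), ("t",), (Arc("p", "t"),))
        assert hazard(net, StochasticRates({"t": 1.0}), Marking({"p": 0}), "t") == 0.0

    def test_weight_two_combinatorial(self):
        net = PetriNet(("p",), ("t",), (Arc("p", "t", 2),))
        a = hazard(net, StochasticRates({"t": 1.0}), Marking({"p": 4}), "t")
        assert a == pytest.approx(6.0)  # C(4,2) reactant pairs

    def test_product_kinetics_variant(self):
        net = PetriNet(("p",), ("t",), (Arc("p", "t", 2),))
        rates = StochasticRates({"t": 1.0}, kinetics="product")
        assert hazard(net, rates, Marking({"p": 4}), "t") == pytest.approx(16.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            StochasticRates({"t": -1.0})


class TestGillespie:
    def test_seed_reproducibility(self, birth_net):
        net, m, rates = birth_net
        a = gillespie_run(net, m, rates, horizon=5.0, seed=42)
        b = gillespie_run(net, m, rates, horizon=5.0, seed=42)
        assert np.array_equal(a.counts["p"], b.counts["p"])
        assert a.n_steps == b.n_steps

    def test_deadlock_at_start(self):
        net = PetriNet(("p",), ("t",), (Arc("p", "t"),))
        tr = gillespie_run(net, Marking({"p": 0}), StochasticRates({"t": 1.0}),
                           horizon=1.0, seed=0)
        assert tr.termination == "deadlock" and tr.n_steps == 0
        assert np.all(tr.counts["p"] == 0)

    def test_conservation_in_cycle(self, two_cycle):
        net, m = two_cycle
        rates = StochasticRates({"t0": 1.0, "t1": 1.0})
        m10 = Marking({"p0": 7, "p1": 3})
        tr = gillespie_run(net, m10, rates, max_steps=500, seed=3)
        total = tr.counts["p0"] + tr.counts["p1"]
        assert np.all(total == 10)

    def test_birth_process_mean(self, birth_net):
        """Ensemble mean of a rate-2 Poisson source at t=10 is 20 +- 3 SE."""
        net, m, rates = birth_net
        ens = run_ensemble(net, m, rates, runs=1000, horizon=10.0, seed=7,
                           observed=("p",), grid_points=11)
        mean = ens.final_mean("p")
        se = ens.sem("p")[-1]
        assert abs(mean - 20.0) < 3 * max(se, 1e-9)

    def test_decay_process_mean(self, decay_net):
        """Mean of the linear death process follows 100*exp(-c t)."""
        net, m, rates = decay_net
        t_obs = 2.0
        ens = run_ensemble(net, m, rates, runs=1000, horizon=t_obs, seed=11,
                           observed=("p",), grid_points=21)
        expected = 100 * np.exp(-0.5 * t_obs)
        se = ens.sem("p")[-1]
        assert abs(ens.final_mean("p") - expected) < 3 * max(se, 1e-9)

    def test_monte_carlo_error_scaling(self, decay_net):
        """Quadrupling run count roughly halves the standard error."""
        net, m, rates = decay_net
        e1 = run_ensemble(net, m, rates, runs=250, horizon=2.0, seed=1,
                          observed=("p",), grid_points=5)
        e2 = run_ensemble(net, m, rates, runs=1000, horizon=2.0, seed=1,
                          observed=("p",), grid_points=5)
        ratio = e1.sem("p")[-1] / e2.sem("p")[-1]
        assert 2.0 * 0.7 < ratio < 2.0 * 1.3


class TestEnsemble:
    def test_single_run_mean_equals_run(self, birth_net):
        net, m, rates = birth_net
        ens = run_ensemble(net, m, rates, runs=1, horizon=3.0, seed=5,
                           observed=("p",), grid_points=7)
        assert np.all(ens.sd["p"] == 0)

    def test_requires_runs(self, birth_net):
        net, m, rates = birth_net
        with pytest.raises(ValueError):
            run_ensemble(net, m, rates, runs=0, horizon=1.0)

    def test_empty_observation_list_rejected(self, birth_net):
        net, m, rates = birth_net
        with pytest.raises(ValueError):
            run_ensemble(net, m, rates, runs=2, horizon=1.0, observed=())


class TestKnockout:
    def test_zero_rate_never_fires(self, two_cycle):
        net, _ = two_cycle
        rates = apply_knockout(
            StochasticRates({"t0": 1.0, "t1": 1.0}),
            KnockoutSpec(frozenset({"t1"})),
        )
        m = Marking({"p0": 5, "p1": 0})
        for seed in range(100):
            tr = gillespie_run(net, m, rates, max_steps=50, seed=seed)
            # t1 silenced: all tokens end up in p1, none return
            assert tr.counts["p0"][-1] + tr.counts["p1"][-1] == 5
            assert tr.counts["p1"][-1] >= tr.counts["p1"][0]

    def test_original_rates_untouched(self):
        r = StochasticRates({"a": 1.0})
        r2 = apply_knockout(r, KnockoutSpec(frozenset({"a"})))
        assert r["a"] == 1.0 and r2["a"] == 0.0

    def test_unknown_id_rejected(self):
        with pytest.raises(UnknownIdError):
            apply_knockout(StochasticRates({"a": 1.0}), KnockoutSpec(frozenset({"b"})))
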