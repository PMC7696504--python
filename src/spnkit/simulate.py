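"""Gillespie stochastic simulation of an SPN with mass-action hazards.

Each transition t carries a rate constant ``c_t`` (per second).  Its
propensity in marking ``m`` follows the stochastic mass-action law:
``c_t * prod_p binom(m(p), w(p,t))`` over its pre-places — the number of
distinct reactant token combinations.  The direct-method SSA draws an
exponential waiting time from the total propensity and picks the firing
transition proportionally to its propensity.  A rate of 0 encodes an
in-silico knockout: the transition can never fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np

from .knockout import KnockoutSpec
from .net import Marking, PetriNet, UnknownIdError

__all__ = [
    "StochasticRates",
    "Trajectory",
    "TrajectoryEnsemble",
    "hazard",
    "gillespie_run",
    "run_ensemble",
    "apply_knockout",
]


@dataclass(frozen=True)
class StochasticRates:
    """Per-transition mass-action rate constants (1/s).

    ``kinetics`` selects the stoichiometric convention: ``"combinatorial"``
    (default, ``binom(m, w)`` reactant combinations) or ``"product"``
    (``m ** w``).  The two coincide on weight-1 arcs.
    """

    rate_constants: Mapping[str, float]
    kinetics: str = "combinatorial"

    def __post_init__(self) -> None:
        bad = {t: c for t, c in self.rate_constants.items() if c < 0}
        if bad:
            raise ValueError(f"negative rate constants: {bad}")
        if self.kinetics not in ("combinatorial", "product"):
            raise ValueError(f"unknown kinetics tag {self.kinetics!r}")
        object.__setattr__(self, "rate_constants", dict(self.rate_constants))

    def __getitem__(self, t: str) -> float:
        return self.rate_constants[t]


def hazard(net: PetriNet, rates: StochasticRates, m: Marking, t: str) -> float:
    """Mass-action propensity of transition ``t`` in marking ``m``."""
    net._check_transition(t)
    c = rates.rate_constants.get(t, 0.0)
    a = c
    for p, w in net._pre_t[t].items():
        n = m.counts[p]
        a *= comb(n, w) if rates.kinetics == "combinatorial" else n**w
        if a == 0.0:
            return 0.0
    return a


@dataclass(frozen=True)
class Trajectory:
    """One SSA run sampled on a fixed output grid (last value carried forward)."""

    grid: np.ndarray                     # seconds, covers [0, horizon]
    counts: Mapping[str, np.ndarray]     # observed place -> tokens per grid point
    n_steps: int
    termination: str                     # "horizon" | "max_steps" | "deadlock"
    seed: int | None = None


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Grid-aligned mean and standard deviation over independent runs."""

    grid: np.ndarray
    mean: Mapping[str, np.ndarray]
    sd: Mapping[str, np.ndarray]
    n_runs: int

    def final_mean(self, place: str) -> float:
        return float(self.mean[place][-1])

    def time_average(self, place: str) -> float:
        """Ensemble mean averaged over the whole observation grid."""
        return float(np.mean(self.mean[place]))

    def sem(self, place: str) -> np.ndarray:
        """Standard error of the ensemble mean."""
        return self.sd[place] / np.sqrt(self.n_runs)


try:  # optional JIT fast path for long ensemble runs
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@_njit(cache=False)
def _ssa_kernel(c, pre_ptr, pre_idx, pre_w, dep_ptr, dep_idx,
                d_ptr, d_idx, d_val, tokens, combinatorial,
                max_steps, horizon, grid, obs_idx, out, seed):
    np.random.seed(seed)
    m = c.shape[0]
    props = np.zeros(m)
    for j in range(m):
        a = c[j]
        for r in range(pre_ptr[j], pre_ptr[j + 1]):
            n = tokens[pre_idx[r]]
            w = pre_w[r]
            if combinatorial:
                f = 1.0
                for q in range(w):
                    f *= (n - q) / (q + 1.0)
                a *= f if f > 0 else 0.0
            else:
                a *= float(n) ** w
            if a <= 0.0:
                a = 0.0
                break
        props[j] = a
    total = props.sum()
    now = 0.0
    steps = 0
    gp = 0
    gN = grid.shape[0]
    term = 0  # deadlock
    while True:
        if total <= 0.0:
            term = 0
            break
        if steps >= max_steps:
            term = 1
            break
        wait = np.random.exponential(1.0 / total)
        nxt = now + wait
        while gp < gN and grid[gp] < nxt:
            for k in range(obs_idx.shape[0]):
                out[gp, k] = tokens[obs_idx[k]]
            gp += 1
        if nxt > horizon:
            term = 2
            now = horizon
            break
        now = nxt
        u = np.random.random() * total
        acc = 0.0
        j = -1
        for jj in range(m):
            acc += props[jj]
            if u < acc:
                j = jj
                break
        if j < 0 or props[j] <= 0.0:
            j = -1
            for jj in range(m):
                if props[jj] > 0.0:
                    j = jj
            if j < 0:
                total = 0.0
                continue
        for r in range(d_ptr[j], d_ptr[j + 1]):
            tokens[d_idx[r]] += d_val[r]
        for r in range(d_ptr[j], d_ptr[j + 1]):
            i = d_idx[r]
            for q in range(dep_ptr[i], dep_ptr[i + 1]):
                jj = dep_idx[q]
                total -= props[jj]
                a = c[jj]
                for rr in range(pre_ptr[jj], pre_ptr[jj + 1]):
                    n = tokens[pre_idx[rr]]
                    w = pre_w[rr]
                    if combinatorial:
                        f = 1.0
                        for qq in range(w):
                            f *= (n - qq) / (qq + 1.0)
                        a *= f if f > 0 else 0.0
                    else:
                        a *= float(n) ** w
                    if a <= 0.0:
                        a = 0.0
                        break
                props[jj] = a
                total += a
        steps += 1
        if steps % 4096 == 0:
            total = props.sum()
    while gp < gN:
        for k in range(obs_idx.shape[0]):
            out[gp, k] = tokens[obs_idx[k]]
        gp += 1
    return steps, term


class _Engine:
    """Pre-indexed SSA engine; propensities are updated incrementally."""

    def __init__(self, net: PetriNet, rates: StochasticRates):
        self.net = net
        self.combinatorial = rates.kinetics == "combinatorial"
        self.pidx = {p: i for i, p in enumerate(net.places)}
        self.c = [float(rates.rate_constants.get(t, 0.0)) for t in net.transitions]
        self.pre: list[list[tuple[int, int]]] = []
        self.delta: list[list[tuple[int, int]]] = []
        touching: dict[int, set[int]] = {}
        for j, t in enumerate(net.transitions):
            pre = [(self.pidx[p], w) for p, w in net._pre_t[t].items()]
            self.pre.append(pre)
            d: dict[int, int] = {}
            for p, w in net._pre_t[t].items():
                d[self.pidx[p]] = d.get(self.pidx[p], 0) - w
            for p, w in net._post_t[t].items():
                d[self.pidx[p]] = d.get(self.pidx[p], 0) + w
            self.delta.append(sorted(d.items()))
            for i, _ in pre:
                touching.setdefault(i, set()).add(j)
        # place index -> transitions whose propensity depends on it
        self.dependents = {i: sorted(js) for i, js in touching.items()}
        # flattened CSR-style arrays for the JIT kernel
        n_places = len(net.places)
        self.c_arr = np.array(self.c)
        pp, pi, pw = [0], [], []
        for j in range(len(net.transitions)):
            for i, w in self.pre[j]:
                pi.append(i)
                pw.append(w)
            pp.append(len(pi))
        self.pre_ptr = np.array(pp, dtype=np.int64)
        self.pre_idx = np.array(pi, dtype=np.int64)
        self.pre_w = np.array(pw, dtype=np.int64)
        dp, di, dv = [0], [], []
        for j in range(len(net.transitions)):
            for i, d in self.delta[j]:
                di.append(i)
                dv.append(d)
            dp.append(len(di))
        self.d_ptr = np.array(dp, dtype=np.int64)
        self.d_idx = np.array(di, dtype=np.int64)
        self.d_val = np.array(dv, dtype=np.int64)
        qp, qi = [0], []
        for i in range(n_places):
            for jj in self.dependents.get(i, ()):
                qi.append(jj)
            qp.append(len(qi))
        self.dep_ptr = np.array(qp, dtype=np.int64)
        self.dep_idx = np.array(qi, dtype=np.int64)

    def propensity(self, j: int, tokens: list[int]) -> float:
        a = self.c[j]
        if a == 0.0:
            return 0.0
        for i, w in self.pre[j]:
            n = tokens[i]
            a *= comb(n, w) if self.combinatorial else n**w
            if a == 0.0:
                return 0.0
        return a


def gillespie_run(net: PetriNet, marking: Marking, rates: StochasticRates,
                  *, horizon: float | None = None, max_steps: int | None = None,
                  seed: int | np.random.SeedSequence | None = None,
                  observed: Sequence[str] | None = None,
                  grid_points: int = 101) -> Trajectory:
    """One direct-method SSA run.

    At least one of ``horizon`` (seconds) or ``max_steps`` must bound the
    run.  Observed places are sampled on a uniform grid over
    ``[0, horizon]`` (or ``[0, final event time]`` when only ``max_steps``
    is given) with last-value-carried-forward semantics.  Identical seeds
    give identical trajectories.
    """
    if horizon is None and max_steps is None:
        raise ValueError("need a horizon or a step cap")
    if observed is None:
        observed = net.places
    unknown = set(observed) - set(net.places)
    if unknown:
        raise UnknownIdError(f"unknown observed places {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    eng = _Engine(net, rates)
    tokens = [marking.counts[p] for p in net.places]
    m = net.n_transitions
    obs_idx = [eng.pidx[p] for p in observed]

    if horizon is not None and _HAVE_NUMBA:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        kseed = int(ss.generate_state(1)[0])
        grid = np.linspace(0.0, horizon, grid_points)
        out = np.zeros((grid_points, len(obs_idx)), dtype=np.int64)
        steps, term = _ssa_kernel(
            eng.c_arr, eng.pre_ptr, eng.pre_idx, eng.pre_w,
            eng.dep_ptr, eng.dep_idx, eng.d_ptr, eng.d_idx, eng.d_val,
            np.array(tokens, dtype=np.int64),
            rates.kinetics == "combinatorial",
            max_steps if max_steps is not None else 2**62,
            float(horizon), grid, np.array(obs_idx, dtype=np.int64), out, kseed,
        )
        termination = ("deadlock", "max_steps", "horizon")[term]
        counts = {p: out[:, k].copy() for k, p in enumerate(observed)}
        return Trajectory(grid=grid, counts=counts, n_steps=int(steps),
                          termination=termination,
                          seed=None if isinstance(seed, np.random.SeedSequence) else seed)

    props = [eng.propensity(j, tokens) for j in range(m)]
    total = sum(props)
    # with only a step cap the grid end is unknown: record sparse events,
    # with a horizon fill the fixed grid on the fly (last value carried fwd)
    fixed_grid = horizon is not None
    if fixed_grid:
        grid = np.linspace(0.0, horizon, grid_points)
        out = np.empty((grid_points, len(obs_idx)), dtype=np.int64)
        gp = 0  # next grid index to fill
    else:
        events_t: list[float] = [0.0]
        events_x: list[list[int]] = [[tokens[i] for i in obs_idx]]

    now = 0.0
    steps = 0
    termination = "deadlock"
    while True:
        if total <= 0.0:
            termination = "deadlock"
            break
        if max_steps is not None and steps >= max_steps:
            termination = "max_steps"
            break
        wait = rng.exponential(1.0 / total)
        nxt = now + wait
        if fixed_grid:
            while gp < grid_points and grid[gp] < nxt:
                for k, i in enumerate(obs_idx):
                    out[gp, k] = tokens[i]
                gp += 1
        if horizon is not None and nxt > horizon:
            termination = "horizon"
            now = horizon
            break
        now = nxt
        # propensity-proportional choice
        u = rng.random() * total
        acc = 0.0
        j = -1
        for jj in range(m):
            acc += props[jj]
            if u < acc:
                j = jj
                break
        if j < 0 or props[j] <= 0.0:
            # float drift in the running total: fall back to the last
            # transition with positive propensity, or resync on true deadlock
            live = [jj for jj in range(m) if props[jj] > 0.0]
            if not live:
                total = 0.0
                continue
            j = live[-1]
        for i, d in eng.delta[j]:
            tokens[i] += d
        for i, _ in eng.delta[j]:
            for jj in eng.dependents.get(i, ()):
                total -= props[jj]
                props[jj] = eng.propensity(jj, tokens)
                total += props[jj]
        steps += 1
        if steps % 4096 == 0:
            # guard against float drift on long runs
            total = sum(props)
        if not fixed_grid:
            events_t.append(now)
            events_x.append([tokens[i] for i in obs_idx])

    if fixed_grid:
        while gp < grid_points:
            for k, i in enumerate(obs_idx):
                out[gp, k] = tokens[i]
            gp += 1
        counts = {p: out[:, k].copy() for k, p in enumerate(observed)}
        return Trajectory(grid=grid, counts=counts, n_steps=steps,
                          termination=termination,
                          seed=None if isinstance(seed, np.random.SeedSequence) else seed)

    end = max(now, events_t[-1]) or 1.0
    grid = np.linspace(0.0, end, grid_points)
    ev_t = np.array(events_t)
    idx = np.searchsorted(ev_t, grid, side="right") - 1
    ev_x = np.array(events_x, dtype=np.int64)
    counts = {p: ev_x[idx, k] for k, p in enumerate(observed)}
    return Trajectory(grid=grid, counts=counts, n_steps=steps,
                      termination=termination,
                      seed=None if isinstance(seed, np.random.SeedSequence) else seed)


def run_ensemble(net: PetriNet, marking: Marking, rates: StochasticRates,
                 *, runs: int, seed: int | None = None,
                 horizon: float | None = None, max_steps: int | None = None,
                 observed: Sequence[str] | None = None,
                 grid_points: int = 101) -> TrajectoryEnsemble:
    """Aggregate ``runs`` independent SSA runs on a shared grid.

    Per-run seeds are spawned from the master seed with numpy's
    ``SeedSequence`` splitting, so results are reproducible and independent
    of execution order.
    """
    if runs < 1:
        raise ValueError("need at least one run")
    if observed is not None and len(tuple(observed)) == 0:
        raise ValueError("empty observation list")
    if observed is None:
        observed = tuple(net.places)
    if horizon is None and max_steps is not None:
        # shared grid needs a common horizon: bound it by a pilot run
        pilot = gillespie_run(net, marking, rates, max_steps=max_steps,
                              seed=np.random.SeedSequence(seed).spawn(1)[0],
                              observed=observed, grid_points=grid_points)
        horizon = float(pilot.grid[-1])
    children = np.random.SeedSequence(seed).spawn(runs)
    acc = {p: np.zeros(grid_points) for p in observed}
    acc2 = {p: np.zeros(grid_points) for p in observed}
    for ss in children:
        tr = gillespie_run(net, marking, rates, horizon=horizon,
                           max_steps=max_steps, seed=ss,
                           observed=observed, grid_points=grid_points)
        for p in observed:
            x = tr.counts[p].astype(float)
            acc[p] += x
            acc2[p] += x * x
    mean = {p: acc[p] / runs for p in observed}
    sd = {
        p: np.sqrt(np.maximum(acc2[p] / runs - mean[p] ** 2, 0.0))
        for p in observed
    }
    grid = np.linspace(0.0, horizon, grid_points)
    return TrajectoryEnsemble(grid=grid, mean=mean, sd=sd, n_runs=runs)


def apply_knockout(rates: StochasticRates, spec: KnockoutSpec) -> StochasticRates:
    """Copy of ``rates`` with every knocked transition's constant set to 0."""
    unknown = spec.knocked - set(rates.rate_constants)
    if unknown:
        raise UnknownIdError(f"unknown transitions in knockout spec: {sorted(unknown)}")
    new = dict(rates.rate_constants)
    for t in spec.knocked:
        new[t] = 0.0
    return replace(rates, rate_constants=new)
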