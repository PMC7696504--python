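# spnkit

Structural and stochastic analysis of Petri nets for systems biology:
minimal t-invariant enumeration, MCT sets, t-clustering, in-silico
knockout analysis, and exact Gillespie simulation of stochastic Petri
nets with mass-action kinetics. The package ships a fully encoded
56-place / 70-transition stochastic Petri net of interleukin-18 (IL-18)
signalling in atherosclerotic plaque formation as its worked example.

## The scientific problem

Atherosclerosis is an inflammatory-fibroproliferative disease of the
arterial wall in which the cytokine IL-18 plays a central, proatherogenic
role: it is matured from pro-IL-18 by caspase 1, signals through the
IL-18 receptor and MyD88 to NF-kB, induces IFN-g production by T/NK
cells, and feeds the TNF, adhesion-molecule and apoptosis programmes that
drive foam-cell formation and plaque growth.

A Petri net captures this web as a bipartite graph of *places* (species,
holding integer tokens) and *transitions* (reactions). Its structure is
summarised by the incidence matrix `A` (places x transitions), where
`A[i,j]` is the net token change of place `i` when transition `j` fires.
The analysis revolves around the **minimal t-invariants**: nonnegative
integer vectors `x` with

    A · x = 0,

minimal support, gcd-reduced — each one a self-contained subprocess that
returns the system to its starting state. Derived from them are:

* **MCT sets** — maximal groups of transitions occurring in exactly the
  same invariant supports (functional building blocks);
* **t-clusters** — UPGMA clustering of invariant coefficient vectors
  under the `1 − Pearson r` distance, scored with Calinski–Harabasz and
  Mean Split Silhouette indices;
* **knockout analysis** — removing transitions and counting the
  surviving invariants and the transitions they no longer cover;
* **stochastic simulation** — the direct-method Gillespie SSA with
  mass-action propensities `c_t · ∏ C(m(p), w(p,t))`, where a knockout is
  a rate set to zero.

## Worked example

```python
from spnkit import incidence_matrix, minimal_t_invariants, compute_mct_sets
from spnkit.models import build_il18_model

bundle = build_il18_model()
A = incidence_matrix(bundle.net)          # 56 x 70 integer matrix
invs = minimal_t_invariants(A, bundle.net.transitions)
mct = [m for m in compute_mct_sets(invs) if not m.is_trivial]
print(len(invs), len(mct))
```

Running `python examples/01_invariants_and_mct.py` prints:

```
net: 56 places, 70 transitions, 158 arcs
minimal t-invariants: 177   covered: True
non-trivial MCT sets: 11
  m1: t19,t33,t35,t36,t37,t38,t39,t40,t41,t42,t43,t56,t57,t58,t59
  ...
  m9: t0,t3
  m10: t4,t7
  m11: t49,t51
```

Every transition lies in the support of some minimal invariant (the net
is covered), and the 70 transitions partition into 11 non-trivial MCT
sets — e.g. the pair `t0, t3` (classical macrophage activation), the
pair `t4, t7` (pro-IL-18 synthesis and caspase-1 cleavage) and the
fifteen transitions of the MyD88 → NF-kB cascade — plus trivial
singletons. The invariant count (177 on this reconstruction, against a
published 223 for the original figure-defined wiring; see the note
below) measures how many distinct self-contained subprocesses the wiring
supports. The other examples cover knockout batteries (`02`),
t-clustering (`03`), ensemble simulation with and without IL-18 (`04`)
and the synthetic ground-truth generators (`05`).

A thin CLI wraps the same library calls:

```bash
spnk analyze --model il18 --out out/
spnk knockout --model il18
spnk simulate --model il18 --runs 200 --steps 10000 --knock t7 --knock t0
spnk validate
```

`spnk validate` recomputes every recorded headline claim about the
bundled model (structural flags, invariant and MCT counts, the knockout
battery, cluster cardinalities) and reports pass/fail per claim.

A note on the bundled model: the place/transition catalogue, initial
marking and rate constants are printed model data, while the arc
structure is a reconstruction from the model's published structural and
invariant properties; `spnk validate` makes its fidelity measurable
claim by claim (see `docs/methods.md`).

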