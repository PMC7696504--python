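# Methods

## Model class

The package analyses place/transition Petri nets and their stochastic
extension. A net is `(P, T, F, W)` with places `P`, transitions `T`,
arcs `F` and positive integer weights `W`; a marking assigns nonnegative
token counts to places. The stochastic reading attaches a rate constant
`c_t` (1/s) to each transition and interprets the net as a continuous-time
Markov jump process: transition `t` fires with mass-action propensity
`c_t · ∏_p C(m(p), w(p,t))` over its pre-places, the combinatorial count
of reactant token combinations. The firing-time distribution is
exponential; simulation uses the exact direct-method SSA (waiting time
from the total propensity, firing transition chosen proportionally).
A configurable `product` convention (`c_t · ∏ m^w`) is provided because
published tools differ in their stoichiometric convention on weighted
arcs; the two coincide on weight-1 arcs, which dominate biochemical nets.

## Invariant analysis

Minimal t-invariants are computed by the classical Fourier–Motzkin /
Farkas tableau on `[Aᵀ | I]`, eliminating one place per step by forming
all positive row combinations with opposite signs, pruning rows whose
support strictly contains another row's after every step, and
gcd-normalising. Arithmetic is exact (Python integers), so `A·x = 0`
holds exactly for every output. Intermediate blow-up aborts at a
configurable row cap (default 10^6 — the bundled model peaks far below
this). p-invariants use the same routine on the transpose. The
enumeration is validated in the test suite against an exhaustive oracle
that tests every small coefficient vector on nets with few transitions.
Canonical output order is lexicographic by support.

MCT sets partition transitions by identical invariant-support
membership; transitions outside every support are kept as individual
trivial sets so the partition property holds on uncovered nets.
Signatures compare support membership only, not coefficients.

## t-clustering

Invariant coefficient vectors (not binarised supports) are compared by
the sample Pearson correlation; the clustering distance is `1 − r`
(range [0, 2]); constant vectors are assigned correlation 0 to keep the
matrix total. UPGMA is implemented directly (unweighted arithmetic-mean
linkage, ties broken toward the lexicographically smallest node pair for
determinism) and cross-checked against SciPy's average linkage in the
tests. Cut quality is scored by the Calinski–Harabasz variance ratio
(zero within-dispersion reported as +inf) and a Mean Split Silhouette:
each cluster is re-split by a deterministic 2-medoid partition of its
own distance submatrix and scored by the mean silhouette of its points;
clusters with fewer than three points contribute 0 since no meaningful
split exists. The published reference for MSS underdetermines the split
procedure; the deterministic 2-medoid split is this package's reading,
chosen for reproducibility.

## Knockout analysis

A knockout removes every minimal t-invariant whose support meets the
knocked transition set. Reported quantities: surviving invariants,
uncovered transitions (in no surviving support), dependent transitions
(uncovered minus knocked), per-transition survival counts, and two
impact percentages. The invariant impact (removed / total) is
unambiguous. For the transition impact two conventions are emitted —
all uncovered transitions, or uncovered excluding the knocked set —
because neither naive formula reproduces published transition-impact
tables exactly; the discrepancy is surfaced rather than hidden, and the
invariant-based numbers are the primary surface. Percentages are
rounded half-up to two decimals. Knockout of an MCT set knocks all its
members; knockout "at a place" knocks the place's producer transitions.
In simulation a knockout sets the transition's rate constant to zero.

## The IL-18 model bundle

The bundled model encodes IL-18 signalling in atherosclerotic plaque
formation: 56 places, 70 transitions. Its catalogue (names of places
and transitions), the initial marking (tokens in {0, 10, 100, 1000},
standing for absent / low / medium / high pM-scale concentrations — the
pM equivalence is metadata; all computation is on integer counts) and
the rate-constant ladder {1, 1/40, 1/100, 1/200, 1/500} s⁻¹ (reciprocals
of a six-level duration scale from seconds to days) are printed model
data, stored as reviewable JSON rather than generated in code.

The arc structure is the one component not available as a table: the
published figure is the only primary source, and this package was built
without access to a machine-readable version of it. The bundled arcs are
therefore a **reconstruction**: the wiring was derived from the model's
published structural properties (purity, connectivity, absence of
input/output places), the explicitly described pathway fragments (e.g.
peroxynitrite → oxidised LDL → foam cells → plaque/CVD, the two MCP1
sources, the two peroxynitrite sources, producers of activated
macrophages), the published MCT partition, four fully listed invariant
supports, per-transition invariant-membership counts implied by the
published knockout-impact table, and the knockout scenario counts.
These constraints over-determine much of the topology and the
reconstruction reproduces the qualitative structure exactly (all
structural flags, the four listed invariant supports, and most of the
MCT partition); the global invariant count and several membership counts
are not yet exactly reproduced, and `validate_recorded_claims` /
`spnk validate` reports every such claim individually so the remaining
divergence is measurable, not hidden. Quantities that depend only on
correctly reconstructed substructures (e.g. the single surviving
invariant under knockout of the activated-macrophage producers) already
match.

## Synthetic data

The generators emulate the regime of curated signalling SPNs rather than
any particular organism: planted-cycle nets whose minimal invariants are
elementary circuits known by construction; random connected bipartite
nets (spanning alternating backbone plus density-controlled extra arcs)
with markings drawn from {0, 10, 100, 1000} and rates from the bundled
model's ladder; and nonnegative integer vector sets with a planted
partition whose within-cluster correlation exceeds between-cluster
correlation by a requested margin (amplitude 20, integer noise ≈
amplitude/separation, verified post hoc and retried up to 50 times).
They capture the combinatorial and statistical structure the pipeline
operates on; they do not capture biological topology motifs (hubs,
scale-free degree distributions) or kinetic stiffness, so passing tests
certify algorithmic correctness, not biological realism.

## Numerical and design choices

* Exact integer arithmetic everywhere in the structural pipeline; no
  rational or floating kernels.
* Markings are immutable; firing returns a new marking (cheap snapshots
  for simulation and replay).
* SSA ensembles derive per-run seeds from the master seed via numpy's
  `SeedSequence` spawning, so results are reproducible and independent
  of execution order; the running total propensity is resynchronised
  every 4096 steps to bound float drift, with a guarded fallback if
  drift would select an impossible transition.
* Ensemble observation uses a fixed uniform grid with last-value-carried
  forward sampling, enabling cross-run aggregation.
* Desk scale defaults: ensembles of hundreds to a thousand runs and
  10^4–10^5 steps stabilise the means used in the directional scenario
  analyses; the scenario tests use 200 runs with a 10^5-step cap.
* Scenario observables are compared on windows matched to their intrinsic
  timescales: nuclear NF-kB turns over within tens of seconds (its
  consumers sum to ≈0.02 s⁻¹), so its arms are compared as time averages
  over a 500 s horizon; foam cells accumulate through reactions on the
  100–500 s-per-event scale, so they are compared over a 3×10^5 s
  horizon. A single shared window would bury one observable's signal in
  the other's transient.
* Simulation scenarios observe the foam-cell place and nuclear NF-kB.
  The foam-cell place is addressed by its catalogue entry (p11);
  published scenario prose refers to it once under a different index,
  and the catalogue numbering is followed.

## Known limitations

* The arc reconstruction is the main caveat (above); all
  transcription-sensitive results are funnelled through the claims
  checklist.
* Boundedness/liveness analysis, coloured/timed/queueing net variants,
  and non-minimal invariant bases are out of scope.
* The UPGMA/Pearson pipeline is the only clustering configuration;
  the validity-index machinery is general enough to extend.
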