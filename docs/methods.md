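# Methods

`rrspace` draws approximately uniform random molecules from a user-defined
chemical space and estimates how many molecules such a space contains,
without ever enumerating the space. This note records the model, the
numerical choices, and what the built-in validation does and does not show.

## The model of a chemical space

A space is a set of *atom types* — pairs (element, valence) — plus an
atom-count range [N_min, N_max], N_min ≥ 2. Elements are opaque labels: the
package carries no periodic-table knowledge, and an element appearing with
two valences is simply two atom types. Molecules are *protomolecules*:
connected loop-free undirected multigraphs whose vertex degrees (counting
bond multiplicity) equal the atom valences. There are no charges, radicals,
isotopes, or open valences, and by default no cap on bond multiplicity
beyond what the endpoint valences force (an optional cap, e.g. 3, is
available for chemical realism). No stability or 3D-geometry filtering is
applied: samples represent possible molecular topologies, not necessarily
stable compounds.

## Formula enumeration

All sum formulas are found by a two-stage integer partition: the atom count
is first composed over the ordered valence types, keeping compositions whose
degree multiset is realizable, then each valence's share is partitioned over
the elements of that valence. Realizability of a degree multiset means: even
degree sum, maximum degree at most the sum of the others (loop-free
multigraph condition), and at least n−1 edges so the graph can be connected.
The nested enumeration is verified against the direct one-stage partition on
all fixture spaces, and the realizability predicate against brute-force
multigraph search on up to five vertices.

## Exact counting

Up to a configurable cap (default 10 atoms) protomolecule universes are
enumerated exhaustively: a recursive constructor grows a single connected
component, saturating one vertex at a time, with a symmetry cut over
interchangeable untouched vertices; duplicates are removed by canonical
form. Canonical forms come from BLISS canonical labeling (igraph) on an
auxiliary simple graph in which each bonded pair is subdivided by a vertex
colored with the bond order; automorphism group orders come from VF2 on the
same encoding. Exact enumeration is the oracle for every estimator below.

## Edit distance

The distance between two protomolecules of one labeled degree sequence is
the minimum over atom-type-respecting vertex matchings of the L1 transport
cost between bond-order matrices (half the sum of absolute differences =
number of unit bond edits; moving one bond costs 2). The ground metric is a
deliberate choice, isolated in one function, since alternatives (e.g. L2)
are defensible. Below 100 type-respecting permutations the minimum is exact
by exhaustion. Above, six pooled upper-bound heuristics are used: random
shuffles, steepest-descent pairwise switches, 2-opt on the
quadratic-assignment trace objective, per-element-class linear-assignment
refinement in one or several scans, and budgeted depth-first
branch-and-bound. Default budgets are of order 50–100 evaluations per
heuristic; a light preset serves inner loops. A complete branch-and-bound
(`edit_distance_bnb`) provides exact values far beyond the exhaustion
threshold and is used as the test oracle; on fixture pairs the pooled
heuristics match it in well over 90% of cases and never undercut it.

## Count estimation

The universe U(d) — one vertex per protomolecule of degree sequence d,
edges between minimal-edit-distance pairs — behaves like a small-world
network, so its average path length l_G tracks ln |U(d)|. The package uses

    ln |U(d)| ≈ a7 · l_G + b7,      defaults a7 = 1.220, b7 = −0.7295,

with constants obtained at database scale elsewhere; they are refittable
from local exact data (`refit_calibration`), and the desk-scale refit on the
built-in fixtures gives a slope near 1 with R² ≈ 0.9. All logarithms are
natural; the constants absorb the base convention.

l_G is measured by sampling protomolecule pairs from the MCMC sampler
(class-uniform mode, see below), scoring them with the heuristic distance,
and averaging over pairs with distinct canonical forms. Sampling is
adaptive: batches of 8 pairs until the standard error is below 5% of the
mean or 60 pairs are reached. A single-graph universe has l_G = 0 by
convention.

Nonpure sequences reduce to their pure counterpart through the asymmetry
assumption (large random graphs rarely have automorphisms): the count
multiplies by N_P(d) = ∏_v ∏_i C(Σ_{j≥i} c_j, c_i) and the path length
stretches by (1 + ln N_P / Σ_i d_i). On small fixtures, where symmetry is
common, N_P·|U(d_U)| is verified to bound |U(d)| from above, with equality
exactly when no pure-universe graph has an automorphism moving
nonpure-valence vertices — the tests report the deviations.

For large pure sequences the asymptotic multigraph count G (prefactor
M!/((M/2)! 2^{M/2} ∏ k_i!) with exponential corrections in the
falling-factorial sums M_2, M_3, evaluated in log space) feeds a second
calibrated line l_G ≈ a10·ln G + b10 (defaults 0.7561, −14.40). Because the
raw law keeps growing as monovalent atoms exhaust the double-bond
equivalents, G is divided by t!, where t counts monovalent atoms in excess
of the least-hydrogenated realizable formula with the same heavy-atom
profile; this baseline for t is a package choice — the trend, not the
anchor, is fixed by theory. When the correction terms dominate the log
prefactor the estimate is refused unless forced, since the relation is
uncalibrated in that regime.

Dispatch is a cascade: exact (within cap or stored) → base (stored measured
l_G for d) → pure (stored or freshly measured l_G of d_U, stretched) →
asymptotic. Every record carries its tier, provenance, seed and pair count;
the counts database is an append-only CSV with a JSON calibration sidecar.

## Sampling

A molecule is drawn by first choosing a stoichiometry with probability
proportional to its estimated count, then running a degree-preserving chain
within that stoichiometry's degree sequence. The start is a stub-matched
random realization with a deterministic greedy fallback (spanning tree, then
max-residual stub pairing) for tree-dominated sequences where random stub
pairing almost never connects. Chain moves are double edge swaps on four
distinct atoms; moves that disconnect the graph are rejected, and a Hastings
factor (m(a,c)+1)(m(b,d)+1)/(m(a,b)·m(c,d)) corrects the proposal asymmetry
of parallel bonds, making the stationary law uniform over labeled bond
matrices. Ergodicity over fixture universes is checked by computing the full
transitive closure of the move set and comparing with exact enumeration.

Uniformity over bond matrices weights an isomorphism class by the number of
its labeled realizations, i.e. by 1/|Aut|. Since the package's uniformity
claim is at class level, an extra Metropolis factor |Aut(g′)|/|Aut(g)|
(automorphism orders cached per canonical class) flattens this by default.
The correction deepens wells at symmetric graphs and so lengthens the
correlation time; the default schedule is therefore burn-in 10·E and
thinning 5·E with the correction on (E = bond count), E without it. These
defaults were validated by the fixture chi-square suite: with thinning E the
corrected chain shows visible autocorrelation (not bias) on the pentane
universe, with 5·E it is statistically uniform. For large molecules, where
nontrivial automorphisms are rare, the correction can be switched off and
the two stationary laws practically coincide.

Element labels are attached afterwards: atom types of equal valence and
count are interchangeable, and the slot-to-element bijection is drawn
uniformly.

## Database comparison

Molecules are grouped by full stoichiometry with valences realized from
bond orders (so amine N³ and nitro N⁵ are distinct atom types). Database
frequencies and space counts are aligned on the space's support, sorted by
size in the reference space (ties by canonical key), normalized, and turned
into CDFs. Reported scores: the KS statistic (max |ΔCDF|, in [0,1]) and
KL(P‖Q) with natural log, Q floored at eps = 1/(10·total space count);
floored bins are counted and flagged because they inflate KL. A subsampling
curve (mean KS of random fractions vs the full space) shows how small a
database may be while staying representative.

## Fixtures and what passing tests show

The built-in fixtures are small spaces (≤ 8–17 atoms including monovalent
caps) whose universes are exactly enumerable: a two-monovalent alphabet, an
alkane-like space, divalent chains, a halogenated space rich in nonpure
sequences, a mixed-valence space, a 26-sequence space with counts from 3 to
~4400 for calibration refits, and a 6-stoichiometry/131-graph space for the
joint-sampling uniformity test (6000 samples against simulated multinomial
envelopes and per-stoichiometry frequencies, chi-square at α = 0.01). Sizes
were chosen so the whole validation runs on one core in minutes.

These fixtures establish correctness of the machinery — enumeration,
distances, chain stationarity, the calibration pipeline — at desk scale.
They do not show that the small-world calibration constants transfer to
30-atom molecules, that the asymmetry assumption holds quantitatively for
any particular space (at fixture scale it visibly fails for symmetric
graphs), or that sampled topologies are chemically stable. The estimators
above the exact tier carry a systematic per-stoichiometry error that does
not average out within a stoichiometry; at space level errors partially
cancel across many stoichiometries.

## Known limitations

- Exact enumeration and the automorphism correction are exponential in the
  worst case; both are desk-scale tools, guarded by caps.
- The heuristic edit distance is an upper bound; overestimated distances
  bias l_G, and hence counts, upward in hard instances.
- The t! baseline and the KL eps floor are documented conventions, not
  derived quantities.
- SMILES output requires real element symbols and bond orders ≤ 6 (RDKit's
  range); abstract labels fall back to a graph JSON format.
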