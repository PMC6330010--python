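# Methods

## Model and geometry

A metabolic network is the stoichiometric matrix N ∈ ℝ^{m×r} of its m
internal metabolites and r reactions, a partition of the reactions into
irreversible (I_irr) and reversible (I_rev), and optional box bounds
ℓ, u and objective c. Steady state and irreversibility define the flux
cone C = {v : Nv = 0, v_i ≥ 0 for i ∈ I_irr}; finite bounds turn it into
the flux polyhedron P.

Sign vectors over {−, 0, +} are ordered conformally: ξ ≤ η iff every
nonzero entry of ξ equals the matching entry of η. A *tope* is C_{≤τ} for
a full sign vector τ (no zeros, + on irreversibles) realized by some flux.
Writing v = Kx with K an r×d nullspace basis of N, the sign of v_i
locates x relative to the hyperplane K_i x = 0, so topes are the cells of
a central hyperplane arrangement that satisfy the irreversibility
constraints; 2·Σ_{i<d} C(r−1, i) bounds the cell count and 2^{|I_rev|}
bounds the tope count.

## Consistency and preprocessing

The enumeration assumes a *consistent* cone: every reaction can carry
nonzero flux in each direction its reversibility allows. Then every tope
has full support (a convex-combination argument: any flux missing support
can be perturbed toward a supporting flux without leaving its sign class).
`make_consistent` enforces this with flux variability analysis: a
direction counts as feasible when a flux of magnitude ≥ 10⁻⁶ can use it
(the same scale as the feasibility LP below, with magnitudes capped at
10³); blocked reactions are removed, one-directional reversibles are
demoted to irreversible, and backward-only columns are negated. The
negations are recorded and inverted on output, so all reported sign
vectors refer to the model's original orientation. The pass is idempotent.

Reactions whose rows of K are scalar multiples carry proportional fluxes
in *every* steady state, so their signs flip in lockstep; the first such
reaction in model order represents the class, and only classes whose
members are all reversible are flippable. Proportionality is detected by
vanishing 2×2 minors (< 10⁻⁹ after normalizing rows to unit max-abs, a
scale-invariant test). Nullspace bases are computed exactly (sympy
rational RREF) whenever N is rational, falling back to SVD with relative
rank tolerance 10⁻⁹ otherwise; exactness removes rank ambiguity on
published models, whose coefficients are rational in practice. A
variant parametrized by chosen free coordinates (rows of K forming an
identity block) supports bases pinned to designated reactions.

The initial tope comes from a generic convex combination of per-direction
witness fluxes: consistency guarantees each reaction a forward witness,
and a random positive weighting (fixed internal seed, retried on the
measure-zero cancellation event) gives a full-support flux whose sign
vector — after flipping the negative reversible columns — is the all-plus
root of the search.

## Tope enumeration

Feasibility of a candidate τ is one LP on the sparse stoichiometric
matrix: Nv = 0 and ℓ ≤ τ_i v_i ≤ u for all i, intersected with the
model's box bounds and, for polyhedron runs, extra linear rows. Defaults
ℓ = 10⁻⁶ and u = 10³ keep witnesses away from zero and the LP bounded;
the HiGHS feasibility tolerance is set to 10⁻¹⁰, and signs are extracted
from floating-point fluxes with zero tolerance 10⁻⁹ — between the two
scales, so a witness never straddles the threshold.

The search is breadth-first by the number of minus entries among the
flippable (independent, all-reversible-class) positions. Level n expands
every feasible level-(n−1) tope by flipping one more + position (and its
coupled class members); candidates are deduplicated in a visited set
keyed on the packed bit pattern, so each LP runs at most once. The search
stops when a level produces no feasible candidate, when all flippable
positions are exhausted, or at the user's `max_level`/`limit` (flagged
incomplete). Children of infeasible parents are never visited — the
pruning premise of reverse-search cell enumeration, which guarantees for
hyperplane-arrangement cells that the cell set is connected through
single-hyperplane flips. We do not re-prove that no tope's entire
lower neighborhood can be infeasible; instead the test suite checks BFS
output against exhaustive 2^n LP scans on 50+ random networks (and the
toy model), which has never shown a missed tope.

Parallelism follows a level-synchronized pool: the children of each
parent form an independent task, results are merged by a single writer,
and the *set* of topes (and the emitted canonical order, sorted by packed
sign bits) is deterministic and independent of the thread count; only
discovery order and the provenance "first parent" metadata could differ,
and parent assignment is made deterministic by expanding parents in
sorted order.

## Optimization

Flux-balance analysis maximizes cᵀv over P; the polyhedron of optima
P* = {v ∈ P : cᵀv = d} is represented by appending the window
d − tol ≤ cᵀv ≤ d with tol = 10⁻⁶·max(1, |d|) (relative, to absorb
solver-level jitter of the reported optimum). Flux variability on P*
then demotes reversibles that lost a direction, exactly as in cone
preprocessing; reactions forced to (near-)zero at the optimum cannot
appear in a full-support sign vector, so they are dropped from the
sign-vector alphabet and reported separately. Tope enumeration then runs
unchanged with the window inside every feasibility LP, yielding the
optimal topes directly.

## EFM enumeration per tope

Orienting the columns of N along a tope's sign vector maps the tope onto
{v : N'v = 0, v ≥ 0}, all reactions irreversible — so extreme rays can be
enumerated without the doubling of dimension that reversible-reaction
splitting causes. In nullspace coordinates the tope is the pointed cone
{x ∈ ℝ^d : Kx ≥ 0 row-wise}, and the double description method runs in
exact rational arithmetic: initialization from d independent rows
(simplicial cone, rays = columns of the inverse), insertion of remaining
rows most-zeros-first, adjacency of positive/negative ray pairs by the
combinatorial test (no third ray's active set contains the pair's common
active set, with the |active| ≥ d−2 quick filter), and normalization of
every ray to a primitive integer vector. Exactness trades speed for
certainty; the intended scale is desk-size topes, not genome-scale runs.

EFMs are canonically normalized by clearing denominators and dividing by
the gcd — a primitive integer vector whose tuple is the deduplication key
across topes (sign patterns alone would not do: distinct EFMs can share a
support). Each EFM appears in exactly the topes whose sign vector it
conforms to; `verify_tope_efm_duality` checks on small models that
per-tope sets are the conforming subsets of the global set, that each is
maximal conformal, and that their union is the global set.
`conformal_decomposition_check` certifies the conformal-sum property of a
flux by LP feasibility over the conformal EFMs.

## Analytics and extrapolation

Adjacency (sign vectors differing in one flippable position) is computed
on packed bit patterns; dependent reactions flip with their
representative and do not count separately. Direction frequencies and
the pair-direction matrix are straight counts over the tope set, with
zero-count direction combinations flagged infeasible.

For enumerations too large to finish, the per-level counts are fitted by
a·exp(−(n−μ)²/2σ²) in raw counts (least squares). Raw-count fitting from
a truncated prefix is badly initialized by moments, so the starting point
comes from a parabola fitted to the log counts — exact for noise-free
Gaussian data even when only the rising flank is observed — after which
the raw-count refinement dominates. The total estimate sums the fitted
curve over integer levels (floored at the observed cumulative count);
fits with σ < 10⁻⁴ or σ > 10⁵ are rejected as degenerate rather than
extrapolated.

## Synthetic networks

`random_network(m, r, n_rev, density, seed)` draws integer stoichiometric
coefficients in [−3, 3] and balances the last column against a positive
integer flux, so a full-support positive flux always exists and no
reaction is blocked; about half of the requested reversibles receive a
negated twin column, whose two-cycle makes the backward direction
feasible. A consistency pass then demotes reversibles that still cannot
run backward, so the realized reversible count is at most `n_rev`. The
generator emulates the combinatorial structure the enumeration operates
on — consistent cones with coupled and reversible reactions — not the
biology of genome-scale reconstructions: column density, bounds and
objective structure of real models are out of its scope, so passing
tests demonstrate algorithmic correctness (agreement with exhaustive
enumeration, duality of topes and EFMs), not biological realism.

## Problem sizes and limitations

The shipped tests and the acceptance script run at desk scale: the
six-reaction toy network, random networks up to ~5×10 with ≤ 6
reversibles, and synthetic level counts for the extrapolation. Published
genome-scale models are supported through the SBML/JSON readers, but
enumerations with tens of independent reversible reactions are
long-running by nature; `max_level`, `limit` and `threads` exist for
exactly that regime. Known limitations: the double description
implementation is exact but not competitive with compiled tools on large
topes; thermodynamic feasibility of topes is not modeled; and the
reverse-search connectivity premise, while backed by arrangement theory
and extensive brute-force testing, is not re-proved here for cones with
irreversibility constraints.
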