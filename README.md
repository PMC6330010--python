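# fluxtopes

Flux tope analysis for constraint-based metabolic models.

A metabolic network with stoichiometric matrix **N** ∈ ℝ^{m×r} constrains
its steady-state reaction rates to the *flux cone*

    C = { v ∈ ℝ^r : Nv = 0,  v_i ≥ 0 for irreversible i }.

Elementary flux modes (EFMs) — the support-minimal elements of C — describe
the cone from below, but their number explodes with model size. A **flux
tope** describes it from above: fix the direction of *every* reversible
reaction, i.e. pick a full sign vector τ ∈ {−,+}^r with + on all
irreversible positions, and take the subcone

    C_{≤τ} = { v ∈ C : sign(v) ≤ τ }.

If the cone is consistent (every reaction can carry flux in each allowed
direction), each tope contains a "maximal pathway" using all reactions, and
the cone is the union of its topes. Topes are the feasible combinations of
reaction directions — the object of interest when studying how direction
choices are coordinated across a network — and there are typically far
fewer topes than EFMs.

This package provides:

- **Tope enumeration** (`enumerate_topes`): breadth-first search over full
  sign vectors ordered by the number of minus entries among the independent
  reversible reactions. A candidate τ is feasible iff the LP
  `Nv = 0, ℓ ≤ τ_i v_i ≤ u` (ℓ = 10⁻⁶, u = 10³ by default) has a solution;
  children of infeasible parents are pruned, and a visited table keyed on
  packed sign bits guarantees one LP per candidate.
- **Preprocessing** (`make_consistent`, `flux_variability`,
  `reaction_dependencies`, `initial_tope`): flux variability analysis
  removes blocked reactions and demotes one-directional reversibles;
  reactions whose nullspace-basis rows are proportional flip in lockstep
  and are collapsed onto one representative.
- **Optimal topes** (`fba`, `enumerate_optimal_topes`): the same search on
  the polyhedron of optimal fluxes P* = {v ∈ P : cᵀv = d}, finding the
  direction combinations compatible with, e.g., maximal biomass — without
  enumerating the cone's topes first.
- **EFM enumeration per tope** (`enumerate_efms_in_tope`,
  `enumerate_efms_via_topes`): inside a tope all directions are fixed, so
  the double description method (exact rational arithmetic) runs on a
  nonnegative cone of the *original* dimension — no reversible-reaction
  splitting. The union over topes, deduplicated by primitive integer
  normalization, is the global EFM set.
- **Analytics** (`adjacency_histogram`, `direction_frequencies`,
  `pair_direction_matrix`, `fit_incremental_gaussian`): tope-graph
  adjacency, per-reaction direction preferences, infeasible pairs of
  directions, and Gaussian extrapolation of the per-level counts to
  predict a total from a truncated run.

Models are read from SBML (via cobrapy), a native JSON schema, or triplet
TSV; a built-in six-reaction toy network (`toy_model`) and a seeded random
consistent-network generator (`random_network`) serve as fixtures.

## Worked example

The toy network has 3 internal metabolites, 6 reactions (R3, R4, R5
reversible), hence at most 2³ = 8 topes:

```bash
python examples/enumerate_toy_topes.py
```

```
5 topes found (per BFS level: [1, 2, 2], 8 LP checks):
  R1    R2    R3    R4    R5    R6
  +     +     +     +     +     +     level 0
  +     +     -     +     +     +     level 1
  +     +     +     -     +     +     level 1
  +     +     -     -     +     +     level 2
  +     +     -     +     -     +     level 2
```

Five of the eight direction combinations are realizable; level n collects
the topes with n reversed reversible reactions. EFM enumeration inside
these topes (`python examples/efms_via_topes.py`) yields 3 EFMs per tope
and 6 distinct EFMs overall — the most widely shared one, primitive form
`(1, 1, 0, 0, 1, 1)`, lies in 4 of the 5 topes, and
`(0, 0, 0, -1, 1, 1)` is the internal cycle through R4, R5, R6.

Bounding both uptake reactions at 10 and maximizing the product flux v₂
(`python examples/optimal_topes.py`):

```
max v2 = 30 at flux [10.0, 30.0, 10.0, 10.0, 20.0, 0.0]

2 topes attain the optimum:
  ++++++
  +++-++
```

The optimum pins every reversible direction except R4, so exactly two
adjacent topes are optimal.

A shell front-end wraps the same pipeline:

```bash
fta topes --model toy.json --out topes.tsv --report report.json
fta optimal-topes --model toy.json --objective R2 --out opt.tsv
fta efms --model toy.json --out efms.tsv
fta analyze --model toy.json --topes topes.tsv --out analysis.json
```

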