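"""Metabolic network container, the built-in toy network, and a random
consistent-network generator used throughout the test-suite.

A network is the stoichiometric matrix of the internal metabolites together
with reversibility flags, optional box bounds on the fluxes and an optional
linear objective.  Reactions flagged irreversible have lower bound >= 0; the
flux cone is ``{v : Nv = 0, v_i >= 0 for irreversible i}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class ModelError(ValueError):
    """Malformed or degenerate model input."""


class GenerationError(RuntimeError):
    """Random network generation failed to produce a consistent cone."""


@dataclass(frozen=True)
class MetabolicNetwork:
    """Stoichiometry of m internal metabolites times r reactions.

    Attributes
    ----------
    N : (m, r) array of net stoichiometric coefficients.
    metabolite_ids, reaction_ids : row / column labels.
    reversible : length-r boolean flags; ``~reversible`` defines I_irr.
    lb, ub : optional box bounds (None entries mean unbounded); an
        irreversible reaction always has an effective lower bound >= 0.
    objective : optional length-r objective coefficients c.
    """

    N: np.ndarray
    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    reversible: np.ndarray
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    objective: np.ndarray | None = None

    def __post_init__(self):
        N = np.asarray(self.N, dtype=float)
        object.__setattr__(self, "N", N)
        if N.ndim != 2:
            raise ModelError("stoichiometric matrix must be two-dimensional")
        m, r = N.shape
        if r == 0:
            raise ModelError("model has no reactions")
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != r:
            raise ModelError("label counts do not match matrix shape")
        if len(set(self.reaction_ids)) != r:
            dup = [x for x in self.reaction_ids
                   if list(self.reaction_ids).count(x) > 1][0]
            raise ModelError(f"duplicate reaction id {dup!r}")
        rev = np.asarray(self.reversible, dtype=bool)
        object.__setattr__(self, "reversible", rev)
        if rev.shape != (r,):
            raise ModelError("reversible flags must have one entry per reaction")
        for name in ("lb", "ub", "objective"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (r,):
                    raise ModelError(f"{name} must have one entry per reaction")
                object.__setattr__(self, name, v)
        if self.lb is not None and self.ub is not None:
            if (self.lb > self.ub).any():
                raise ModelError("lb must be <= ub componentwise")
        if self.lb is not None and (self.lb[~rev] < 0).any():
            raise ModelError("irreversible reactions require lb >= 0")
        rev.setflags(write=False)
        N.setflags(write=False)

    @property
    def m(self) -> int:
        return self.N.shape[0]

    @property
    def r(self) -> int:
        return self.N.shape[1]

    @property
    def irr_mask(self) -> np.ndarray:
        return ~self.reversible

    @property
    def n_rev(self) -> int:
        return int(self.reversible.sum())

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ModelError(f"unknown reaction id {rid!r}") from None

    def cone_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Effective (lb, ub) with +-inf for missing bounds and the
        irreversibility floor applied."""
        lb = np.full(self.r, -np.inf) if self.lb is None else self.lb.copy()
        ub = np.full(self.r, np.inf) if self.ub is None else self.ub.copy()
        lb[self.irr_mask] = np.maximum(lb[self.irr_mask], 0.0)
        return lb, ub

    def subnetwork(self, keep: Sequence[int]) -> "MetabolicNetwork":
        """Restriction to the reaction columns in ``keep`` (order kept)."""
        keep = list(keep)
        return replace(
            self,
            N=self.N[:, keep],
            reaction_ids=tuple(self.reaction_ids[i] for i in keep),
            reversible=self.reversible[keep],
            lb=None if self.lb is None else self.lb[keep],
            ub=None if self.ub is None else self.ub[keep],
            objective=None if self.objective is None else self.objective[keep],
        )

    def with_reversible(self, reversible: np.ndarray) -> "MetabolicNetwork":
        lb = self.lb
        if lb is not None:
            lb = lb.copy()
            lb[~np.asarray(reversible, bool)] = np.maximum(
                lb[~np.asarray(reversible, bool)], 0.0)
        return replace(self, reversible=np.asarray(reversible, bool), lb=lb)

    def with_flipped_columns(self, flip: Sequence[int]) -> "MetabolicNetwork":
        """Negate the stoichiometry of the reactions in ``flip`` (reverse
        their conventional direction); bounds are mirrored accordingly."""
        flip = list(flip)
        N = self.N.copy()
        N[:, flip] *= -1
        lb = None if self.lb is None else self.lb.copy()
        ub = None if self.ub is None else self.ub.copy()
        if lb is not None or ub is not None:
            lo, hi = self.cone_bounds()
            lo, hi = lo.copy(), hi.copy()
            lo[flip], hi[flip] = -hi[flip], -lo[flip]
            lb, ub = lo, hi
        obj = None if self.objective is None else self.objective.copy()
        if obj is not None:
            obj[flip] *= -1
        return replace(self, N=N, lb=lb, ub=ub, objective=obj)


def toy_model() -> MetabolicNetwork:
    """The six-reaction demonstration network.

    Three internal metabolites A, B, C; reactions R1 (uptake of A), R2
    (secretion from B), R3 (uptake producing two C), R4 (A -> B), R5
    (C -> B) and R6 (A -> C).  R1, R2, R6 are irreversible; R3, R4, R5 are
    reversible.  Its flux cone has a three-dimensional nullspace and
    exactly five flux topes generated by six elementary flux modes.
    """
    N = np.array([
        [1, 0, 0, -1, 0, -1],
        [0, -1, 0, 1, 1, 0],
        [0, 0, 2, 0, -1, 1],
    ], dtype=float)
    return MetabolicNetwork(
        N=N,
        metabolite_ids=("A", "B", "C"),
        reaction_ids=("R1", "R2", "R3", "R4", "R5", "R6"),
        reversible=np.array([False, False, True, True, True, False]),
    )


def random_network(m: int, r: int, n_rev: int, density: float = 0.4,
                   seed: int = 0) -> MetabolicNetwork:
    """Random consistent metabolic network for property tests.

    The generator embeds a guaranteed full-support positive flux: all but
    the last column are drawn with integer coefficients in [-3, 3] and the
    last column balances ``N v* = 0`` for a positive integer flux ``v*``
    with last entry 1, so no reaction is blocked.  Roughly half of the
    requested reversible reactions are paired with a negated twin column,
    creating two-cycles that make both directions feasible.  The result is
    passed through :func:`fluxtopes.preprocess.make_consistent`, which may
    demote reversible reactions that cannot run backwards; the realized
    reversible count is therefore at most ``n_rev``.

    Deterministic for a fixed seed.
    """
    from .preprocess import make_consistent

    if not (r > m >= 1):
        raise ModelError("need r > m >= 1")
    if not (0 <= n_rev <= r):
        raise ModelError("need 0 <= n_rev <= r")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        N = np.zeros((m, r))
        v_star = rng.integers(1, 4, size=r).astype(float)
        v_star[-1] = 1.0
        for j in range(r - 1):
            col = rng.integers(-3, 4, size=m) * (rng.random(m) < density)
            if not col.any():
                col[rng.integers(m)] = rng.choice([-1, 1])
            N[:, j] = col
        rev_idx = rng.choice(r - 1, size=min(n_rev, r - 1), replace=False)
        # negated twin columns give reversible pairs a feasible 2-cycle
        twins = rev_idx[: len(rev_idx) // 2 + len(rev_idx) % 2]
        partners = rng.choice([j for j in range(r - 1) if j not in twins],
                              size=len(twins), replace=False)
        for t, p in zip(twins, partners):
            N[:, t] = -N[:, p]
        N[:, -1] = -N[:, :-1] @ v_star[:-1]
        reversible = np.zeros(r, bool)
        reversible[rev_idx] = True
        # drop metabolites that ended up in no reaction
        used = np.abs(N).sum(axis=1) > 0
        if not used.all():
            if not used.any():
                continue
            N = N[used]
        mets = tuple(f"M{i}" for i in range(N.shape[0]))
        rxns = tuple(f"R{j}" for j in range(r))
        try:
            net = MetabolicNetwork(N=N, metabolite_ids=mets,
                                   reaction_ids=rxns, reversible=reversible)
            consistent, _ = make_consistent(net)
        except (ModelError, Exception):
            continue
        if consistent.r >= 2:
            return consistent
    raise GenerationError(
        f"no consistent network after 100 attempts (m={m}, r={r})")
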