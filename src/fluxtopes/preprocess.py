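"""Pre-processing of the flux cone: consistency via flux variability
analysis, nullspace computation, reaction-dependency detection and the
initial tope orientation.

Consistency means every reaction can carry nonzero steady-state flux in
every direction its reversibility allows.  On a consistent cone all flux
topes have full support, which is what the breadth-first tope enumeration
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy

from . import _lp
from .model import MetabolicNetwork, ModelError
from .signs import SIGN_EPS, FullSignVector

#: A direction counts as feasible when a flux of magnitude >= FLUX_LB can
#: use it; matches the lower bound of the tope-feasibility LP.
FLUX_LB = 1e-6
#: Magnitude cap applied in feasibility LPs to keep the cone bounded.
FLUX_UB = 1e3


class InconsistencyError(RuntimeError):
    """The network violates a consistency precondition."""


class NoFluxError(RuntimeError):
    """The stoichiometric matrix has a trivial nullspace."""


class EmptyModelError(RuntimeError):
    """Consistency reduction removed every reaction."""


@dataclass
class ConsistencyReport:
    """What :func:`make_consistent` changed."""

    removed: list[str] = field(default_factory=list)
    fixed_forward: list[str] = field(default_factory=list)
    fixed_backward: list[str] = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0

    @property
    def unchanged(self) -> bool:
        return not (self.removed or self.fixed_forward or self.fixed_backward)

    def to_dict(self) -> dict:
        return {
            "removed": self.removed,
            "fixed_forward": self.fixed_forward,
            "fixed_backward": self.fixed_backward,
            "n_before": self.n_before,
            "n_after": self.n_after,
        }


@dataclass
class ReactionDependency:
    """Partition of reactions into independent representatives and
    dependents whose nullspace-basis rows are scalar multiples.

    ``dependent`` maps a dependent reaction index to its representative and
    the sign of the scalar multiplier: with sign +, the two fluxes always
    share their sign; with sign -, they are always opposite.
    """

    independent: list[int]
    dependent: dict[int, tuple[int, int]]

    @property
    def r_ind(self) -> int:
        return len(self.independent)

    def members(self, i: int) -> list[int]:
        """All reactions coupled to independent reaction ``i`` (incl. i)."""
        return [i] + [j for j, (k, _) in self.dependent.items() if k == i]


def _direction_feasible(network: MetabolicNetwork, i: int, forward: bool,
                        lb_mag: float = FLUX_LB,
                        ub_mag: float = FLUX_UB,
                        extra_rows=None) -> bool:
    lb, ub = network.cone_bounds()
    lb, ub = np.maximum(lb, -ub_mag), np.minimum(ub, ub_mag)
    if forward:
        lb[i] = max(lb[i], lb_mag)
    else:
        ub[i] = min(ub[i], -lb_mag)
    if lb[i] > ub[i]:
        return False
    ok, _ = _lp.feasible(network.N, lb, ub, extra_rows=extra_rows)
    return ok


def is_consistent(network: MetabolicNetwork, extra_rows=None) -> bool:
    """True iff every reaction supports nonzero flux in each allowed
    direction."""
    for i in range(network.r):
        if not _direction_feasible(network, i, True, extra_rows=extra_rows):
            return False
        if network.reversible[i] and not _direction_feasible(
                network, i, False, extra_rows=extra_rows):
            return False
    return True


def flux_variability(network: MetabolicNetwork,
                     extra: tuple[np.ndarray, float] | None = None
                     ) -> list[tuple[float, float]]:
    """Per-reaction (min, max) flux over the cone/polyhedron.

    ``extra`` optionally adds an equality ``c^T v = d`` (an optimality
    constraint).  Unbounded directions are reported as +-inf.
    """
    lb, ub = network.cone_bounds()
    rows = None
    if extra is not None:
        c, d = extra
        rows = [(np.asarray(c, float), d, d)]
    out = []
    e = np.eye(network.r)
    for i in range(network.r):
        vals = []
        for sense in ("min", "max"):
            status, val, _ = _lp.solve(network.N, c=e[i], sense=sense,
                                       lb=lb, ub=ub, extra_rows=rows)
            if status == "infeasible":
                raise _lp.InfeasibleError(
                    "constraint system is infeasible; no flux variability")
            vals.append((-np.inf if sense == "min" else np.inf)
                        if status == "unbounded" else val)
        out.append((vals[0], vals[1]))
    return out


def make_consistent(network: MetabolicNetwork, extra_rows=None
                    ) -> tuple[MetabolicNetwork, ConsistencyReport]:
    """Remove blocked reactions and demote one-directional reversibles.

    Reactions that cannot carry flux of magnitude >= 1e-6 in any allowed
    direction are removed.  Reversible reactions feasible only backwards
    have their column negated and are flagged irreversible (recorded in
    ``fixed_backward``); reversible reactions feasible only forwards are
    flagged irreversible (``fixed_forward``).  Idempotent.
    """
    report = ConsistencyReport(n_before=network.r)
    keep, flip, demote = [], [], []
    for i, rid in enumerate(network.reaction_ids):
        fwd = _direction_feasible(network, i, True, extra_rows=extra_rows)
        bwd = (network.reversible[i]
               and _direction_feasible(network, i, False,
                                       extra_rows=extra_rows))
        if not fwd and not bwd:
            report.removed.append(rid)
            continue
        keep.append(i)
        if network.reversible[i]:
            if fwd and not bwd:
                report.fixed_forward.append(rid)
                demote.append(i)
            elif bwd and not fwd:
                report.fixed_backward.append(rid)
                flip.append(i)
                demote.append(i)
    if not keep:
        raise EmptyModelError("every reaction is blocked")
    result = network
    if flip:
        result = result.with_flipped_columns(flip)
    if demote:
        rev = result.reversible.copy()
        rev[demote] = False
        result = result.with_reversible(rev)
    if report.removed:
        result = result.subnetwork(keep)
    report.n_after = result.r
    return result, report


def _as_fraction_matrix(N: np.ndarray) -> sympy.Matrix | None:
    """Exact rational view of N, or None if entries are not rational."""
    rows = []
    for row in np.asarray(N, float):
        frow = []
        for x in row:
            f = Fraction(x).limit_denominator(10 ** 6)
            if float(f) != x:
                return None
            frow.append(sympy.Rational(f.numerator, f.denominator))
        rows.append(frow)
    return sympy.Matrix(rows)


def nullspace_basis(N: np.ndarray, free: list[int] | None = None
                    ) -> np.ndarray:
    """Basis K (r x d columns) of the nullspace of N, so that N K = 0.

    Computed in exact rational arithmetic when the coefficients are
    rational, otherwise by SVD with a relative rank tolerance of 1e-9.
    With ``free`` given, the basis is the one parametrized by those
    coordinates: the corresponding rows of K form the identity.
    """
    N = np.asarray(N, float)
    if not N.any():
        raise ModelError("stoichiometric matrix is zero")
    r = N.shape[1]
    M = _as_fraction_matrix(N)
    if free is not None:
        if M is None:
            raise ModelError("free-coordinate basis requires rational input")
        free = list(free)
        pivot = [j for j in range(r) if j not in free]
        Np = M[:, pivot]
        Nf = M[:, free]
        sol = -(Np.T * Np).inv() * Np.T * Nf  # least-squares = exact here
        if (Np * sol + Nf != sympy.zeros(N.shape[0], len(free))):
            raise ModelError("chosen free coordinates do not parametrize "
                             "the nullspace")
        K = sympy.zeros(r, len(free))
        for k, j in enumerate(free):
            K[j, k] = 1
        for k, j in enumerate(pivot):
            K[j, :] = sol[k, :]
        Kf = np.array(K.evalf(17), dtype=float)
    elif M is not None:
        basis = M.nullspace()
        if not basis:
            raise NoFluxError("trivial nullspace: only the zero flux")
        Kf = np.array(sympy.Matrix.hstack(*basis).evalf(17), dtype=float)
    else:
        _, s, vh = np.linalg.svd(N)
        rank = int((s > 1e-9 * s[0]).sum())
        Kf = vh[rank:].T
    if Kf.shape[1] == 0:
        raise NoFluxError("trivial nullspace: only the zero flux")
    return Kf


def rational_nullspace(N: np.ndarray) -> sympy.Matrix:
    """Exact rational nullspace basis as a sympy r x d matrix."""
    M = _as_fraction_matrix(N)
    if M is None:
        raise ModelError("exact nullspace requires rational coefficients")
    basis = M.nullspace()
    if not basis:
        raise NoFluxError("trivial nullspace: only the zero flux")
    return sympy.Matrix.hstack(*basis)


def reaction_dependencies(K: np.ndarray, tol: float = 1e-9
                          ) -> ReactionDependency:
    """Group reactions whose rows of the nullspace basis are proportional.

    Two rows are multiples when all their 2x2 minors vanish (below ``tol``
    after normalizing each row to unit max-abs) — a scale-invariant
    proportionality test.  The first reaction of each class (in model
    order) is its independent representative; the coupling sign is the
    sign of the scalar multiplier.
    """
    K = np.asarray(K, float)
    norms = np.abs(K).max(axis=1)
    if (norms == 0).any():
        i = int(np.flatnonzero(norms == 0)[0])
        raise InconsistencyError(
            f"zero nullspace row at reaction index {i}: blocked reaction, "
            "run make_consistent first")
    Kn = K / norms[:, None]
    independent: list[int] = []
    dependent: dict[int, tuple[int, int]] = {}
    for j in range(K.shape[0]):
        rep = None
        for i in independent:
            minors = np.abs(np.outer(Kn[i], Kn[j]) - np.outer(Kn[j], Kn[i]))
            if minors.max() < tol:
                rep = i
                break
        if rep is None:
            independent.append(j)
        else:
            pivot = int(np.argmax(np.abs(Kn[rep])))
            lam = Kn[j, pivot] / Kn[rep, pivot]
            dependent[j] = (rep, 1 if lam > 0 else -1)
    return ReactionDependency(independent=independent, dependent=dependent)


def initial_tope(network: MetabolicNetwork,
                 lb_mag: float = FLUX_LB, ub_mag: float = FLUX_UB,
                 extra_rows=None) -> tuple[FullSignVector, list[int]]:
    """Orient the network so the all-plus sign vector is a tope.

    Builds a full-support flux mode as a generic convex combination of
    per-reaction direction witnesses (consistency guarantees one exists),
    takes its sign vector, and returns the all-plus full sign vector of
    the re-oriented network together with the list of reversible reactions
    whose conventional direction had to be reversed.
    """
    lb, ub = network.cone_bounds()
    lb, ub = np.maximum(lb, -ub_mag), np.minimum(ub, ub_mag)
    witnesses = []
    for i in range(network.r):
        wlb = lb.copy()
        wlb[i] = max(wlb[i], lb_mag)
        ok, w = _lp.feasible(network.N, wlb, ub, extra_rows=extra_rows)
        if not ok:
            raise InconsistencyError(
                f"reaction {network.reaction_ids[i]!r} cannot carry forward "
                "flux; run make_consistent first")
        witnesses.append(w)
    W = np.array(witnesses)
    rng = np.random.default_rng(180733)
    for _ in range(50):
        lam = rng.uniform(0.5, 1.5, size=network.r)
        lam /= lam.sum()
        v = lam @ W
        if (np.abs(v) > SIGN_EPS).all():
            break
    else:
        raise InconsistencyError("no full-support flux mode found")
    flips = [i for i in range(network.r)
             if v[i] < 0 and network.reversible[i]]
    if any(v[i] < 0 and not network.reversible[i] for i in range(network.r)):
        raise InconsistencyError("negative flux on an irreversible reaction")
    tau = FullSignVector(np.ones(network.r, dtype=np.int8), network.irr_mask)
    return tau, flips
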