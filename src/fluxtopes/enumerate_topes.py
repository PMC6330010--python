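"""Breadth-first enumeration of flux topes.

A flux tope is the subcone of the flux cone obtained by fixing the
direction of every reaction, i.e. a full sign vector tau in {-,+}^r that is
realized by some flux mode.  Feasibility of a candidate tau is a single LP
on the sparse stoichiometric matrix:

    N v = 0,   lb_mag <= tau_i * v_i <= ub_mag   for all i

(plus box bounds and optional extra linear rows when enumerating topes of a
flux polyhedron).  Starting from an orientation in which the all-plus sign
vector is feasible, the search proceeds level by level: level n holds the
feasible sign vectors with n minus entries among the independent reversible
reactions, and the children of a level-(n-1) tope are obtained by flipping
one more independent reversible reaction (together with all reactions
coupled to it).  Candidates are deduplicated in a visited table keyed on
the packed bit pattern of independent reversible signs, so each LP is
solved at most once.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _lp
from .model import MetabolicNetwork
from .preprocess import (FLUX_LB, FLUX_UB, InconsistencyError,
                         ReactionDependency, initial_tope, is_consistent,
                         nullspace_basis, reaction_dependencies)
from .signs import FullSignVector, sign_of

log = logging.getLogger(__name__)

ExtraRows = Optional[list]


@dataclass
class FluxTope:
    """A feasible full sign vector with its LP witness flux.

    ``level`` is the number of minus entries among the independent
    reversible reactions relative to the enumeration root; ``pattern`` is
    the packed bit pattern over ``positions`` (bit set = minus relative to
    the root orientation); ``parent`` is the pattern of the first
    discovering parent (provenance only).
    """

    tau: FullSignVector
    witness: np.ndarray
    level: int
    pattern: int = 0
    positions: tuple[int, ...] = ()
    parent: int | None = None

    def sign_string(self) -> str:
        return str(self.tau)


@dataclass
class EnumerationResult:
    """Outcome of a tope enumeration run."""

    topes: list[FluxTope]
    incremental_counts: list[int]
    visited: int
    complete: bool
    reaction_ids: tuple[str, ...]
    reversible: np.ndarray
    flippable: tuple[int, ...]
    dependencies: ReactionDependency | None = None
    n_ind_rev_reported: int = 0

    def __len__(self) -> int:
        return len(self.topes)

    @property
    def cumulative_counts(self) -> list[int]:
        return np.cumsum(self.incremental_counts).tolist()

    def sign_strings(self) -> list[str]:
        return [t.sign_string() for t in self.topes]


def tope_bounds(network: MetabolicNetwork, tau: FullSignVector,
                lb_mag: float = FLUX_LB, ub_mag: float = FLUX_UB
                ) -> tuple[np.ndarray, np.ndarray] | None:
    """Variable bounds of the tope-feasibility LP, or None when the sign
    pattern already contradicts the box bounds."""
    lb, ub = network.cone_bounds()
    t = tau.entries.astype(float)
    lo = np.where(t > 0, np.maximum(lb, lb_mag), np.maximum(lb, -ub_mag))
    hi = np.where(t > 0, np.minimum(ub, ub_mag), np.minimum(ub, -lb_mag))
    if (lo > hi).any():
        return None
    return lo, hi


def check_tope_feasible(network: MetabolicNetwork, tau: FullSignVector,
                        lb_mag: float = FLUX_LB, ub_mag: float = FLUX_UB,
                        extra_rows: ExtraRows = None
                        ) -> tuple[bool, np.ndarray | None]:
    """LP feasibility of the full sign vector ``tau``.

    True (with a witness flux) iff some v satisfies N v = 0 and
    ``lb_mag <= tau_i v_i <= ub_mag`` for every reaction, inside the
    network's box bounds and any extra rows.
    """
    if not (0 < lb_mag < ub_mag):
        raise ValueError("need 0 < lb_mag < ub_mag")
    if len(tau) != network.r:
        raise ValueError("sign vector length does not match reaction count")
    b = tope_bounds(network, tau, lb_mag, ub_mag)
    if b is None:
        return False, None
    try:
        return _lp.feasible(network.N, b[0], b[1], extra_rows=extra_rows)
    except _lp.SolverError as exc:
        raise _lp.SolverError(f"{exc} (sign vector {tau})") from exc


def children(tau: FullSignVector, deps: ReactionDependency,
             flippable: Sequence[int] | None = None) -> list[FullSignVector]:
    """Sign vectors one flip further from the root.

    For each independent reversible reaction currently +, flip it to -
    together with every reaction coupled to it (a dependent flux is a fixed
    scalar multiple of its representative, so its sign always flips in
    lockstep, whatever the coupling sign).
    """
    if flippable is None:
        flippable = [i for i in deps.independent
                     if not tau.irr_mask[list(deps.members(i))].any()]
    out = []
    for i in flippable:
        if tau[i] == 1:
            out.append(tau.flipped(deps.members(i)))
    return out


def are_adjacent(t1: FluxTope, t2: FluxTope) -> bool:
    """True iff the topes differ in exactly one independent reversible
    direction (coupled reactions flip in lockstep and do not count)."""
    if len(t1.tau) != len(t2.tau):
        raise ValueError("topes live on different networks")
    if t1.positions and t1.positions == t2.positions:
        return (t1.pattern ^ t2.pattern).bit_count() == 1
    diff = np.flatnonzero(t1.tau.entries != t2.tau.entries)
    return len(diff) == 1


def _expand_entries(root: np.ndarray, pattern: int,
                    member_lists: list[list[int]]) -> np.ndarray:
    entries = root.copy()
    k = 0
    p = pattern
    while p:
        if p & 1:
            entries[member_lists[k]] *= -1
        p >>= 1
        k += 1
    return entries


def enumerate_topes(network: MetabolicNetwork, *,
                    max_level: int | None = None,
                    threads: int = 1,
                    lb_mag: float = FLUX_LB,
                    ub_mag: float = FLUX_UB,
                    limit: int | None = None,
                    extra_rows: ExtraRows = None,
                    assume_consistent: bool = False) -> EnumerationResult:
    """Enumerate all flux topes of a consistent network.

    Breadth-first over full sign vectors by number of minus entries among
    the independent reversible reactions; each candidate is LP-checked at
    most once.  The search stops when a level yields no feasible sign
    vector, when every independent reversible reaction has been flipped,
    when ``max_level`` is reached, or when ``limit`` topes have been found
    (the last two flag the result incomplete).  The returned tope set is
    deterministic and independent of ``threads``; topes are ordered by
    their packed sign bit pattern.
    """
    if not assume_consistent and not is_consistent(network, extra_rows):
        raise InconsistencyError(
            "network is not consistent; run make_consistent first")
    root_tau, flips = initial_tope(network, lb_mag, ub_mag,
                                   extra_rows=extra_rows)
    oriented = network.with_flipped_columns(flips) if flips else network
    o_extra = extra_rows
    if flips and extra_rows:
        sgn = np.ones(network.r)
        sgn[flips] = -1
        o_extra = [(np.asarray(a, float) * sgn, lo, hi)
                   for a, lo, hi in extra_rows]

    K = nullspace_basis(oriented.N)
    deps = reaction_dependencies(K)
    # a direction class can flip only if every member is reversible
    flippable = tuple(
        i for i in deps.independent
        if all(oriented.reversible[j] for j in deps.members(i)))
    member_lists = [deps.members(i) for i in flippable]
    n_ind_rev = sum(
        1 for i in deps.independent
        if any(oriented.reversible[j] for j in deps.members(i)))

    ok, w = check_tope_feasible(oriented, root_tau, lb_mag, ub_mag, o_extra)
    if not ok:
        raise InconsistencyError(
            "all-plus orientation infeasible on a consistent network")

    back = np.ones(network.r)
    back[flips] = -1  # map oriented signs/fluxes back to model orientation

    def make_tope(pattern: int, witness: np.ndarray, level: int,
                  parent: int | None) -> FluxTope:
        entries = _expand_entries(root_tau.entries.astype(np.int8).copy(),
                                  pattern, member_lists)
        orig = (entries * back).astype(np.int8)
        return FluxTope(
            tau=FullSignVector(orig, network.irr_mask),
            witness=witness * back,
            level=level, pattern=pattern,
            positions=flippable, parent=parent)

    def check_pattern(pattern: int):
        entries = _expand_entries(root_tau.entries.astype(np.int8).copy(),
                                  pattern, member_lists)
        tau = root_tau.with_entries(entries)
        return check_tope_feasible(oriented, tau, lb_mag, ub_mag, o_extra)

    topes = [make_tope(0, w, 0, None)]
    incremental = [1]
    visited: set[int] = {0}
    frontier = [0]
    n_checks = 1
    complete = True
    level = 0
    pool = ThreadPoolExecutor(threads) if threads > 1 else None
    try:
        while frontier and level < len(flippable):
            if max_level is not None and level >= max_level:
                complete = False
                break
            if limit is not None and len(topes) >= limit:
                complete = False
                break
            level += 1
            candidates: list[tuple[int, int]] = []  # (child, parent)
            seen_now: set[int] = set()
            for parent in sorted(frontier):
                for k in range(len(flippable)):
                    child = parent | (1 << k)
                    if child == parent or child in visited \
                            or child in seen_now:
                        continue
                    seen_now.add(child)
                    candidates.append((child, parent))
            visited |= seen_now
            n_checks += len(candidates)
            if pool is not None:
                outcomes = list(pool.map(
                    lambda cp: check_pattern(cp[0]), candidates))
            else:
                outcomes = [check_pattern(c) for c, _ in candidates]
            frontier = []
            found = 0
            for (child, parent), (ok, wit) in zip(candidates, outcomes):
                if ok:
                    topes.append(make_tope(child, wit, level, parent))
                    frontier.append(child)
                    found += 1
            if found:
                incremental.append(found)
                log.info("level %d: %d new topes (%d candidates checked)",
                         level, found, len(candidates))
            else:
                break
            if limit is not None and len(topes) > limit:
                complete = False
                topes = topes[:limit]
                break
    finally:
        if pool is not None:
            pool.shutdown()
    topes.sort(key=lambda t: t.pattern)
    return EnumerationResult(
        topes=topes, incremental_counts=incremental, visited=n_checks,
        complete=complete, reaction_ids=network.reaction_ids,
        reversible=network.reversible, flippable=flippable,
        dependencies=deps, n_ind_rev_reported=n_ind_rev)


def brute_force_topes(network: MetabolicNetwork, *,
                      lb_mag: float = FLUX_LB, ub_mag: float = FLUX_UB,
                      extra_rows: ExtraRows = None) -> list[FullSignVector]:
    """Exhaustive LP check of every full sign vector (oracle, small models).

    Iterates over all 2^n_rev assignments of the reversible reaction
    directions and returns the feasible ones.  Exponential; intended as an
    independent cross-check of :func:`enumerate_topes` on small networks.
    """
    import itertools

    rev_idx = np.flatnonzero(network.reversible)
    base = np.ones(network.r, dtype=np.int8)
    out = []
    for signs in itertools.product((1, -1), repeat=len(rev_idx)):
        entries = base.copy()
        entries[rev_idx] = signs
        tau = FullSignVector(entries, network.irr_mask)
        ok, _ = check_tope_feasible(network, tau, lb_mag, ub_mag, extra_rows)
        if ok:
            out.append(tau)
    return out
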