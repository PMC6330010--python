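"""Flux-balance analysis and tope enumeration on the optimal flux
polyhedron.

Fixing a linear objective c at its optimum d turns the flux polyhedron
P = {v : Nv = 0, lb <= v <= ub} into the optimal polyhedron
P* = {v in P : c^T v = d}.  Topes of P* are enumerated with the same
breadth-first search as for the cone, with the box bounds and the
optimality window carried inside the feasibility LP — so the optimal
direction combinations are found directly, without enumerating all cone
topes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _lp
from .enumerate_topes import EnumerationResult, enumerate_topes
from .model import MetabolicNetwork
from .preprocess import FLUX_LB, ConsistencyReport, flux_variability


@dataclass
class FluxPolyhedron:
    """A flux set under box bounds, optionally sliced at an optimum.

    ``optimality`` holds (c, d_opt, tol): members must satisfy
    d_opt - tol <= c^T v <= d_opt.
    """

    network: MetabolicNetwork
    lb: np.ndarray = None
    ub: np.ndarray = None
    optimality: tuple[np.ndarray, float, float] | None = None

    def __post_init__(self):
        lo, hi = self.network.cone_bounds()
        self.lb = lo if self.lb is None else np.asarray(self.lb, float)
        self.ub = hi if self.ub is None else np.asarray(self.ub, float)

    def extra_rows(self) -> list | None:
        if self.optimality is None:
            return None
        c, d, tol = self.optimality
        return [(np.asarray(c, float), d - tol, d)]


def _coerce(p) -> FluxPolyhedron:
    return p if isinstance(p, FluxPolyhedron) else FluxPolyhedron(network=p)


def fba(polyhedron: FluxPolyhedron | MetabolicNetwork, c: np.ndarray
        ) -> tuple[float, np.ndarray]:
    """Maximize c^T v over the flux polyhedron.

    Returns the optimal value and one optimal flux.  Raises on infeasible
    or unbounded problems; in the unbounded case a recession ray along
    which the objective grows is named in the error.
    """
    p = _coerce(polyhedron)
    c = np.asarray(c, float)
    status, val, x = _lp.solve(p.network.N, c=c, sense="max",
                               lb=p.lb, ub=p.ub,
                               extra_rows=p.extra_rows())
    if status == "infeasible":
        raise _lp.InfeasibleError("flux polyhedron is empty")
    if status == "unbounded":
        ray = _recession_ray(p, c)
        raise _lp.UnboundedError(
            "objective unbounded over the flux polyhedron; improving ray "
            f"{np.round(ray, 6).tolist()}")
    return val, x


def _recession_ray(p: FluxPolyhedron, c: np.ndarray) -> np.ndarray:
    """A recession direction of P with c^T d = 1 (exists iff unbounded)."""
    lo = np.where(np.isfinite(p.lb), 0.0, -np.inf)
    hi = np.where(np.isfinite(p.ub), 0.0, np.inf)
    ok, x = _lp.feasible(p.network.N, lo, hi,
                         extra_rows=[(c, 1.0, 1.0)])
    return x if ok else np.full(p.network.r, np.nan)


def optimal_polyhedron(polyhedron: FluxPolyhedron | MetabolicNetwork,
                       c: np.ndarray, d_opt: float,
                       tol: float | None = None) -> FluxPolyhedron:
    """Slice the polyhedron at the optimum c^T v = d_opt.

    ``tol`` defaults to 1e-6 * max(1, |d_opt|) to absorb solver-level
    jitter of the optimum.  Flux variability analysis on the slice then
    demotes reversible reactions that lost one direction to irreversible
    (negating the column when only the backward direction survives), so
    that all topes of the optimal polyhedron have full support.  Reactions
    forced to (near-)zero flux at the optimum are dropped from the
    returned network and listed in the attached consistency report.
    """
    p = _coerce(polyhedron)
    c = np.asarray(c, float)
    if tol is None:
        tol = 1e-6 * max(1.0, abs(d_opt))
    net = p.network
    if p.lb is not None or p.ub is not None:
        from dataclasses import replace
        net = replace(net, lb=np.maximum(p.lb, net.cone_bounds()[0]),
                      ub=p.ub)
    rows = [(c, d_opt - tol, d_opt)]
    ok, _ = _lp.feasible(net.N, *net.cone_bounds(), extra_rows=rows)
    if not ok:
        raise _lp.InfeasibleError(
            f"optimum {d_opt} not attainable within tolerance {tol}")
    from .preprocess import make_consistent
    consistent, report = make_consistent(net, extra_rows=rows)
    kept = [i for i, rid in enumerate(net.reaction_ids)
            if rid not in report.removed]
    c_kept = c[kept]
    out = FluxPolyhedron(network=consistent,
                         optimality=(c_kept, d_opt, tol))
    out.report = report
    return out


@dataclass
class OptimalTopesResult:
    """Topes of the optimal flux polyhedron plus how it was built."""

    result: EnumerationResult
    d_opt: float
    v_opt: np.ndarray
    report: ConsistencyReport
    objective: np.ndarray

    def __len__(self) -> int:
        return len(self.result)


def enumerate_optimal_topes(network: MetabolicNetwork, c: np.ndarray,
                            *, max_level: int | None = None,
                            threads: int = 1, limit: int | None = None,
                            lb_mag: float = FLUX_LB,
                            ub_mag: float = 1e3) -> OptimalTopesResult:
    """Enumerate the topes that attain max c^T v over the flux polyhedron.

    Composes :func:`fba`, the optimal-polyhedron slice with its
    consistency pass, and the breadth-first tope search with the
    optimality window inside every feasibility LP.
    """
    c = np.asarray(c, float)
    p = _coerce(network if isinstance(network, FluxPolyhedron) else network)
    d_opt, v_opt = fba(p, c)
    pstar = optimal_polyhedron(p, c, d_opt)
    result = enumerate_topes(
        pstar.network, max_level=max_level, threads=threads, limit=limit,
        lb_mag=lb_mag, ub_mag=ub_mag, extra_rows=pstar.extra_rows(),
        assume_consistent=True)
    return OptimalTopesResult(result=result, d_opt=d_opt, v_opt=v_opt,
                              report=pstar.report, objective=c)
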