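"""Elementary flux mode enumeration, one tope at a time.

Inside a flux tope every reaction direction is fixed, so after orienting
all columns of N along the tope's sign vector the tope becomes the
nonnegative cone {v : N v = 0, v >= 0} and its extreme rays — the EFMs
conforming to the tope — can be enumerated with the double description
method *without* splitting reversible reactions into forward/backward
pairs.  The union of the per-tope EFM sets over all topes is the full EFM
set of the network; EFMs shared between topes are removed by a canonical
integer normalization.

The double description runs in exact rational arithmetic (Fractions) in
nullspace coordinates: with K an r x d rational nullspace basis of the
oriented N, the tope is isomorphic to {x in R^d : K x >= 0 row-wise}, a
pointed cone cut out by r halfspaces, and extreme rays are preserved by
the isomorphism v = K x.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd

import numpy as np
import sympy

from .enumerate_topes import (EnumerationResult, check_tope_feasible,
                              enumerate_topes)
from .model import MetabolicNetwork
from .preprocess import rational_nullspace
from .signs import FullSignVector, SignVector, sign_of

Ray = tuple[Fraction, ...]


@dataclass(frozen=True)
class EFM:
    """A support-minimal flux mode, normalized to a primitive integer
    vector (entries coprime, orientation as in the model)."""

    flux: tuple[int, ...]

    @property
    def support(self) -> frozenset[int]:
        return frozenset(i for i, x in enumerate(self.flux) if x != 0)

    @property
    def sign_vector(self) -> SignVector:
        return SignVector([0 if x == 0 else (1 if x > 0 else -1)
                           for x in self.flux])

    def conforms_to(self, tau: FullSignVector) -> bool:
        return self.sign_vector.conforms(tau)

    def as_array(self) -> np.ndarray:
        return np.array(self.flux, dtype=float)


@dataclass
class EFMSet:
    """EFMs of one tope (``tope`` = its sign vector) or of the whole
    network (``tope`` = "global")."""

    efms: list[EFM]
    tope: FullSignVector | str

    def __len__(self) -> int:
        return len(self.efms)

    def __iter__(self):
        return iter(self.efms)

    def keys(self) -> set[tuple[int, ...]]:
        return {e.flux for e in self.efms}


def _primitive(vec: list[Fraction]) -> tuple[int, ...]:
    """Scale a rational vector to coprime integers (first normalizing the
    sign is unnecessary: the orientation is fixed by the tope)."""
    den = 1
    for f in vec:
        den = den * f.denominator // gcd(den, f.denominator)
    ints = [int(f * den) for f in vec]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    return tuple(ints)


def _dot(a: Ray, b: Ray) -> Fraction:
    return sum((x * y for x, y in zip(a, b)), Fraction(0))


def _nonsingular_rows(rows: list[Ray], d: int) -> list[int]:
    """Greedy choice of d rows forming a nonsingular matrix (rational
    Gaussian elimination)."""
    chosen: list[int] = []
    basis: list[list[Fraction]] = []
    for idx, row in enumerate(rows):
        v = list(row)
        for b in basis:
            # eliminate along b's pivot
            p = next(k for k, x in enumerate(b) if x != 0)
            if v[p] != 0:
                f = v[p] / b[p]
                v = [x - f * y for x, y in zip(v, b)]
        if any(x != 0 for x in v):
            basis.append(v)
            chosen.append(idx)
            if len(chosen) == d:
                return chosen
    raise ValueError("constraint rows do not have full rank")


def double_description(rows: list[Ray], d: int) -> list[Ray]:
    """Extreme rays of the pointed cone {x in R^d : a.x >= 0 for a in rows}.

    Incremental Motzkin double description: start from a simplicial cone
    given by d linearly independent rows, then insert the remaining
    halfspaces one at a time (rows with most zeros first), combining
    adjacent positive/negative rays on each cut.  Adjacency uses the
    combinatorial test: two rays are adjacent iff no third ray's active
    set contains the intersection of theirs.
    """
    init_idx = _nonsingular_rows(rows, d)
    B = sympy.Matrix([[sympy.Rational(f) for f in rows[i]]
                      for i in init_idx])
    Binv = B.inv()
    rays: list[Ray] = []
    for j in range(d):
        col = [Fraction(sympy.Rational(Binv[i, j])) for i in range(d)]
        rays.append(tuple(col))
    remaining = [i for i in range(len(rows)) if i not in init_idx]
    remaining.sort(key=lambda i: -sum(1 for x in rows[i] if x == 0))
    processed = list(init_idx)

    def active_set(ray: Ray) -> frozenset[int]:
        return frozenset(i for i in processed if _dot(rows[i], ray) == 0)

    for i in remaining:
        a = rows[i]
        vals = [_dot(a, ray) for ray in rays]
        pos = [k for k, s in enumerate(vals) if s > 0]
        neg = [k for k, s in enumerate(vals) if s < 0]
        zero = [k for k, s in enumerate(vals) if s == 0]
        if not neg:
            processed.append(i)
            continue
        actives = [active_set(r) for r in rays]
        new_rays: list[Ray] = []
        for p in pos:
            for n in neg:
                meet = actives[p] & actives[n]
                if len(meet) < d - 2:
                    continue
                adjacent = all(
                    k in (p, n) or not meet <= actives[k]
                    for k in range(len(rays)))
                if not adjacent:
                    continue
                comb = [vals[p] * rays[n][t] - vals[n] * rays[p][t]
                        for t in range(d)]
                new_rays.append(tuple(Fraction(x) for x in comb))
        kept = [rays[k] for k in pos + zero]
        # normalize new rays to primitive form for deduplication
        seen = set()
        for ray in new_rays:
            key = _primitive(list(ray))
            if key not in seen:
                seen.add(key)
                kept.append(tuple(Fraction(x) for x in key))
        rays = kept
        processed.append(i)
    return rays


def enumerate_efms_in_tope(network: MetabolicNetwork, tau: FullSignVector
                           ) -> EFMSet:
    """All EFMs conforming to the tope ``tau`` (its extreme rays)."""
    ok, _ = check_tope_feasible(network, tau)
    if not ok:
        raise ValueError(f"sign vector {tau} is not a feasible tope")
    signs = tau.entries.astype(float)
    N_oriented = network.N * signs  # negate the minus columns
    K = rational_nullspace(N_oriented)
    d = K.shape[1]
    rows = [tuple(Fraction(sympy.Rational(K[i, j]).p,
                           sympy.Rational(K[i, j]).q)
                  for j in range(d))
            for i in range(K.shape[0])]
    xs = double_description(rows, d)
    efms = []
    seen = set()
    for x in xs:
        v = [sum((rows[i][j] * x[j] for j in range(d)), Fraction(0))
             for i in range(network.r)]
        v = [int(tau[i]) * v[i] for i in range(network.r)]  # back to model
        key = _primitive(v)
        if any(key) and key not in seen:
            seen.add(key)
            efms.append(EFM(flux=key))
    return EFMSet(efms=efms, tope=tau)


def enumerate_efms_via_topes(network: MetabolicNetwork, *,
                             threads: int = 1,
                             result: EnumerationResult | None = None
                             ) -> tuple[EFMSet, dict]:
    """Global EFM set assembled tope by tope.

    Runs the tope enumeration (unless a complete ``result`` is supplied),
    enumerates the EFMs of every tope, and deduplicates them by their
    primitive integer normalization.  Returns the global set and a summary
    with per-tope counts and the duplication factor (total per-tope slots
    divided by distinct EFMs).
    """
    if result is None:
        result = enumerate_topes(network, threads=threads)
    per_tope: dict[str, int] = {}
    global_efms: dict[tuple[int, ...], EFM] = {}
    slots = 0
    for tope in result.topes:
        efm_set = enumerate_efms_in_tope(network, tope.tau)
        per_tope[str(tope.tau)] = len(efm_set)
        slots += len(efm_set)
        for e in efm_set:
            global_efms.setdefault(e.flux, e)
    summary = {
        "per_tope_counts": per_tope,
        "n_topes": len(result.topes),
        "n_efms": len(global_efms),
        "duplication_factor": slots / max(1, len(global_efms)),
    }
    return EFMSet(efms=list(global_efms.values()), tope="global"), summary


def conformal_decomposition_check(v: np.ndarray, efms: EFMSet,
                                  tol: float = 1e-6
                                  ) -> tuple[bool, np.ndarray | None]:
    """Certify that ``v`` is a nonnegative combination of conformal EFMs.

    Selects the EFMs whose signs do not conflict with ``v`` and solves the
    feasibility LP sum_k lambda_k e_k = v, lambda >= 0.  Returns the
    certificate coefficients on success.
    """
    v = np.asarray(v, float)
    sv = sign_of(v).entries.astype(int)
    cols = [e for e in efms
            if ((e.sign_vector.entries.astype(int) * sv) >= 0).all()]
    if not cols:
        return bool(np.allclose(v, 0, atol=tol)), np.zeros(0)
    E = np.array([c.as_array() for c in cols]).T  # r x k
    k = E.shape[1]
    from scipy.optimize import linprog
    res = linprog(np.zeros(k), A_eq=E, b_eq=v,
                  bounds=[(0, None)] * k, method="highs")
    if res.status != 0:
        return False, None
    resid = np.abs(E @ res.x - v).max()
    if resid > tol * (1 + np.abs(v).max()):
        return False, None
    return True, res.x


def verify_tope_efm_duality(network: MetabolicNetwork) -> dict:
    """Check the correspondence between topes and maximal conformal EFM
    sets on a network small enough for global enumeration.

    Verifies that (a) the EFMs enumerated inside each tope are exactly the
    global EFMs conforming to its sign vector, (b) each per-tope set is a
    maximal conformal set (every outside EFM conflicts with some member),
    and (c) the union over topes is the global set.  Returns a report with
    any violations listed.
    """
    result = enumerate_topes(network)
    global_set, summary = enumerate_efms_via_topes(network, result=result)
    violations = {"conforming_mismatch": [], "not_maximal": []}
    union: set[tuple[int, ...]] = set()
    for tope in result.topes:
        inside = enumerate_efms_in_tope(network, tope.tau)
        union |= inside.keys()
        conforming = {e.flux for e in global_set if e.conforms_to(tope.tau)}
        if inside.keys() != conforming:
            violations["conforming_mismatch"].append(str(tope.tau))
        members = [e for e in global_set if e.flux in inside.keys()]
        outside = [e for e in global_set if e.flux not in inside.keys()]
        for e in outside:
            ev = e.sign_vector.entries.astype(int)
            if all(((m.sign_vector.entries.astype(int) * ev) >= 0).all()
                   for m in members):
                violations["not_maximal"].append((str(tope.tau), e.flux))
    ok = (not violations["conforming_mismatch"]
          and not violations["not_maximal"]
          and union == global_set.keys())
    return {
        "ok": ok,
        "union_equals_global": union == global_set.keys(),
        "violations": violations,
        **summary,
    }


def support_minimal(network: MetabolicNetwork, efm: EFM) -> bool:
    """Algebraic support-minimality: restricted to its support, the system
    {N_support w = 0, signs fixed} has a one-dimensional solution space."""
    sup = sorted(efm.support)
    if not sup:
        return False
    Ns = network.N[:, sup]
    rank = np.linalg.matrix_rank(Ns)
    return rank == len(sup) - 1
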