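"""Post-enumeration analytics on a set of flux topes.

Given a (complete) tope enumeration, these helpers quantify how reaction
directions are coordinated across the network: the adjacency structure of
the tope graph, per-reaction forward-direction frequencies, the pairwise
direction-combination matrix, and a Gaussian extrapolation of the per-level
tope counts that predicts the total count from a truncated breadth-first
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.optimize import curve_fit

from .enumerate_topes import EnumerationResult


class FitFailureError(RuntimeError):
    """The Gaussian fit to the level counts did not converge sensibly."""


def adjacency_histogram(result: EnumerationResult) -> dict[int, int]:
    """Frequency of the number of adjacent topes.

    Two topes are adjacent when they differ in exactly one independent
    reversible direction.  Requires a complete enumeration — adjacency
    counts on a truncated set would be biased low.
    """
    if not result.complete:
        raise ValueError("adjacency is undefined on a partial enumeration")
    patterns = {t.pattern for t in result.topes}
    n_bits = len(result.flippable)
    hist: dict[int, int] = {}
    for p in patterns:
        n = sum(1 for k in range(n_bits) if (p ^ (1 << k)) in patterns)
        hist[n] = hist.get(n, 0) + 1
    return hist


def direction_frequencies(result: EnumerationResult) -> dict[str, float]:
    """Fraction of topes that use each reaction in the forward direction.

    Irreversible reactions always run forward and are reported as 1.0.
    """
    if not result.topes:
        raise ValueError("empty tope set")
    n = len(result.topes)
    freq: dict[str, float] = {}
    for i, rid in enumerate(result.reaction_ids):
        if not result.reversible[i]:
            freq[rid] = 1.0
        else:
            fwd = sum(1 for t in result.topes if t.tau[i] == 1)
            freq[rid] = fwd / n
    return freq


@dataclass
class PairDirectionMatrix:
    """Tope counts for every direction combination of reaction pairs.

    ``counts[(a, b)][(sa, sb)]`` is the number of topes in which reversible
    reaction ``a`` runs in direction ``sa`` (+1/-1) and ``b`` in ``sb``;
    pairs are stored with a < b in reaction order and are symmetric under
    swapping.  Direction combinations supported by no tope are collected in
    ``infeasible_pairs``.
    """

    reactions: list[str]
    counts: dict[tuple[str, str], dict[tuple[int, int], int]]
    infeasible_pairs: list[tuple[str, int, str, int]] = field(
        default_factory=list)
    n_topes: int = 0

    def frequency(self, a: str, sa: int, b: str, sb: int) -> float:
        if (a, b) in self.counts:
            return self.counts[(a, b)][(sa, sb)] / self.n_topes
        return self.counts[(b, a)][(sb, sa)] / self.n_topes


def pair_direction_matrix(result: EnumerationResult) -> PairDirectionMatrix:
    """Count topes for each direction combination of reversible pairs."""
    rev = [i for i in range(len(result.reaction_ids)) if result.reversible[i]]
    if len(rev) < 2:
        raise ValueError("need at least two reversible reactions")
    ids = list(result.reaction_ids)
    counts: dict = {}
    for ai in range(len(rev)):
        for bi in range(ai + 1, len(rev)):
            a, b = rev[ai], rev[bi]
            cell = {(sa, sb): 0 for sa in (1, -1) for sb in (1, -1)}
            for t in result.topes:
                cell[(t.tau[a], t.tau[b])] += 1
            counts[(ids[a], ids[b])] = cell
    infeasible = [(a, sa, b, sb)
                  for (a, b), cell in counts.items()
                  for (sa, sb), n in cell.items() if n == 0]
    return PairDirectionMatrix(
        reactions=[ids[i] for i in rev], counts=counts,
        infeasible_pairs=infeasible, n_topes=len(result.topes))


def signed_pair_count(n_rev: int) -> int:
    """Number of unordered pairs of signed reaction directions among
    ``n_rev`` reversible reactions: C(2*n_rev, 2)."""
    if n_rev < 0:
        raise ValueError("n_rev must be nonnegative")
    return comb(2 * n_rev, 2)


@dataclass
class GaussianFit:
    """Normal curve fitted to the incremental per-level tope counts."""

    mu: float
    sigma: float
    amplitude: float
    total_estimate: float
    observed_total: float
    diagnostics: dict = field(default_factory=dict)


def _gauss(n, a, mu, sigma):
    return a * np.exp(-((n - mu) ** 2) / (2.0 * sigma ** 2))


def fit_incremental_gaussian(incremental_counts, observed_through: int,
                             n_levels_total: int | None = None
                             ) -> GaussianFit:
    """Extrapolate the total tope count from a truncated breadth-first run.

    Fits a * exp(-(n - mu)^2 / (2 sigma^2)) by least squares to the
    incremental counts observed through level ``observed_through`` and sums
    the fitted curve over the integer levels 0..n_levels_total (default:
    mu + 8 sigma) to predict the total.  The prediction is floored at the
    observed cumulative count.
    """
    counts = np.asarray(incremental_counts, float)[: observed_through + 1]
    levels = np.arange(counts.size, dtype=float)
    if (counts > 0).sum() < 4:
        raise FitFailureError("need at least 4 observed positive levels")
    # Initialize from the log-parabola (exact for noise-free Gaussian
    # counts, and well-posed even when only the rising flank is observed),
    # then refine by least squares on the raw counts.
    pos = counts > 0
    b2, b1, b0 = np.polyfit(levels[pos], np.log(counts[pos]), 2)
    if b2 < 0:
        sigma0 = float(np.sqrt(-1.0 / (2.0 * b2)))
        mu0 = float(-b1 / (2.0 * b2))
        a0 = float(np.exp(b0 - b1 ** 2 / (4.0 * b2)))
    else:  # log counts convex: no interior mode visible
        a0, mu0, sigma0 = counts.max(), float(levels[-1]), counts.size / 2.0
    try:
        popt, _ = curve_fit(
            _gauss, levels, counts,
            p0=[max(a0, 1e-12), max(mu0, 0.0), max(sigma0, 0.25)],
            bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"Gaussian fit did not converge: {exc}") from exc
    a, mu, sigma = popt
    if not np.all(np.isfinite(popt)) or sigma < 1e-4:
        raise FitFailureError(f"degenerate fit: sigma = {sigma:g}")
    if sigma > 1e5 or mu > 1e6:
        raise FitFailureError(
            f"degenerate fit: mu = {mu:g}, sigma = {sigma:g} (the level "
            "counts carry no peak information)")
    top = n_levels_total if n_levels_total is not None \
        else int(np.ceil(mu + 8 * sigma))
    grid = np.arange(0, top + 1, dtype=float)
    observed_total = float(counts.sum())
    total = max(float(_gauss(grid, a, mu, sigma).sum()), observed_total)
    resid = counts - _gauss(levels, a, mu, sigma)
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    diagnostics = {
        "r_squared": 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot else 0.0,
        "n_levels_observed": int(counts.size),
        "degenerate": bool(sigma > 10 * counts.size),
    }
    return GaussianFit(mu=float(mu), sigma=float(sigma), amplitude=float(a),
                       total_estimate=total, observed_total=observed_total,
                       diagnostics=diagnostics)
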