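"""Sign-vector algebra and arrangement combinatorics.

A sign vector records the direction of every reaction flux as one of the
three symbols ``-``, ``0``, ``+``.  The conformal partial order (``0`` below
both signs, signs incomparable) turns the set of sign vectors of the flux
cone into a poset whose maximal elements define flux topes and whose minimal
nonzero elements are the sign patterns of elementary flux modes.

Internally a sign vector is a small immutable wrapper around an ``int8``
array with values in {-1, 0, +1}; full (zero-free) sign vectors additionally
carry the irreversibility mask and can be packed into an integer bit pattern
(one bit per reversible position) for hashing inside the enumeration tree.
"""

from __future__ import annotations

from math import comb
from typing import Iterable, Sequence

import numpy as np

#: Zero tolerance for extracting signs from floating-point fluxes.  Chosen
#: three orders of magnitude below the LP flux lower bound (1e-6) and well
#: above solver feasibility tolerance (<=1e-10), so witness fluxes never
#: straddle the threshold.
SIGN_EPS = 1e-9

_SYMBOLS = {-1: "-", 0: "0", 1: "+"}
_VALUES = {"-": -1, "0": 0, "+": 1}


def _as_entries(entries: Iterable[int]) -> np.ndarray:
    arr = np.asarray(list(entries) if not isinstance(entries, np.ndarray) else entries,
                     dtype=np.int8)
    if arr.ndim != 1:
        raise ValueError("sign vector entries must be one-dimensional")
    if not np.isin(arr, (-1, 0, 1)).all():
        raise ValueError("sign vector entries must be -1, 0 or +1")
    return arr


class SignVector:
    """An element of {-,0,+}^r, ordered by conformality."""

    __slots__ = ("_entries",)

    def __init__(self, entries: Iterable[int] | str):
        if isinstance(entries, str):
            try:
                entries = [_VALUES[c] for c in entries]
            except KeyError as exc:
                raise ValueError(f"invalid sign symbol {exc.args[0]!r}") from exc
        self._entries = _as_entries(entries)
        self._entries.setflags(write=False)

    @property
    def entries(self) -> np.ndarray:
        return self._entries

    def __len__(self) -> int:
        return self._entries.size

    def __getitem__(self, i: int) -> int:
        return int(self._entries[i])

    def __iter__(self):
        return iter(int(v) for v in self._entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignVector):
            return NotImplemented
        return (len(self) == len(other)
                and bool(np.array_equal(self._entries, other._entries)))

    def __hash__(self) -> int:
        return hash(self._entries.tobytes())

    def __repr__(self) -> str:
        return f"{type(self).__name__}('{self}')"

    def __str__(self) -> str:
        return "".join(_SYMBOLS[int(v)] for v in self._entries)

    @property
    def support(self) -> np.ndarray:
        """Indices of the nonzero entries."""
        return np.flatnonzero(self._entries)

    def has_full_support(self) -> bool:
        return bool((self._entries != 0).all())

    def conforms(self, other: "SignVector") -> bool:
        """True iff self <= other in the conformal order.

        Every nonzero entry of ``self`` must equal the corresponding entry
        of ``other``; zeros of ``self`` are below everything.
        """
        if len(self) != len(other):
            raise ValueError(
                f"length mismatch: {len(self)} vs {len(other)}")
        a, b = self._entries, other._entries
        return bool(((a == 0) | (a == b)).all())

    def negated(self) -> "SignVector":
        return SignVector(-self._entries)


class FullSignVector(SignVector):
    """A zero-free sign vector with + at every irreversible position.

    Full sign vectors are the candidates for flux topes: they fix the
    direction of every reaction.  ``irr_mask`` marks the irreversible
    positions, which are pinned to +.
    """

    __slots__ = ("_irr_mask",)

    def __init__(self, entries: Iterable[int] | str, irr_mask: Iterable[bool]):
        super().__init__(entries)
        mask = np.asarray(list(irr_mask) if not isinstance(irr_mask, np.ndarray)
                          else irr_mask, dtype=bool)
        if mask.shape != self._entries.shape:
            raise ValueError("irr_mask length must match entries")
        if (self._entries == 0).any():
            raise ValueError("a full sign vector has no zero entries")
        if (self._entries[mask] != 1).any():
            raise ValueError("irreversible positions must carry +")
        self._irr_mask = mask
        self._irr_mask.setflags(write=False)

    @property
    def irr_mask(self) -> np.ndarray:
        return self._irr_mask

    def with_entries(self, entries: Sequence[int]) -> "FullSignVector":
        return FullSignVector(entries, self._irr_mask)

    def flipped(self, positions: Iterable[int]) -> "FullSignVector":
        """Return a copy with the entries at ``positions`` negated."""
        new = self._entries.copy()
        for i in positions:
            if self._irr_mask[i]:
                raise ValueError(f"cannot flip irreversible position {i}")
            new[i] = -new[i]
        return FullSignVector(new, self._irr_mask)

    def minus_count(self, positions: Sequence[int] | None = None) -> int:
        """Number of minus entries, optionally restricted to ``positions``."""
        e = self._entries if positions is None else self._entries[list(positions)]
        return int((e == -1).sum())


def sign_of(x, eps: float = SIGN_EPS) -> SignVector:
    """Component-wise sign of a real vector, with zero tolerance ``eps``.

    Entry i is + if x_i > eps, - if x_i < -eps and 0 otherwise.
    """
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("sign_of requires finite entries")
    return SignVector(np.sign(arr * (np.abs(arr) > eps)).astype(np.int8))


def conforms(xi: SignVector, eta: SignVector) -> bool:
    """True iff ``xi`` <= ``eta`` componentwise in the conformal order."""
    return xi.conforms(eta)


def is_conformal(x, y, eps: float = SIGN_EPS) -> bool:
    """True iff x_i * y_i >= 0 for all i (no sign conflict).

    Equivalent to the existence of a sign vector above both sign(x) and
    sign(y).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    sa, sb = sign_of(a, eps).entries, sign_of(b, eps).entries
    return bool((sa.astype(int) * sb.astype(int) >= 0).all())


def cell_upper_bound(r: int, d: int) -> int:
    """Maximum number of cells of a central arrangement of ``r`` distinct
    hyperplanes in dimension ``d``: 2 * sum_{i<d} C(r-1, i).

    Equals 2**r when d >= r (every full sign vector is a cell).
    """
    if r < 1 or d < 1:
        raise ValueError("r and d must be positive")
    if d >= r:
        return 2 ** r
    return 2 * sum(comb(r - 1, i) for i in range(d))


def tope_upper_bound(n_rev: int) -> int:
    """Trivial bound 2**n_rev on the number of flux topes.

    ``n_rev`` counts the independent reversible reactions; with none of
    them the cone is a single tope.
    """
    if n_rev < 0:
        raise ValueError("n_rev must be nonnegative")
    return 2 ** n_rev


def pack_bits(tau: FullSignVector, positions: Sequence[int]) -> int:
    """Pack the signs at ``positions`` into an int (bit set = minus)."""
    pattern = 0
    for k, i in enumerate(positions):
        if tau[i] == -1:
            pattern |= 1 << k
    return pattern


def unpack_bits(pattern: int, positions: Sequence[int]) -> list[int]:
    """Positions whose bit is set (minus) in ``pattern``."""
    return [i for k, i in enumerate(positions) if pattern >> k & 1]
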