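"""Coincidence distances: observed recurrence gaps and the first-collision law.

Two related quantities live here.

* The *observed* coincidence distance of a symbol: for consecutive
  occurrences at positions j1 < j2 (0- or 1-based, it cancels), the
  distance is D = j2 - j1 + 1, i.e. the first occurrence is counted as
  draw 1 and the repeat as draw D.  In ``abcdabc`` the symbol ``a``
  recurs at distance 5.  All consecutive pairs contribute to the mean
  ``D_bar``, which maximizes the data used at small sample sizes.

* The *model* first-coincidence law f(n; M): the probability that, in
  i.i.d. draws from a rank distribution, the first repeat of any symbol
  happens exactly at draw n.  The no-repeat (survival) probability after
  n draws is F~(n) = n! * e_n(p), where e_n is the n-th elementary
  symmetric polynomial of the symbol probabilities — for an equiprobable
  alphabet this reduces to the classic birthday product
  prod_{h=2..n} (1 - (h-1)/M).  The per-draw repeat probability is
  P_h = 1 - F~(h)/F~(h-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_corpus import SymbolSequence
from .zipf_models import RankedDistribution


class NoCoincidenceError(ValueError):
    """A symbol did not occur at least twice, so no distance exists."""

    def __init__(self, symbol: str, occurrences: int):
        self.symbol = symbol
        self.occurrences = occurrences
        super().__init__(
            f"symbol {symbol!r} occurs {occurrences} time(s); "
            "at least 2 occurrences are needed for a coincidence distance"
        )


@dataclass(frozen=True)
class CoincidenceStats:
    """Observed inter-occurrence distances for one symbol."""

    symbol: str
    rank: int | None
    distances: np.ndarray
    expected: float | None = None

    @property
    def D_bar(self) -> float:
        return float(self.distances.mean())

    @property
    def k(self) -> int:
        """Number of coincidences (distance observations)."""
        return int(self.distances.size)


@dataclass(frozen=True)
class CoincidencePMF:
    """First-coincidence probability mass f(n), n = 2..n_max."""

    M: int
    n: np.ndarray          # support values 2..n_max
    f: np.ndarray          # mass at each n
    survival: np.ndarray   # F~(n): no repeat in the first n draws
    per_draw: np.ndarray   # P_h: repeat at draw h given no repeat before

    @property
    def F(self) -> np.ndarray:
        """Cumulative coincidence probability up to each n."""
        return np.cumsum(self.f)

    def to_tsv(self) -> str:
        lines = ["n\tf\tF\tsurvival"]
        F = self.F
        for i, n in enumerate(self.n):
            lines.append(f"{n}\t{self.f[i]:.17g}\t{F[i]:.17g}\t{self.survival[i]:.17g}")
        return "\n".join(lines) + "\n"


def observed_distances(
    seq: SymbolSequence, symbol: str, rank: int | None = None
) -> CoincidenceStats:
    """Distances between consecutive occurrences of ``symbol`` in ``seq``."""
    idx = seq.alphabet.index()
    if symbol not in idx:
        raise NoCoincidenceError(symbol, 0)
    positions = np.flatnonzero(seq.codes == idx[symbol])
    if positions.size < 2:
        raise NoCoincidenceError(symbol, int(positions.size))
    distances = np.diff(positions) + 1
    return CoincidenceStats(symbol=symbol, rank=rank,
                            distances=distances.astype(np.int64))


def empirical_rank_order(codes: np.ndarray, M: int) -> np.ndarray:
    """Symbol codes ordered by decreasing count, ties by first occurrence.

    Only observed symbols appear in the result.  This is the operational
    ranking used both when estimating from data and when calibrating the
    distance model, so any selection effect of picking the empirically
    most frequent symbol is identical in both places.
    """
    counts = np.bincount(codes, minlength=M)
    observed = np.flatnonzero(counts > 0)
    first = np.full(M, codes.size, dtype=np.int64)
    # reversed scan: earlier positions overwrite later ones
    first[codes[::-1]] = np.arange(codes.size - 1, -1, -1)
    order = np.lexsort((first[observed], -counts[observed]))
    return observed[order]


def rank_symbol(seq: SymbolSequence, r: int) -> str:
    """The r-th most frequent symbol; ties broken by first occurrence."""
    if seq.N == 0:
        raise ValueError("cannot rank symbols of an empty sequence")
    order = empirical_rank_order(seq.codes, seq.alphabet.M)
    if not 1 <= r <= order.size:
        raise ValueError(
            f"rank {r} exceeds the {order.size} distinct observed symbols"
        )
    return seq.alphabet.symbols[order[r - 1]]


def _survival_equiprobable(M: int, n_max: int) -> np.ndarray:
    """F~(n) for n = 1..n_max under an equiprobable M-alphabet."""
    h = np.arange(2, n_max + 1, dtype=float)
    factors = 1.0 - (h - 1.0) / M
    factors = np.clip(factors, 0.0, None)
    return np.concatenate([[1.0], np.cumprod(factors)])


def _elementary_symmetric(p: np.ndarray, n_top: int) -> np.ndarray:
    """e_0..e_n_top of the values in p.

    One DP pass per symbol; the right-hand side is evaluated on the old
    array before assignment, so each step is e_j <- e_j + p * e_{j-1}.
    """
    e = np.zeros(n_top + 1)
    e[0] = 1.0
    for prob in p:
        e[1 : n_top + 1] = e[1 : n_top + 1] + prob * e[0:n_top]
    return e


def first_coincidence_pmf(
    dist: RankedDistribution | None = None,
    M: int | None = None,
    n_max: int | None = None,
) -> CoincidencePMF:
    """First-coincidence PMF under a rank distribution or equiprobable(M).

    Exactly one of ``dist`` (any rank distribution) or ``M``
    (equiprobable shortcut) must be given.  Support runs to ``n_max``
    (default: one past the alphabet size, where a repeat is forced).
    """
    if (dist is None) == (M is None):
        raise ValueError("give exactly one of dist= or M=")
    if dist is not None:
        p = dist.p
        K = p.size
        if n_max is None:
            n_max = K + 1
        if n_max < 2:
            raise ValueError("n_max must be >= 2")
        n_top = min(n_max, K)
        e = _elementary_symmetric(p, n_top)
        factorials = np.cumprod(np.concatenate([[1.0], np.arange(1, n_top + 1)]))
        surv_core = factorials * e  # F~(0)..F~(n_top)
        survival = np.zeros(n_max + 1)
        survival[: n_top + 1] = surv_core
        K_size = K
    else:
        if M < 1:
            raise ValueError("M must be >= 1")
        if n_max is None:
            n_max = M + 1
        if n_max < 2:
            raise ValueError("n_max must be >= 2")
        survival = np.zeros(n_max + 1)
        survival[0] = 1.0
        survival[1 : n_max + 1] = _survival_equiprobable(M, n_max)
        K_size = M
    # survival index i holds F~(i); F~(0) = F~(1) = 1
    survival[0] = 1.0
    n = np.arange(2, n_max + 1)
    f = survival[n - 1] - survival[n]
    with np.errstate(divide="ignore", invalid="ignore"):
        per_draw = np.where(survival[n - 1] > 0, f / survival[n - 1], 1.0)
    return CoincidencePMF(M=K_size, n=n, f=f,
                          survival=survival[2:], per_draw=per_draw)


def expected_coincidence_distance(pmf: CoincidencePMF) -> float:
    """Model expectation E[n] of the first-coincidence draw, D(M)."""
    total = float(pmf.f.sum())
    if total < 1.0 - 1e-9:
        raise ValueError(
            f"pmf support is truncated (mass {total:.6f} < 1); "
            "increase n_max to at least M + 1"
        )
    return float((pmf.n * pmf.f).sum())
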