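"""Analytic Zipf-Mandelbrot-Li (ZML) rank models and constrained variants.

The ZML law gives a rank-probability distribution P(r; M) = gamma /
(r + beta)^alpha over ranks r = 1..M whose parameters are closed-form
functions of the alphabet size M alone, derived from a random-typing
word model: an M-letter alphabet plus a word delimiter generates words
whose length-to-rank transformation yields the power law with

    alpha = log(M + 1) / log(M),      beta = M / (M + 1).

The constrained variants shrink the admissible word space.  With a
per-position continuation branching factor B (the number of letters
allowed to follow a given letter), the count of admissible words of
length L is M * B^(L-1) instead of M^L, and repeating the same
length-to-rank transformation gives

    alpha~ = log(M + 1) / log(B),     beta~ = M / (B - 1).

The exponent follows because rank grows like B^L while per-word
probability still decays like (M + 1)^-L; the offset follows from the
cumulative admissible-word count M (B^L - 1)/(B - 1), which aligns the
band edge of length-L words with a pure power in B^L when shifted by
M/(B - 1).  cZML-I is the no-adjacent-repeated-letter model, B = M - 1.
cZML-II reduces the branching further (continuation-style lexicon
reduction), default B = ceil((M - 1)/2); B = M - 1 recovers cZML-I.

All distributions are renormalized numerically over the finite rank
support (the kappa step), so closed-form gamma inaccuracies can never
break conservation.  Non-integer M is accepted — the entropy estimator
produces continuous alphabet-size estimates — in which case the rank
support is round(M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

FAMILIES = ("zml", "czml1", "czml2", "equiprobable")


@dataclass(frozen=True)
class ZipfParams:
    """Closed-form parameters of a ZML-family distribution."""

    family: str
    M: float
    alpha: float
    beta: float
    gamma: float
    kappa: float
    branching: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class RankedDistribution:
    """A probability-by-rank vector p(1) >= p(2) >= ... >= p(M)."""

    params: ZipfParams
    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if not math.isclose(float(self.p.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("rank probabilities must sum to 1")
        if (self.p <= 0).any():
            raise ValueError("rank probabilities must be positive")

    @property
    def M_support(self) -> int:
        return int(self.p.size)

    def to_tsv(self) -> str:
        lines = ["rank\tprobability"]
        lines += [f"{r + 1}\t{v:.17g}" for r, v in enumerate(self.p)]
        return "\n".join(lines) + "\n"


def _support(M: float) -> int:
    """Rank support for a possibly continuous M: round half up, floor 2."""
    return max(2, int(math.floor(M + 0.5)))


def _normalized(family: str, M: float, alpha: float, beta: float,
                gamma: float, branching: float) -> RankedDistribution:
    r = np.arange(1, _support(M) + 1, dtype=float)
    unnorm = (r + beta) ** (-alpha)
    kappa = float(unnorm.sum())
    params = ZipfParams(family, float(M), alpha, beta, gamma, kappa, branching)
    return RankedDistribution(params, unnorm / kappa)


def make_zml(M: float) -> RankedDistribution:
    """Unconstrained ZML distribution over ranks 1..round(M)."""
    if M < 2:
        raise ValueError("zml requires M >= 2")
    alpha = math.log(M + 1) / math.log(M)
    beta = M / (M + 1)
    gamma = M ** (alpha - 1) / (M - 1) ** alpha
    return _normalized("zml", M, alpha, beta, gamma, M)


def _czml(family: str, M: float, B: float) -> RankedDistribution:
    alpha = math.log(M + 1) / math.log(B)
    beta = M / (B - 1)
    gamma = M ** (alpha - 1) / (B - 1) ** alpha
    return _normalized(family, M, alpha, beta, gamma, B)


def make_czml1(M: float) -> RankedDistribution:
    """Constrained ZML, no adjacent repeated letters (branching M - 1)."""
    if M < 3:
        raise ValueError("czml1 requires M >= 3 (branching M - 1 >= 2)")
    return _czml("czml1", M, M - 1)


def default_branching(M: float) -> int:
    """Default continuation branching for cZML-II: ceil((M-1)/2), floor 2."""
    return max(2, math.ceil((M - 1) / 2))


def make_czml2(M: float, B: float | None = None) -> RankedDistribution:
    """Constrained ZML with reduced continuation branching B.

    Relative to the unconstrained model the top and bottom ranks lose
    probability while mid ranks gain (the offset flattens the head, the
    larger exponent steepens the tail).  ``B = M - 1`` reduces to cZML-I.
    """
    if M < 3:
        raise ValueError("czml2 requires M >= 3")
    if B is None:
        B = default_branching(M)
    if not 2 <= B <= M - 1:
        raise ValueError(f"branching B={B} outside [2, M-1] for M={M}")
    return _czml("czml2", M, B)


def make_equiprobable(M: float) -> RankedDistribution:
    """Uniform distribution over round(M) symbols (degenerate rank model)."""
    if M < 2:
        raise ValueError("equiprobable model requires M >= 2")
    K = _support(M)
    params = ZipfParams("equiprobable", float(M), 0.0, 0.0, 1.0, float(K), M)
    # bypass the strict-decrease expectation: uniform is the flat limit
    return RankedDistribution(params, np.full(K, 1.0 / K))


def make_family(family: str, M: float, B: float | None = None) -> RankedDistribution:
    """Dispatch by family name."""
    if family == "zml":
        return make_zml(M)
    if family == "czml1":
        return make_czml1(M)
    if family == "czml2":
        return make_czml2(M, B)
    if family == "equiprobable":
        return make_equiprobable(M)
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class WordSpace:
    """Admissible-word counting model behind a ZML-family distribution.

    ``N_w`` counts admissible words of length L; ``p_word`` is the
    probability of any single admissible word of that length,
    gamma_w / (M+1)^(L+2), with gamma_w solved from the geometric-series
    condition sum_L N_w(L) p_word(L) = 1.
    """

    M: int
    L: int
    family: str
    branching: int
    N_w: int
    p_word: float
    gamma_w: float

    @property
    def length_mass(self) -> float:
        """Total probability N_w * p_word carried by words of length L.

        Evaluated in log space: N_w alone exceeds float range for long
        words even though the product is tiny.
        """
        log_mass = (
            math.log(self.M)
            + (self.L - 1) * math.log(self.branching)
            + math.log(self.gamma_w)
            - (self.L + 2) * math.log(self.M + 1)
        )
        return math.exp(log_mass) if log_mass > -745 else 0.0


def word_space(M: int, L: int, family: str = "zml", B: int | None = None) -> WordSpace:
    """Count admissible words of length L and their per-word probability."""
    if M < 2 or L < 1:
        raise ValueError("word_space requires M >= 2 and L >= 1")
    if family == "zml":
        branching = M
    elif family == "czml1":
        branching = M - 1
    elif family == "czml2":
        branching = int(B if B is not None else default_branching(M))
        if not 2 <= branching <= M - 1:
            raise ValueError("branching outside [2, M-1]")
    else:
        raise ValueError(f"word_space undefined for family {family!r}")
    N_w = M * branching ** (L - 1)
    # sum_L M B^(L-1) gamma (M+1)^-(L+2) = gamma M / ((M+1)^2 (M+1-B)) = 1
    gamma_w = (M + 1) ** 2 * (M + 1 - branching) / M
    # log-space evaluation: (M+1)^(L+2) overflows float64 for long words
    log_p = math.log(gamma_w) - (L + 2) * math.log(M + 1)
    p_word = math.exp(log_p) if log_p > -745 else 0.0
    return WordSpace(M, L, family, branching, N_w, p_word, gamma_w)


def model_entropy(dist: RankedDistribution) -> float:
    """Shannon entropy of the model's own rank probabilities, in bits."""
    p = dist.p
    return float(-(p * np.log2(p)).sum())


def alpha_ratio_curve(M_values) -> list[tuple[float, float]]:
    """Ratio of the constrained (cZML-I) to unconstrained exponent per M.

    alpha~/alpha = log(M) / log(M - 1): largest at small M, tending to 1.
    """
    out = []
    for M in M_values:
        if M < 3:
            raise ValueError("alpha ratio requires M >= 3")
        out.append((float(M), math.log(M) / math.log(M - 1)))
    return out
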