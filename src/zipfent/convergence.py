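"""DKW sample-size planning and the rank-1 convergence advantage.

The Dvoretzky-Kiefer-Wolfowitz inequality bounds the deviation of an
empirical distribution function.  For a rank distribution it yields the
number of samples sufficient to pin the rank-r probability down to a
precision that still separates it from its neighbour:

    N_r = ceil( 8 P(r) / Delta_r^2 * ln(2 / (1 - zeta')) )

with Delta_r = P(r) - P(r+1) the rank gap and zeta' the confidence
level, zeta' = 1 - 2 exp(-2 n eps^2).  The default precision target is
eps_r = Delta_r / 2, the largest precision that still distinguishes
adjacent ranks.

The convergence factor lambda_f(M) compares the cost of resolving the
easiest symbol (rank 1, all the coincidence estimator needs) with the
cost of resolving the hardest (rank M, which a plug-in estimator cannot
avoid):

    lambda_f(M) = P(1) Delta_1^2 / ( P(M) Delta_M^2 )

where the bottom-rank gap Delta_M is the gap P(M-1) - P(M) separating
the rank-M symbol from its neighbour.  The confidence terms cancel, so
lambda_f is independent of zeta'.  Oriented this way the factor is
>= 1 for every M >= 2 and grows steeply with M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .zipf_models import RankedDistribution, make_zml


@dataclass(frozen=True)
class SampleBound:
    """A DKW-derived sample requirement for one ranked symbol."""

    rank: int
    epsilon_r: float
    zeta_prime: float
    N_r: int
    Delta_r: float
    lambda_f: float


def rank_gap(dist: RankedDistribution, r: int) -> float:
    """Delta_r = p(r) - p(r+1); strictly positive for the Zipfian families."""
    M = dist.M_support
    if not 1 <= r <= M - 1:
        raise ValueError(f"rank gap needs 1 <= r <= M-1 = {M - 1}")
    gap = float(dist.p[r - 1] - dist.p[r])
    if gap <= 0:
        raise ValueError(
            f"rank gap at r={r} is zero (flat distribution); the DKW "
            "bound is undefined"
        )
    return gap


def dkw_confidence(n_r: float, epsilon_r: float) -> float:
    """Confidence zeta' = 1 - 2 exp(-2 n eps^2), clamped at 0 (no guarantee)."""
    if n_r <= 0 or epsilon_r <= 0:
        raise ValueError("n_r and epsilon_r must be positive")
    return max(0.0, 1.0 - 2.0 * math.exp(-2.0 * n_r * epsilon_r**2))


def dkw_samples_for_confidence(zeta_prime: float, epsilon_r: float) -> float:
    """Exact inversion of :func:`dkw_confidence` (continuous sample count)."""
    if not 0 < zeta_prime < 1:
        raise ValueError("zeta' must lie in (0, 1)")
    if epsilon_r <= 0:
        raise ValueError("epsilon_r must be positive")
    return math.log(2.0 / (1.0 - zeta_prime)) / (2.0 * epsilon_r**2)


def dkw_required_samples(p_r: float, delta_r: float, zeta_prime: float) -> int:
    """N_r = ceil(8 p_r / delta_r^2 * ln(2/(1-zeta')))."""
    if delta_r <= 0:
        raise ValueError("rank gap must be positive")
    if not 0 < zeta_prime < 1:
        raise ValueError("zeta' must lie in (0, 1)")
    return math.ceil(
        8.0 * p_r / delta_r**2 * math.log(2.0 / (1.0 - zeta_prime))
    )


def required_samples(
    dist: RankedDistribution, r: int, zeta_prime: float
) -> SampleBound:
    """Sufficient sample count to resolve the rank-r probability."""
    delta = rank_gap(dist, r)
    p_r = float(dist.p[r - 1])
    N_r = dkw_required_samples(p_r, delta, zeta_prime)
    lam = convergence_factor(dist.params.M) if dist.params.family == "zml" else float("nan")
    return SampleBound(
        rank=r,
        epsilon_r=delta / 2.0,
        zeta_prime=zeta_prime,
        N_r=N_r,
        Delta_r=delta,
        lambda_f=lam,
    )


def convergence_factor(M: float, zeta_prime: float | None = None) -> float:
    """Sample-savings factor lambda_f(M) of rank-1 vs rank-M estimation.

    ``zeta_prime`` is accepted for interface symmetry but the confidence
    terms cancel in the ratio, so it never enters.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    dist = make_zml(M)
    K = dist.M_support
    p1 = float(dist.p[0])
    pM = float(dist.p[-1])
    delta1 = rank_gap(dist, 1)
    deltaM = rank_gap(dist, K - 1)  # for M = 2 this is delta_1 itself
    return (p1 * delta1**2) / (pM * deltaM**2)
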