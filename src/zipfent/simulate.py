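"""Seeded synthetic symbol-sequence generation from the rank models.

Sequences are drawn i.i.d. by inverse-CDF over ranks — also for the
constrained families, whose constraints alter the rank probabilities,
not the sampling dependence; the coincidence theory assumes independent
draws.  A separate no-adjacent-repeat word sampler exists for
word-space tests only.

All randomness flows through ``numpy.random.Generator`` seeded with
PCG64 (the numpy default), so identical seeds give identical sequences
on any platform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_corpus import AlphabetSpec, SymbolSequence
from .zipf_models import RankedDistribution, model_entropy

RNG_ALGORITHM = "PCG64"


def rank_alphabet(K: int) -> AlphabetSpec:
    """Alphabet whose symbols are rank labels r1..rK."""
    return AlphabetSpec(tuple(f"r{i}" for i in range(1, K + 1)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_codes(dist: RankedDistribution, Ns: int, rng) -> np.ndarray:
    """Integer rank codes (0-based) of Ns i.i.d. draws from ``dist``."""
    if Ns < 1:
        raise ValueError("Ns must be >= 1")
    cdf = np.cumsum(dist.p)
    cdf[-1] = 1.0
    u = _as_rng(rng).random(Ns)
    return np.searchsorted(cdf, u, side="right").astype(np.int64)


def sample_iid_sequence(dist: RankedDistribution, Ns: int, seed) -> SymbolSequence:
    """I.i.d. sequence of Ns symbols, labeled by rank (r1 most frequent)."""
    codes = sample_codes(dist, Ns, seed)
    return SymbolSequence(codes, rank_alphabet(dist.M_support))


def sample_constrained_words(
    M: int, L: int, count: int, seed
) -> list[tuple[int, ...]]:
    """Uniform sample of words with no adjacent repeated letters.

    Letters are integers 0..M-1.  The first letter is uniform over M
    choices and each continuation uniform over the M - 1 letters that
    differ from the previous one, which is exactly uniform over the
    M (M-1)^(L-1) admissible words.
    """
    if M < 2 or L < 1 or count < 1:
        raise ValueError("require M >= 2, L >= 1, count >= 1")
    rng = _as_rng(seed)
    first = rng.integers(0, M, size=count)
    letters = np.empty((count, L), dtype=np.int64)
    letters[:, 0] = first
    for j in range(1, L):
        step = rng.integers(1, M, size=count)  # offset 1..M-1 avoids repeats
        letters[:, j] = (letters[:, j - 1] + step) % M
    return [tuple(row) for row in letters]


def run_convergence_experiment(
    M: int,
    Ns_grid,
    Nv: int,
    methods,
    seed,
    family: str = "zml",
    calib=None,
    rank: int = 1,
) -> pd.DataFrame:
    """Mean entropy estimate per (method, Ns) over Nv seeded trials.

    Each trial draws one sequence of max(Ns_grid) symbols from the
    family distribution at alphabet size M and evaluates every method on
    each prefix of length Ns, so the per-Ns estimates within a trial are
    nested exactly as they would be for a growing data stream.  The true
    model entropy is attached as a column for reference.
    """
    from .calibration import default_calibration
    from .estimator import (
        estimate_entropy_model,
        miller_madow_entropy,
        plugin_entropy,
    )
    from .zipf_models import make_family

    methods = list(methods)
    Ns_grid = sorted(int(n) for n in Ns_grid)
    if not Ns_grid or Ns_grid[0] < 2:
        raise ValueError("Ns grid must contain sizes >= 2")
    dist = make_family(family, M)
    H_true = model_entropy(dist)
    if calib is None and any(m.endswith("coincidence") for m in methods):
        calib = default_calibration(family)
    rng = np.random.default_rng(seed)
    alphabet = rank_alphabet(dist.M_support)

    rows = []
    for trial in range(Nv):
        codes = sample_codes(dist, Ns_grid[-1], rng)
        for Ns in Ns_grid:
            prefix = SymbolSequence(codes[:Ns], alphabet)
            for method in methods:
                try:
                    if method == "plugin":
                        est = plugin_entropy(prefix.counts())
                    elif method == "miller_madow":
                        est = miller_madow_entropy(prefix.counts())
                    elif method.endswith("coincidence"):
                        fam = method[: -len("_coincidence")]
                        est = estimate_entropy_model(
                            prefix, calib, family=fam, r=rank
                        )
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    value = est.value
                except ValueError:
                    value = np.nan
                rows.append((trial, Ns, method, value))
    df = pd.DataFrame(rows, columns=["trial", "Ns", "method", "estimate"])
    out = (
        df.groupby(["method", "Ns"])["estimate"]
        .agg(mean="mean", std="std", n_valid="count")
        .reset_index()
    )
    out["H_true"] = H_true
    return out


def sample_markov_sequence(
    transition: np.ndarray, Ns: int, seed, init=None
) -> SymbolSequence:
    """First-order Markov chain with the given row-stochastic matrix.

    Used to exercise the entropy-rate machinery against the analytic
    conditional entropy of a known chain.
    """
    P = np.asarray(transition, dtype=float)
    K = P.shape[0]
    if P.shape != (K, K) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition must be a square row-stochastic matrix")
    rng = _as_rng(seed)
    cdf = np.cumsum(P, axis=1)
    cdf[:, -1] = 1.0
    codes = np.empty(Ns, dtype=np.int64)
    if init is None:
        # stationary start
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        codes[0] = rng.choice(K, p=pi)
    else:
        codes[0] = int(init)
    u = rng.random(Ns)
    for t in range(1, Ns):
        codes[t] = np.searchsorted(cdf[codes[t - 1]], u[t], side="right")
    return SymbolSequence(codes, rank_alphabet(K))


def markov_stationary(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    P = np.asarray(transition, dtype=float)
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmax(np.real(w))])
    pi = np.abs(pi)
    return pi / pi.sum()


def markov_entropy_rate(transition: np.ndarray) -> float:
    """Analytic conditional entropy sum_i pi_i sum_j P_ij log2(1/P_ij)."""
    P = np.asarray(transition, dtype=float)
    pi = markov_stationary(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log2(P), 0.0)
    return float(-(pi[:, None] * terms).sum())
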