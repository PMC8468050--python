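"""Block entropies, conditional entropy rates and text preprocessing.

The entropy rate of a stationary source is the limit of the conditional
entropies h_N = H_N - H_{N-1}, where H_N is the Shannon entropy of the
distribution of length-N blocks (n-grams).  Computing h_N as a
difference of block entropies is algebraically identical to the
conditional form for a stationary source and lets every unigram-style
estimator be reused unchanged on the derived n-gram alphabet.

Text is prefiltered to lowercase alphanumerics and single spaces, and
n-grams straddling a word boundary can be excluded (``within_words``),
matching the usual character-level entropy-rate protocol for natural
language.

Reliability: block entropies become untrustworthy once the number of
distinct n-grams approaches the stream length.  A block size N is
flagged reliable while distinct n-grams <= ``reliability_fraction`` of
the n-gram stream (default 10%), and the reported rate is h_N at the
largest reliable N; the full series is always returned so any N can be
inspected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .estimator import (
    EntropyEstimate,
    estimate_entropy_model,
    miller_madow_entropy,
    plugin_entropy,
)
from .io_corpus import SymbolSequence

_KEEP = re.compile(r"[^a-z0-9 ]+")
_SPACES = re.compile(r" +")


def preprocess_text(text: str) -> SymbolSequence:
    """Lowercase, strip non-alphanumerics except spaces, collapse runs.

    Idempotent: applying the rules to their own output changes nothing.
    """
    cleaned = _SPACES.sub(" ", _KEEP.sub("", text.lower())).strip()
    return SymbolSequence.from_tokens(list(cleaned))


def ngram_stream(
    seq: SymbolSequence, n: int, within_words: bool = True
) -> list[str]:
    """Overlapping n-gram tokens of the character stream.

    With ``within_words`` any n-gram containing a space is dropped, so
    only n-grams occurring inside a word survive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    toks = seq.tokens()
    grams = ["".join(toks[i : i + n]) for i in range(len(toks) - n + 1)]
    if within_words:
        grams = [g for g in grams if " " not in g]
    return grams


@dataclass(frozen=True)
class BlockEntropySeries:
    """H_N, h_N = H_N - H_{N-1}, and reliability flags per block size."""

    N_values: tuple[int, ...]
    H_N: tuple[float, ...]
    n_grams_observed: tuple[int, ...]
    stream_lengths: tuple[int, ...]
    reliable: tuple[bool, ...]
    method: str

    @property
    def h_N(self) -> tuple[float, ...]:
        rates = [self.H_N[0]]
        rates += [b - a for a, b in zip(self.H_N, self.H_N[1:])]
        return tuple(rates)

    @property
    def rate(self) -> float:
        """h_N at the largest reliable block size."""
        idx = [i for i, ok in enumerate(self.reliable) if ok]
        if not idx:
            raise ValueError("no block size passed the reliability check")
        return self.h_N[idx[-1]]

    @property
    def rate_N(self) -> int:
        idx = [i for i, ok in enumerate(self.reliable) if ok]
        return self.N_values[idx[-1]] if idx else 0

    def to_tsv(self) -> str:
        lines = ["N\tH_N\th_N\tn_grams\tstream\treliable"]
        for i, N in enumerate(self.N_values):
            lines.append(
                f"{N}\t{self.H_N[i]:.6f}\t{self.h_N[i]:.6f}\t"
                f"{self.n_grams_observed[i]}\t{self.stream_lengths[i]}\t"
                f"{int(self.reliable[i])}"
            )
        return "\n".join(lines) + "\n"


def block_entropy(
    seq: SymbolSequence,
    n: int,
    method: str = "plugin",
    calib=None,
    within_words: bool = True,
) -> EntropyEstimate:
    """Entropy of the length-n block distribution, in bits.

    Each distinct n-gram is treated as one symbol of a derived alphabet
    and the chosen estimator is applied to that stream.
    """
    grams = ngram_stream(seq, n, within_words=within_words)
    if not grams:
        raise ValueError(f"no n-grams of size {n} available")
    if method in ("plugin", "miller_madow"):
        derived = SymbolSequence.from_tokens(grams)
        counts = derived.counts()
        est = plugin_entropy(counts) if method == "plugin" else miller_madow_entropy(counts)
        return est
    if method.endswith("_coincidence"):
        family = method[: -len("_coincidence")]
        derived = SymbolSequence.from_tokens(grams)
        if calib is None:
            from .calibration import default_calibration

            calib = default_calibration(family)
        return estimate_entropy_model(derived, calib, family=family)
    raise ValueError(f"unknown method {method!r}")


def entropy_rate(
    seq: SymbolSequence,
    N_max: int,
    method: str = "plugin",
    calib=None,
    within_words: bool = True,
    reliability_fraction: float = 0.1,
) -> BlockEntropySeries:
    """Block-entropy series H_1..H_{N_max} and the conditional rate."""
    if N_max < 1:
        raise ValueError("N_max must be >= 1")
    if seq.N == 0:
        raise ValueError("empty sequence")
    H, counts_distinct, lengths, reliable = [], [], [], []
    for n in range(1, N_max + 1):
        grams = ngram_stream(seq, n, within_words=within_words)
        if not grams:
            break
        est = block_entropy(seq, n, method=method, calib=calib,
                            within_words=within_words)
        distinct = len(set(grams))
        H.append(est.value)
        counts_distinct.append(distinct)
        lengths.append(len(grams))
        reliable.append(distinct <= reliability_fraction * len(grams))
    return BlockEntropySeries(
        N_values=tuple(range(1, len(H) + 1)),
        H_N=tuple(H),
        n_grams_observed=tuple(counts_distinct),
        stream_lengths=tuple(lengths),
        reliable=tuple(reliable),
        method=method,
    )


class MissingConditionalError(KeyError):
    """A conditional probability needed by the Markov product is absent."""


def markov_joint_probability(conditional_table: dict, block) -> float:
    """Joint probability of a block under tabulated conditionals.

    ``conditional_table`` maps a context tuple (possibly empty) to a
    dict of next-symbol probabilities.  The context is capped at the
    table's maximum order, and the longest available context is used for
    each position.
    """
    if not conditional_table:
        raise ValueError("empty conditional table")
    order = max(len(ctx) for ctx in conditional_table)
    prob = 1.0
    symbols = list(block)
    for i, s in enumerate(symbols):
        ctx = tuple(symbols[max(0, i - order) : i])
        while ctx not in conditional_table and ctx:
            ctx = ctx[1:]
        if ctx not in conditional_table or s not in conditional_table[ctx]:
            raise MissingConditionalError(
                f"no conditional for symbol {s!r} in context {ctx!r}"
            )
        prob *= conditional_table[ctx][s]
    return prob
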