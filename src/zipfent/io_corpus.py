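"""Reading symbol streams: plain text, FASTA, token files and rank tables.

Every downstream computation works on a :class:`SymbolSequence`, an
integer-coded view of a token stream over a declared
:class:`AlphabetSpec`.  Integer coding keeps million-symbol simulation
sequences cheap while the alphabet retains the human-readable tokens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class AlphabetError(ValueError):
    """A token was encountered that is not a member of the alphabet."""


@dataclass(frozen=True)
class AlphabetSpec:
    """An ordered set of distinct symbols.

    Parameters
    ----------
    symbols
        Ordered tokens; order fixes the integer code of each symbol.
    kind
        One of ``text``, ``dna``, ``protein``, ``custom``.
    """

    symbols: tuple[str, ...]
    kind: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise AlphabetError("alphabet symbols must be distinct")
        if self.kind not in {"text", "dna", "protein", "custom"}:
            raise ValueError(f"unknown alphabet kind: {self.kind!r}")

    @property
    def M(self) -> int:
        """Alphabet size."""
        return len(self.symbols)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def __contains__(self, token: str) -> bool:
        return token in set(self.symbols)


DNA = AlphabetSpec(("A", "C", "G", "T"), kind="dna")
PROTEIN = AlphabetSpec(tuple("ACDEFGHIKLMNPQRSTVWY"), kind="protein")


@dataclass
class SymbolSequence:
    """A sequence of symbols, stored as integer codes into an alphabet."""

    codes: np.ndarray
    alphabet: AlphabetSpec
    id: str | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.size and (
            self.codes.min() < 0 or self.codes.max() >= self.alphabet.M
        ):
            raise AlphabetError("sequence contains codes outside the alphabet")

    @property
    def N(self) -> int:
        return int(self.codes.size)

    def __len__(self) -> int:
        return self.N

    def tokens(self) -> list[str]:
        syms = self.alphabet.symbols
        return [syms[c] for c in self.codes]

    def counts(self) -> np.ndarray:
        """Occurrence count per alphabet symbol (length M)."""
        return np.bincount(self.codes, minlength=self.alphabet.M)

    @classmethod
    def from_tokens(
        cls,
        tokens: Sequence[str],
        alphabet: AlphabetSpec | None = None,
        id: str | None = None,
    ) -> "SymbolSequence":
        """Build a sequence from tokens, inferring the alphabet if absent.

        An inferred alphabet lists the distinct tokens in sorted order so
        that the coding is deterministic.
        """
        if alphabet is None:
            alphabet = AlphabetSpec(tuple(sorted(set(tokens))))
        idx = alphabet.index()
        try:
            codes = np.fromiter(
                (idx[t] for t in tokens), dtype=np.int64, count=len(tokens)
            )
        except KeyError as exc:
            raise AlphabetError(f"token {exc.args[0]!r} not in alphabet") from None
        return cls(codes, alphabet, id=id)


def read_text_corpus(
    path: str | Path,
    alphabet_policy: str = "infer",
    alphabet: AlphabetSpec | None = None,
    unit: str = "char",
) -> SymbolSequence:
    """Read a UTF-8 text file as a symbol sequence.

    The symbol unit is the character by default (the natural unit for
    coincidence counting on text); ``unit="word"`` splits on whitespace
    instead.  With ``alphabet_policy="infer"`` the alphabet is the set
    of distinct tokens observed; with ``"fixed"`` an ``alphabet`` must
    be given and any token outside it raises :class:`AlphabetError`.
    """
    if alphabet_policy not in {"infer", "fixed"}:
        raise ValueError("alphabet_policy must be 'infer' or 'fixed'")
    if alphabet_policy == "fixed" and alphabet is None:
        raise ValueError("fixed alphabet_policy requires an alphabet")
    if unit not in {"char", "word"}:
        raise ValueError("unit must be 'char' or 'word'")
    text = Path(path).read_text(encoding="utf-8")
    tokens = list(text) if unit == "char" else text.split()
    if alphabet_policy == "infer":
        return SymbolSequence.from_tokens(tokens, id=str(path))
    return SymbolSequence.from_tokens(tokens, alphabet=alphabet, id=str(path))


def read_fasta(
    path: str | Path,
    alphabet: AlphabetSpec = DNA,
    strict: bool = True,
) -> list[SymbolSequence]:
    """Read a FASTA file into one :class:`SymbolSequence` per record.

    Residues are uppercased before matching.  In strict mode a residue
    outside the alphabet raises; in lenient mode it is dropped.  Silent
    dropping hides alphabet mis-specification, which is fatal to an
    alphabet-size estimator, hence strict is the default.
    """
    from Bio import SeqIO

    out: list[SymbolSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = list(str(rec.seq).upper())
        if not residues:
            raise ValueError(f"empty FASTA record: {rec.id}")
        if not strict:
            members = set(alphabet.symbols)
            residues = [r for r in residues if r in members]
        try:
            out.append(SymbolSequence.from_tokens(residues, alphabet, id=rec.id))
        except AlphabetError as exc:
            raise AlphabetError(f"record {rec.id}: {exc}") from None
    return out


def read_tokens(path: str | Path, alphabet: AlphabetSpec | None = None) -> SymbolSequence:
    """Read a pre-tokenized stream, one token per line."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return SymbolSequence.from_tokens(lines, alphabet=alphabet, id=str(path))


def write_tokens(seq: SymbolSequence, path: str | Path) -> None:
    """Write one token per line; round-trips with :func:`read_tokens`."""
    Path(path).write_text(
        "".join(f"{t}\n" for t in seq.tokens()), encoding="utf-8"
    )


def read_rank_table(path: str | Path, case_fold: bool = False) -> pd.DataFrame:
    """Read a TSV of (token, count) into a ranked frequency table.

    Returns a DataFrame with columns ``token, count, probability, rank``,
    sorted by descending count.  Ties are broken by lexicographic token
    order so that ranking is deterministic.  ``case_fold`` lowercases
    tokens (merging counts) before ranking.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if "token" in cols and "count" in cols:
        df.columns = cols
        df = df[["token", "count"]]
    else:
        # headerless two-column file
        df = pd.read_csv(path, sep="\t", header=None, names=["token", "count"],
                         dtype={0: str})
    if case_fold:
        df["token"] = df["token"].str.lower()
        df = df.groupby("token", as_index=False)["count"].sum()
    if (df["count"] < 0).any():
        raise ValueError("rank table contains negative counts")
    if df["token"].duplicated().any():
        dupes = df.loc[df["token"].duplicated(), "token"].tolist()
        raise ValueError(f"duplicate tokens in rank table: {dupes}")
    total = df["count"].sum()
    if total <= 0:
        raise ValueError("rank table has zero total count")
    df = df.sort_values(["count", "token"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["probability"] = df["count"] / total
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def write_json_report(payload: dict, path: str | Path | None) -> str:
    """Serialize a result dict deterministically; write it if a path is given."""
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
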