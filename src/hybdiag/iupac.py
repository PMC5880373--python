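"""IUPAC nucleotide ambiguity-code algebra.

Each of the 15 IUPAC nucleotide symbols denotes a non-empty subset of
{A, C, G, T}; ``R`` = {A, G}, ``Y`` = {C, T}, ``N`` = {A, C, G, T} and so on.
Interpreting symbols as sets gives the algebra behind character additivity in
hybrids: a hybrid that inherited ``C`` from one parent and ``T`` from the
other shows the additive symbol ``Y`` at that position in a direct read of a
multi-copy marker.

The symbol <-> state-set table is taken from Biopython's IUPACData,
restricted to the 15 standard nucleotide symbols (``X`` is not accepted;
the gap character ``-`` is deliberately *not* a state set and is handled by
the alignment layer).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import InvalidSymbolError

#: The 15 valid IUPAC nucleotide symbols, in canonical order.
IUPAC_SYMBOLS: str = "ACGTRYSWKMBDHVN"

#: symbol -> frozenset of bases, e.g. 'R' -> {'A', 'G'}
STATES: dict[str, frozenset[str]] = {
    s: frozenset(ambiguous_dna_values[s]) for s in IUPAC_SYMBOLS
}

#: frozenset of bases -> symbol (inverse of STATES; a bijection)
SYMBOL_FOR: dict[frozenset[str], str] = {v: k for k, v in STATES.items()}

GAP = "-"


@dataclass(frozen=True)
class NucleotideStateSet:
    """An IUPAC symbol together with the base subset it denotes."""

    symbol: str
    states: frozenset[str]

    def __post_init__(self) -> None:
        if self.symbol not in STATES or STATES[self.symbol] != self.states:
            raise InvalidSymbolError(
                f"inconsistent state set for symbol {self.symbol!r}"
            )

    def __len__(self) -> int:
        return len(self.states)

    @property
    def is_ambiguous(self) -> bool:
        return len(self.states) > 1

    def __or__(self, other: "NucleotideStateSet") -> "NucleotideStateSet":
        return from_states(self.states | other.states)


def parse_symbol(symbol: str) -> NucleotideStateSet:
    """Return the state set denoted by an IUPAC symbol (case-insensitive).

    The gap character and anything outside the 15 IUPAC symbols raise
    :class:`InvalidSymbolError`.
    """
    up = symbol.upper()
    if up not in STATES:
        raise InvalidSymbolError(f"not an IUPAC nucleotide symbol: {symbol!r}")
    return NucleotideStateSet(up, STATES[up])


def from_states(states: frozenset[str] | set[str]) -> NucleotideStateSet:
    """Return the unique symbol whose state set equals ``states``."""
    key = frozenset(states)
    try:
        symbol = SYMBOL_FOR[key]
    except KeyError:
        raise InvalidSymbolError(f"not a valid base subset: {sorted(states)}")
    return NucleotideStateSet(symbol, key)


def union_symbol(a: str, b: str) -> str:
    """The symbol denoting states(a) | states(b) — the additive character.

    ``union_symbol('C', 'T') == 'Y'``; the operation is commutative,
    associative and idempotent, with ``'N'`` absorbing.
    """
    return from_states(parse_symbol(a).states | parse_symbol(b).states).symbol


def is_valid_symbol(symbol: str) -> bool:
    """True for the 15 IUPAC symbols (case-insensitive); False otherwise."""
    return symbol.upper() in STATES
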