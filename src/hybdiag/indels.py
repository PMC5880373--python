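"""Simple indel coding: alignment gaps as binary presence/absence characters.

Each distinct internal gap range observed in at least one sequence becomes
one binary character. A taxon scores 1 when it carries a gap with exactly
that range, ``?`` (inapplicable) when a longer gap of its own properly
contains the range, and 0 otherwise. Terminal (leading/trailing) gap runs
never define characters and score ``?`` for every character they span —
missing sequence, not a deletion event.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TextIO, Union

import pandas as pd

from .alignment import Alignment
from .iupac import GAP

Source = Union[str, Path, TextIO]


@dataclass(frozen=True)
class GapRange:
    """A maximal run of '-' in one sequence, 1-based inclusive columns."""

    sequence_id: str
    start: int
    end: int
    terminal: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gap start {self.start} > end {self.end}")

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def properly_contains(self, start: int, end: int) -> bool:
        return self.contains(start, end) and (self.start, self.end) != (start, end)


@dataclass
class IndelCharacter:
    """One binary character: a gap range plus a 0/1/? state per taxon."""

    start: int
    end: int
    states: dict[str, str]  # taxon id -> '0' | '1' | '?'

    def __post_init__(self) -> None:
        if "1" not in self.states.values():
            raise ValueError(
                f"character ({self.start},{self.end}) has no taxon in state 1"
            )


def extract_gaps(alignment: Alignment) -> list[GapRange]:
    """All maximal gap runs per sequence, terminal runs flagged."""
    out: list[GapRange] = []
    length = alignment.length
    for seq in alignment.sequences:
        col = 1
        while col <= length:
            if seq.symbol_at(col) == GAP:
                start = col
                while col <= length and seq.symbol_at(col) == GAP:
                    col += 1
                end = col - 1
                terminal = start == 1 or end == length
                out.append(GapRange(seq.id, start, end, terminal))
            else:
                col += 1
    return out


def simple_indel_code(alignment: Alignment) -> list[IndelCharacter]:
    """Code internal gaps into binary characters, ordered by (start, end)."""
    gaps = extract_gaps(alignment)
    by_taxon: dict[str, list[GapRange]] = {s.id: [] for s in alignment.sequences}
    for g in gaps:
        by_taxon[g.sequence_id].append(g)

    ranges = sorted({(g.start, g.end) for g in gaps if not g.terminal})
    characters: list[IndelCharacter] = []
    for start, end in ranges:
        states: dict[str, str] = {}
        for seq in alignment.sequences:
            state = "0"
            for g in by_taxon[seq.id]:
                if g.terminal:
                    if g.contains(start, end):
                        state = "?"
                        break
                elif (g.start, g.end) == (start, end):
                    state = "1"
                    break
                elif g.properly_contains(start, end):
                    state = "?"
                    break
            states[seq.id] = state
        characters.append(IndelCharacter(start, end, states))
    return characters


def character_matrix(alignment: Alignment, characters: list[IndelCharacter]) -> pd.DataFrame:
    """Taxa x characters matrix of '0'/'1'/'?' strings."""
    cols = {f"indel_{c.start}_{c.end}": [c.states[s.id] for s in alignment.sequences]
            for c in characters}
    return pd.DataFrame(cols, index=alignment.ids())


def write_indel_tsv(alignment: Alignment, characters: list[IndelCharacter], dest: Source) -> None:
    character_matrix(alignment, characters).to_csv(dest, sep="\t", index_label="taxon")


def write_combined_nexus(alignment: Alignment, characters: list[IndelCharacter], dest: Source) -> None:
    """Nucleotide matrix with the binary indel block appended (0/1/? symbols)."""
    binary = {s.id: "".join(c.states[s.id] for c in characters)
              for s in alignment.sequences}
    nchar = alignment.length + len(characters)
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(alignment)} NCHAR={nchar};",
        '  FORMAT DATATYPE=STANDARD SYMBOLS="ACGTRYSWKMBDHVN01" MISSING=? GAP=-;',
        "  MATRIX",
    ]
    width = max(len(i) for i in alignment.ids()) + 2
    for seq in alignment.sequences:
        lines.append(f"    {seq.id:<{width}}{seq.symbols}{binary[seq.id]}")
    lines += ["  ;", "END;", ""]
    text = "\n".join(lines)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
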