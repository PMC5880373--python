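"""Alignment containers, FASTA I/O and sample-group manifests.

Inputs are pre-aligned nucleotide sequences (the analyses here never align;
alignments are assumed unambiguous). Columns are 1-based in every public
interface. Lowercase is normalised to uppercase and ``U`` to ``T`` on read;
``?`` is rejected in input FASTA (it is reserved for indel-coding output).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentShapeError, HybdiagError, InvalidSymbolError
from .iupac import GAP, is_valid_symbol

Source = Union[str, Path, TextIO]


@dataclass
class AlignedSequence:
    """One row of an alignment: an id, an optional taxon label, symbols."""

    id: str
    symbols: str
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise AlignmentShapeError(f"sequence {self.id!r} is empty")
        for col, ch in enumerate(self.symbols, start=1):
            if ch != GAP and not is_valid_symbol(ch):
                raise InvalidSymbolError(
                    f"record {self.id!r}, column {col}: invalid symbol {ch!r}"
                )
        self.symbols = self.symbols.upper()

    def __len__(self) -> int:
        return len(self.symbols)

    def symbol_at(self, column: int) -> str:
        """Symbol at a 1-based column."""
        return self.symbols[column - 1]

    def ungapped(self) -> str:
        return self.symbols.replace(GAP, "")


class Role(str, Enum):
    PARENT_A = "parentA"
    PARENT_B = "parentB"
    QUERY = "query"


@dataclass
class SampleGroup:
    """Sequence ids playing one role (parentA, parentB or query)."""

    role: Role
    sequence_ids: list[str]

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        if not self.sequence_ids:
            raise HybdiagError(f"group {self.role.value} has no sequence ids")


@dataclass
class Alignment:
    """Equal-length sequences with unique ids."""

    sequences: list[AlignedSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"ragged alignment: lengths {sorted(lengths)}"
            )
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentShapeError(f"duplicate sequence ids: {dup}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def column(self, column: int, seq_ids: Iterable[str] | None = None) -> list[str]:
        """Symbols at a 1-based column, optionally restricted to some ids."""
        if not 1 <= column <= self.length:
            raise IndexError(f"column {column} outside 1..{self.length}")
        rows = self.sequences if seq_ids is None else [self[i] for i in seq_ids]
        return [s.symbol_at(column) for s in rows]

    def validate_groups(self, groups: Iterable[SampleGroup]) -> None:
        """Check every group id exists and roles do not share ids."""
        seen: dict[str, Role] = {}
        known = set(self.ids())
        for g in groups:
            for sid in g.sequence_ids:
                if sid not in known:
                    raise HybdiagError(f"unknown sequence id in manifest: {sid!r}")
                if sid in seen and seen[sid] != g.role:
                    raise HybdiagError(f"sequence id {sid!r} assigned to two roles")
                seen[sid] = g.role


def _normalise(raw: str, rec_id: str) -> str:
    out = []
    for col, ch in enumerate(raw, start=1):
        up = ch.upper()
        if up == "U":
            up = "T"
        if up != GAP and not is_valid_symbol(up):
            raise InvalidSymbolError(
                f"record {rec_id!r}, column {col}: invalid symbol {ch!r}"
            )
        out.append(up)
    return "".join(out)


def read_alignment(source: Source) -> Alignment:
    """Read a multi-FASTA alignment (wrapped or unwrapped).

    Raises :class:`AlignmentShapeError` for ragged records or <2 records and
    :class:`InvalidSymbolError` (naming record and column) for illegal
    characters.
    """
    records = list(SeqIO.parse(source if not isinstance(source, Path) else str(source), "fasta"))
    if len(records) < 2:
        raise AlignmentShapeError(
            f"alignment needs >=2 records, found {len(records)}"
        )
    seqs = [
        AlignedSequence(
            id=r.id,
            symbols=_normalise(str(r.seq), r.id),
            taxon_label=r.description,
        )
        for r in records
    ]
    return Alignment(seqs)


def write_alignment(alignment: Alignment, dest: Source) -> None:
    """Write an alignment as unwrapped FASTA."""
    records = [
        SeqRecord(Seq(s.symbols), id=s.id, description="")
        for s in alignment.sequences
    ]
    handle = str(dest) if isinstance(dest, Path) else dest
    SeqIO.write(records, handle, "fasta-2line")


def read_manifest(source: Source) -> dict[Role, SampleGroup]:
    """Read a `sequence_id<TAB>role` manifest into one group per role."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    by_role: dict[Role, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise HybdiagError(f"manifest line {lineno}: expected 2 tab-separated fields")
        sid, role_str = parts
        if sid == "sequence_id":  # optional header
            continue
        try:
            role = Role(role_str)
        except ValueError:
            raise HybdiagError(f"manifest line {lineno}: unknown role {role_str!r}")
        by_role.setdefault(role, []).append(sid)
    return {role: SampleGroup(role, ids) for role, ids in by_role.items()}


def write_manifest(groups: Iterable[SampleGroup], dest: Source) -> None:
    lines = ["sequence_id\trole"]
    for g in groups:
        for sid in g.sequence_ids:
            lines.append(f"{sid}\t{g.role.value}")
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def warn(message: str) -> None:
    print(f"[hybdiag] {message}", file=sys.stderr)
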