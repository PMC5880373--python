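"""In-silico restriction analysis and clone-screen design.

A rare ribotype hiding in a cloned PCR product can be pre-screened cheaply
when a restriction site present in the dominant ribotype is lost in the rare
one: clones showing the uncut pattern are candidates for the rare variant.
This module predicts digests of linear molecules (PCR products), searches an
enzyme library for site-count differences between two ribotypes, and sizes
the clone screen: drawing clones from a library in which the rare ribotype
has frequency *f*, the chance of seeing it at least once among *n* clones is
1 − (1 − f)^n, so n = ⌈ln(1 − p) / ln(1 − f)⌉ clones reach a target
detection probability *p*.

Degenerate recognition sequences are matched under IUPAC semantics, on both
strands, with overlapping matches all counted; positions are reported
1-based on the forward strand.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import pandas as pd
from Bio.Seq import Seq

from .errors import HybdiagError, ParameterError
from .iupac import GAP, STATES, is_valid_symbol

Source = Union[str, Path, TextIO]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition sequence and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4 or not all(is_valid_symbol(c) for c in rec):
            raise ParameterError(
                f"enzyme {self.name}: recognition must be >=4 IUPAC symbols"
            )
        if not 0 <= self.cut_offset <= len(rec):
            raise ParameterError(
                f"enzyme {self.name}: cut_offset outside 0..{len(rec)}"
            )
        object.__setattr__(self, "recognition", rec)

    @property
    def is_palindromic(self) -> bool:
        return str(Seq(self.recognition).reverse_complement()) == self.recognition


@dataclass
class DigestResult:
    cut_positions: list[int]  # 1-based: cut after this many leading bases
    fragment_lengths: list[int]

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragment_lengths):
            raise HybdiagError("zero-length fragment")
        if len(self.fragment_lengths) != len(self.cut_positions) + 1:
            raise HybdiagError("fragment count must be cut count + 1 (linear molecule)")


@dataclass
class CloneScreenPlan:
    """How many clones to screen to see a rare ribotype at frequency f."""

    minor_fraction: float
    target_probability: float
    clones_needed: int

    def detection_probability_at(self, n_clones: int) -> float:
        """P(at least one positive clone among n) = 1 − (1 − f)^n."""
        if n_clones < 0:
            raise ParameterError("clone count must be >= 0")
        return 1.0 - (1.0 - self.minor_fraction) ** n_clones


def _iupac_regex(recognition: str) -> str:
    parts = []
    for ch in recognition:
        states = sorted(STATES[ch])
        parts.append(states[0] if len(states) == 1 else "[" + "".join(states) + "]")
    return "".join(parts)


def _check_ungapped(sequence: str) -> str:
    seq = sequence.upper()
    if GAP in seq:
        raise HybdiagError("sequence contains gaps; degap before restriction analysis")
    if not seq or not all(is_valid_symbol(c) for c in seq):
        raise HybdiagError("sequence must be non-empty IUPAC nucleotides")
    return seq


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Sorted, deduplicated 1-based start positions of recognition matches.

    Both strands are scanned (the reverse-strand motif is matched as its
    reverse complement on the forward strand); overlapping matches all
    count; palindromic sites are reported once.
    """
    seq = _check_ungapped(sequence)
    motifs = {enzyme.recognition}
    motifs.add(str(Seq(enzyme.recognition).reverse_complement()))
    positions: set[int] = set()
    for motif in motifs:
        pattern = re.compile(f"(?=({_iupac_regex(motif)}))")
        positions.update(m.start() + 1 for m in pattern.finditer(seq))
    return sorted(positions)


def digest_linear(sequence: str, enzyme: Enzyme) -> DigestResult:
    """Predicted fragments of a linear molecule (PCR product).

    Cut coordinate = site start + cut_offset − 1 bases from the 5' end; the
    fragment lengths always sum to the input length. Fragment sizes at
    non-palindromic or offset-unknown enzymes are convention-dependent;
    site presence/absence (what an RFLP screen reads on the gel) is not.
    """
    seq = _check_ungapped(sequence)
    n = len(seq)
    cuts = sorted(
        {s + enzyme.cut_offset - 1 for s in find_sites(seq, enzyme)}
    )
    cuts = [c for c in cuts if 0 < c < n]
    bounds = [0, *cuts, n]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return DigestResult(cut_positions=cuts, fragment_lengths=fragments)


def find_discriminating_enzymes(
    seq_a: str,
    seq_b: str,
    enzyme_library: Sequence[Enzyme],
) -> list[tuple[Enzyme, list[int], list[int]]]:
    """Enzymes whose site count differs between two ribotypes.

    Sorted by |site-count difference| descending, then name. The motivating
    pattern is an enzyme cutting ribotype A but not ribotype B: uncut clones
    then flag the B variant on a gel.
    """
    if not enzyme_library:
        raise ParameterError("enzyme library is empty")
    out = []
    for enz in enzyme_library:
        sites_a = find_sites(seq_a, enz)
        sites_b = find_sites(seq_b, enz)
        if len(sites_a) != len(sites_b):
            out.append((enz, sites_a, sites_b))
    out.sort(key=lambda t: (-abs(len(t[1]) - len(t[2])), t[0].name))
    return out


def plan_clone_screen(minor_fraction: float, target_probability: float) -> CloneScreenPlan:
    """Clones needed so P(>=1 positive) reaches the target.

    ``plan_clone_screen(0.5, 0.99).clones_needed == 7``; at f = 0.025 a
    39-clone screen reaches 1 − 0.975^39 ≈ 0.627.
    """
    if not 0 < minor_fraction < 1:
        raise ParameterError(f"minor_fraction must be in (0, 1), got {minor_fraction}")
    if not 0 < target_probability < 1:
        raise ParameterError(
            f"target_probability must be in (0, 1), got {target_probability}"
        )
    n = math.ceil(math.log(1 - target_probability) / math.log(1 - minor_fraction))
    return CloneScreenPlan(minor_fraction, target_probability, max(n, 1))


def load_enzyme_library(source: Source | None = None) -> list[Enzyme]:
    """Load an enzyme TSV (name, recognition, cut_offset); default: bundled."""
    if source is None:
        source = files("hybdiag").joinpath("data/enzymes.tsv").open()
    df = pd.read_csv(source, sep="\t")
    missing = {"name", "recognition", "cut_offset"} - set(df.columns)
    if missing:
        raise HybdiagError(f"enzyme library missing columns: {sorted(missing)}")
    return [
        Enzyme(r["name"], r["recognition"], int(r["cut_offset"]))
        for _, r in df.iterrows()
    ]


def get_enzyme(name: str, library: Iterable[Enzyme] | None = None) -> Enzyme:
    for enz in library if library is not None else load_enzyme_library():
        if enz.name == name:
            return enz
    raise HybdiagError(f"enzyme {name!r} not in library")
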