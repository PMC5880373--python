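"""Per-position channel-intensity model of polymorphic Sanger reads.

A direct read of a multi-copy marker from a hybrid or polymorphic individual
superimposes several templates; the electropherogram then shows secondary
peaks under the main ones. This module models such a read as a
:class:`TraceMatrix` — per column, four non-negative channel intensities
(A, C, G, T) normalised to sum to 1 — and provides:

- *major* / *sensitive* base calling: the major call ignores secondary peaks
  at or below a relative-intensity threshold (default 30% of total signal),
  while the sensitive call unions in every channel above a small floor
  (default 2%, the lower end of the signal range at which a rare second
  template remains readable by eye);
- simulation of a skewed two-template mixture, including the frame-shifted
  secondary peak train that a 1-bp indel between the templates produces
  downstream of the indel (a shift, and a backshift at a compensating indel);
- the winner-take-all artifact: an automatic base caller resolving each
  polymorphic position toward the locally taller peak, which turns a
  balanced mixture into a chimera of template states;
- detection of a minor component: scoring candidate templates against the
  secondary-signal columns under frame offsets, and segmenting the read into
  constant-offset stretches.

Noise is multiplicative log-normal per channel: what varies between
reactions is relative peak height, not an additive baseline. All stochastic
operations take an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .errors import ParameterError, TraceError
from .iupac import from_states

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

Source = Union[str, Path, TextIO]


@dataclass
class TraceMatrix:
    """Normalised per-column channel intensities, columns 1-based."""

    intensity: np.ndarray  # shape (length, 4), rows sum to 1
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise TraceError(f"trace must be (length, 4), got {arr.shape}")
        if (arr < 0).any():
            raise TraceError("negative channel intensity")
        sums = arr.sum(axis=1)
        zero = np.flatnonzero(sums == 0)
        if zero.size:
            raise TraceError(f"all-zero intensity at column {zero[0] + 1}")
        self.intensity = arr / sums[:, None]

    @property
    def length(self) -> int:
        return self.intensity.shape[0]

    def to_tsv(self, dest: Source) -> None:
        df = pd.DataFrame(self.intensity, columns=list(BASES))
        df.insert(0, "pos", np.arange(1, self.length + 1))
        df.to_csv(dest, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, source: Source, provenance: str = "") -> "TraceMatrix":
        df = pd.read_csv(source, sep="\t")
        missing = {"pos", *BASES} - set(df.columns)
        if missing:
            raise TraceError(f"trace TSV missing columns: {sorted(missing)}")
        df = df.sort_values("pos")
        return cls(df[list(BASES)].to_numpy(dtype=float), provenance=provenance)


@dataclass
class CallPolicy:
    """Thresholds for major vs sensitive base calling (fractions of total)."""

    major_threshold: float = 0.30
    sensitive_floor: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.sensitive_floor < self.major_threshold < 1:
            raise ParameterError(
                "require 0 < sensitive_floor < major_threshold < 1, got "
                f"floor={self.sensitive_floor}, threshold={self.major_threshold}"
            )


@dataclass(frozen=True)
class ShiftSegment:
    """A constant frame-offset stretch of the trace against a candidate."""

    start: int  # 1-based, inclusive
    end: int
    offset: int  # trace column minus candidate position
    candidate_id: str
    score: float  # match fraction among secondary-signal columns in range

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError(f"segment start {self.start} > end {self.end}")
        if not 0.0 <= self.score <= 1.0:
            raise ParameterError(f"segment score {self.score} outside [0, 1]")


def call_sequences(trace: TraceMatrix, policy: CallPolicy | None = None) -> tuple[str, str]:
    """Return the (major, sensitive) IUPAC sequences for a trace.

    Per column, the major symbol is the union of channels whose fraction
    strictly exceeds ``major_threshold`` (falling back to the tallest channel
    when none does); the sensitive symbol is the union of channels at or
    above ``sensitive_floor``. The major states are always a subset of the
    sensitive states.
    """
    policy = policy or CallPolicy()
    frac = trace.intensity
    major = []
    sensitive = []
    for i in range(trace.length):
        row = frac[i]
        above = row > policy.major_threshold
        if not above.any():
            above = row == row.max()
        major.append(from_states({BASES[j] for j in np.flatnonzero(above)}).symbol)
        sens = row >= policy.sensitive_floor
        sens |= row == row.max()  # the tallest channel is always called
        sensitive.append(from_states({BASES[j] for j in np.flatnonzero(sens)}).symbol)
    return "".join(major), "".join(sensitive)


def _check_hap(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq or any(ch not in _BASE_INDEX for ch in seq):
        raise ParameterError(f"{name} must be a non-empty ungapped A/C/G/T sequence")
    return seq


_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-3,
    extend_gap_score=-3,
)
# Gaps cost more than mismatches so substitutions are never explained away
# by spurious insertion/deletion pairs; only genuine indels open gaps.


def _aligned_pair(major_hap: str, minor_hap: str) -> tuple[str, str]:
    """Globally align the two haplotypes; returns (major, minor) gapped strings."""
    aln = next(iter(_ALIGNER.align(major_hap, minor_hap)))
    return str(aln[0]), str(aln[1])


def minor_offsets(major_hap: str, minor_hap: str) -> np.ndarray:
    """Frame offset (major position − minor position) per major column.

    Starts at 0 and shifts by ±1 at each 1-bp indel between the haplotypes;
    at a column where the minor template is gapped the offset of the
    following column applies.
    """
    aligned_major, aligned_minor = _aligned_pair(
        _check_hap(major_hap, "major_hap"), _check_hap(minor_hap, "minor_hap")
    )
    offsets = []
    i = j = 0
    for a, b in zip(aligned_major, aligned_minor):
        if a != "-" and b != "-":
            i += 1
            j += 1
            offsets.append(i - j)
        elif a != "-":  # deletion in minor
            i += 1
            offsets.append(i - j - 1)  # next minor base is j+1 -> i-(j+1)
        else:  # insertion in minor
            j += 1
    return np.array(offsets, dtype=int)


def simulate_mixture_trace(
    major_hap: str,
    minor_hap: str,
    minor_fraction: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TraceMatrix:
    """Simulate a direct read of a two-template mixture.

    Output columns index the major haplotype. Each column receives intensity
    ``1 - f`` on the major base and ``f`` on the minor base aligned to it
    (the alignment cursor shifts by ±1 at 1-bp indels, producing the
    shifted secondary peak train downstream of an indel; at a column where
    the minor template is gapped, the minor mass joins the major base).
    Multiplicative log-normal noise of sd ``noise_sd`` is applied per
    channel, then columns are renormalised. Deterministic for a fixed seed.
    """
    if not 0 < minor_fraction <= 0.5:
        raise ParameterError(f"minor_fraction must be in (0, 0.5], got {minor_fraction}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    major_hap = _check_hap(major_hap, "major_hap")
    minor_hap = _check_hap(minor_hap, "minor_hap")
    aligned_major, aligned_minor = _aligned_pair(major_hap, minor_hap)

    rows = []
    for a, b in zip(aligned_major, aligned_minor):
        if a == "-":
            continue  # insertion in minor consumes no output column
        row = np.zeros(4)
        row[_BASE_INDEX[a]] += 1.0 - minor_fraction
        row[_BASE_INDEX[b if b != "-" else a]] += minor_fraction
        rows.append(row)
    intensity = np.vstack(rows)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * rng.lognormal(0.0, noise_sd, intensity.shape)
    return TraceMatrix(intensity, provenance=f"mixture f={minor_fraction} sd={noise_sd}")


def winner_take_all_call(
    trace: TraceMatrix, jitter_sd: float = 0.0, seed: int | None = None
) -> str:
    """Emulate an automatic base caller that keeps only the tallest peak.

    Each channel is multiplied by an independent log-normal jitter of sd
    ``jitter_sd`` (reaction-typical variation of relative peak heights) and
    the argmax base is emitted. Applied to a balanced two-template mixture
    this yields a chimera: each polymorphic position resolved toward the
    locally taller peak. Deterministic for a fixed seed; ties broken toward
    the alphabetically first base.
    """
    if jitter_sd < 0:
        raise ParameterError(f"jitter_sd must be >= 0, got {jitter_sd}")
    frac = trace.intensity
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        frac = frac * rng.lognormal(0.0, jitter_sd, frac.shape)
    return "".join(BASES[j] for j in frac.argmax(axis=1))


def _secondary_signal(
    trace: TraceMatrix, policy: CallPolicy
) -> dict[int, set[str]]:
    """Columns (1-based) -> bases whose fraction lies in [floor, threshold]."""
    frac = trace.intensity
    out: dict[int, set[str]] = {}
    for i in range(trace.length):
        row = frac[i]
        mask = (row >= policy.sensitive_floor) & (row <= policy.major_threshold)
        if mask.any():
            out[i + 1] = {BASES[j] for j in np.flatnonzero(mask)}
    return out


def detect_minor_component(
    trace: TraceMatrix,
    candidates: dict[str, str] | Sequence[tuple[str, str]],
    policy: CallPolicy | None = None,
    max_offset: int = 2,
    window: int = 20,
) -> tuple[Optional[str], list[ShiftSegment]]:
    """Identify a minor template hiding in the secondary peaks of a trace.

    ``candidates`` maps candidate id -> ungapped sequence. For each candidate
    and each frame offset in [-max_offset, +max_offset] the fraction of
    secondary-signal columns matching the offset-shifted candidate is scored;
    the best-scoring candidate is returned together with a segmentation of
    the trace into constant-offset :class:`ShiftSegment` stretches. A new
    segment opens when a different offset outscores the current one over a
    sliding window of ``window`` trace columns; the boundary is placed just
    after the last column supporting the previous offset. Returns
    ``(None, [])`` when the trace carries no secondary signal at all.
    """
    policy = policy or CallPolicy()
    if isinstance(candidates, dict):
        cand_items = list(candidates.items())
    else:
        cand_items = list(candidates)
    if not cand_items:
        raise ParameterError("at least one candidate sequence is required")
    for cid, seq in cand_items:
        _check_hap(seq, f"candidate {cid!r}")

    secondary = _secondary_signal(trace, policy)
    if not secondary:
        return None, []
    cols = sorted(secondary)
    offsets = range(-max_offset, max_offset + 1)

    def matches(seq: str, col: int, off: int) -> bool:
        p = col - off  # 1-based candidate position
        return 1 <= p <= len(seq) and seq[p - 1] in secondary[col]

    # global score: best offset per candidate
    best_id, best_score = None, -1.0
    for cid, seq in cand_items:
        score = max(
            sum(matches(seq, c, off) for c in cols) / len(cols) for off in offsets
        )
        if score > best_score:
            best_id, best_score = cid, score
    best_seq = dict(cand_items)[best_id]

    # segmentation for the winning candidate via a forward windowed scan
    def window_scores(k: int) -> dict[int, float]:
        lo, hi = cols[k], cols[k] + window
        in_win = [c for c in cols[k:] if c < hi] or [cols[k]]
        return {
            off: sum(matches(best_seq, c, off) for c in in_win) / len(in_win)
            for off in offsets
        }

    def argmax_offset(ws: dict[int, float]) -> int:
        # ties prefer the smallest |offset| (no shift over shift)
        return max(sorted(ws, key=lambda o: (abs(o), o)), key=lambda o: ws[o])

    current = argmax_offset(window_scores(0))
    segments: list[ShiftSegment] = []
    seg_start = 1
    seg_cols: list[int] = []
    for k, col in enumerate(cols):
        ws = window_scores(k)
        challenger = argmax_offset(ws)
        # a column still matching the current offset never opens a segment
        if (
            challenger != current
            and ws[challenger] > ws[current]
            and not matches(best_seq, col, current)
        ):
            end = seg_cols[-1] if seg_cols else col - 1
            score = (
                sum(matches(best_seq, c, current) for c in seg_cols) / len(seg_cols)
                if seg_cols else 0.0
            )
            segments.append(ShiftSegment(seg_start, end, current, best_id, score))
            seg_start = end + 1
            current = challenger
            seg_cols = []
        seg_cols.append(col)
    score = (
        sum(matches(best_seq, c, current) for c in seg_cols) / len(seg_cols)
        if seg_cols else 0.0
    )
    segments.append(ShiftSegment(seg_start, trace.length, current, best_id, score))
    return best_id, segments
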