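"""Diagnostic sites, per-site additivity calls and the hybrid verdict.

A *diagnostic site* is an alignment column at which the state sets of the two
candidate parental taxa are disjoint. A putative hybrid showing, at such a
site, exactly the union of the parental states carries an *additive*
character — the molecular signature of hybridity in biparentally inherited
multi-copy markers. Aggregating per-site calls over all diagnostic sites
yields a verdict: a pure parental sequence, a (fully) additive hybrid read, a
chimeric read in which polymorphic positions were each resolved toward the
locally taller peak, or a partially resolved read biased toward one parent.

Column coordinates are 1-based throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional

import pandas as pd

from .alignment import Alignment, SampleGroup, warn
from .errors import HybdiagError
from .iupac import GAP, NucleotideStateSet, from_states, parse_symbol


class ConsensusMode(str, Enum):
    STRICT_UNION = "strict_union"
    MAJORITY = "majority"
    SINGLE_REFERENCE = "single_reference"


class PolymorphicSiteRule(str, Enum):
    #: Drop columns at which exactly one parent consensus is ambiguous —
    #: "sites containing intra-individual polymorphisms in only one sample
    #: or species are omitted".
    OMIT_IF_ONE_SIDED = "omit_if_one_sided"
    KEEP = "keep"


@dataclass
class ConsensusPolicy:
    mode: ConsensusMode = ConsensusMode.STRICT_UNION
    polymorphic_site_rule: PolymorphicSiteRule = PolymorphicSiteRule.OMIT_IF_ONE_SIDED

    def __post_init__(self) -> None:
        self.mode = ConsensusMode(self.mode)
        self.polymorphic_site_rule = PolymorphicSiteRule(self.polymorphic_site_rule)


@dataclass(frozen=True)
class DiagnosticSite:
    """A column at which the parental state sets are disjoint."""

    column: int  # 1-based
    state_a: NucleotideStateSet
    state_b: NucleotideStateSet

    def __post_init__(self) -> None:
        if self.state_a.states & self.state_b.states:
            raise HybdiagError(
                f"column {self.column}: parental states overlap, not diagnostic"
            )


class Call(str, Enum):
    ADDITIVE = "ADDITIVE"
    PARENT_A = "PARENT_A"
    PARENT_B = "PARENT_B"
    OTHER = "OTHER"
    MISSING = "MISSING"


@dataclass(frozen=True)
class SiteCall:
    site: DiagnosticSite
    query_symbol: str
    call: Call


class Verdict(str, Enum):
    PURE_A = "PURE_A"
    PURE_B = "PURE_B"
    HYBRID_FULL = "HYBRID_FULL"
    HYBRID = "HYBRID"
    PARTIALLY_RESOLVED = "PARTIALLY_RESOLVED"
    CHIMERIC = "CHIMERIC"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class VerdictThresholds:
    """Decision-table cutoffs; compared with >= / <= as written.

    With a = additivity index, fA/fB = parent-specific fractions over usable
    (non-missing) diagnostic sites:

    - PURE_A  if fA >= pure_parent_min and a <= pure_additive_max (B symmetric)
    - HYBRID_FULL if a == 1
    - HYBRID  if a >= hybrid_min
    - CHIMERIC if a < hybrid_min and min(fA, fB) >= chimeric_minor_min
    - PARTIALLY_RESOLVED if partial_additive_min <= a < hybrid_min
      and max(fA, fB) >= partial_parent_min
    - else AMBIGUOUS
    """

    pure_parent_min: float = 0.95
    pure_additive_max: float = 0.05
    hybrid_min: float = 0.80
    chimeric_minor_min: float = 0.20
    partial_additive_min: float = 0.10
    partial_parent_min: float = 0.50


@dataclass
class AdditivityReport:
    n_diagnostic: int
    n_additive: int
    n_parent_a: int
    n_parent_b: int
    n_other: int
    n_missing: int
    additivity_index: Optional[float]
    verdict: Verdict
    site_calls: list[SiteCall] = field(default_factory=list)
    thresholds: VerdictThresholds = field(default_factory=VerdictThresholds)
    policy: ConsensusPolicy = field(default_factory=ConsensusPolicy)
    note: str = ""

    def counts(self) -> dict[str, int]:
        return {
            "n_diagnostic": self.n_diagnostic,
            "n_additive": self.n_additive,
            "n_parent_a": self.n_parent_a,
            "n_parent_b": self.n_parent_b,
            "n_other": self.n_other,
            "n_missing": self.n_missing,
        }

    def to_json(self, indent: int = 2) -> str:
        payload = {
            **self.counts(),
            "additivity_index": (
                None if self.additivity_index is None
                else round(self.additivity_index, 3)
            ),
            "verdict": self.verdict.value,
            "thresholds": asdict(self.thresholds),
            "policy": {
                "mode": self.policy.mode.value,
                "polymorphic_site_rule": self.policy.polymorphic_site_rule.value,
            },
            "note": self.note,
        }
        return json.dumps(payload, indent=indent)

    def per_site_frame(self) -> pd.DataFrame:
        rows = [
            {
                "column": sc.site.column,
                "stateA": sc.site.state_a.symbol,
                "stateB": sc.site.state_b.symbol,
                "query": sc.query_symbol,
                "call": sc.call.value,
            }
            for sc in self.site_calls
        ]
        return pd.DataFrame(rows, columns=["column", "stateA", "stateB", "query", "call"])


MISSING = None  # sentinel returned by parent_consensus for all-gap columns


def parent_consensus(
    alignment: Alignment,
    group: SampleGroup,
    column: int,
    policy: ConsensusPolicy | None = None,
) -> Optional[NucleotideStateSet]:
    """Consensus state set of one parental group at a 1-based column.

    Returns ``None`` (missing) when every group member is gapped. Gapped
    members are ignored otherwise; the gap-exclusion rule for diagnostic
    sites lives in :func:`find_diagnostic_sites`.
    """
    policy = policy or ConsensusPolicy()
    symbols = [s for s in alignment.column(column, group.sequence_ids) if s != GAP]
    if not symbols:
        return MISSING
    if policy.mode is ConsensusMode.SINGLE_REFERENCE:
        ref = alignment[group.sequence_ids[0]].symbol_at(column)
        return MISSING if ref == GAP else parse_symbol(ref)
    if policy.mode is ConsensusMode.MAJORITY:
        freq: dict[str, int] = {}
        for s in symbols:
            freq[s] = freq.get(s, 0) + 1
        top = max(freq.values())
        tied = [s for s, n in freq.items() if n == top]
        states = frozenset().union(*(parse_symbol(s).states for s in tied))
        return from_states(states)
    # strict_union
    states = frozenset().union(*(parse_symbol(s).states for s in symbols))
    return from_states(states)


def find_diagnostic_sites(
    alignment: Alignment,
    parent_a: SampleGroup,
    parent_b: SampleGroup,
    policy: ConsensusPolicy | None = None,
) -> list[DiagnosticSite]:
    """All columns at which the two parental consensus state sets are disjoint.

    Columns are excluded when (i) any parental member is gapped there (indels
    are coded separately, not treated as additivity characters), (ii) a
    consensus is missing, or (iii) under ``omit_if_one_sided``, exactly one
    of the two consensus sets is ambiguous — the rule that drops sites
    polymorphic in only one species. Two-sided polymorphic columns are kept
    only when the two unions are disjoint.
    """
    policy = policy or ConsensusPolicy()
    sites: list[DiagnosticSite] = []
    for col in range(1, alignment.length + 1):
        col_a = alignment.column(col, parent_a.sequence_ids)
        col_b = alignment.column(col, parent_b.sequence_ids)
        if GAP in col_a or GAP in col_b:
            continue
        cons_a = parent_consensus(alignment, parent_a, col, policy)
        cons_b = parent_consensus(alignment, parent_b, col, policy)
        if cons_a is MISSING or cons_b is MISSING:
            continue
        if policy.polymorphic_site_rule is PolymorphicSiteRule.OMIT_IF_ONE_SIDED:
            if cons_a.is_ambiguous != cons_b.is_ambiguous:
                continue
        if cons_a.states & cons_b.states:
            continue
        sites.append(DiagnosticSite(col, cons_a, cons_b))
    if not sites:
        warn("no diagnostic sites found between the parental groups")
    return sites


def classify_site(site: DiagnosticSite, query_symbol: str) -> SiteCall:
    """Classify the query symbol at one diagnostic site.

    ADDITIVE iff states(query) equals the union of both parental sets;
    PARENT_A / PARENT_B iff it equals one parental set exactly; gap is
    MISSING; everything else is OTHER.
    """
    if query_symbol == GAP:
        return SiteCall(site, query_symbol, Call.MISSING)
    q = parse_symbol(query_symbol).states
    if q == site.state_a.states | site.state_b.states:
        call = Call.ADDITIVE
    elif q == site.state_a.states:
        call = Call.PARENT_A
    elif q == site.state_b.states:
        call = Call.PARENT_B
    else:
        call = Call.OTHER
    return SiteCall(site, query_symbol.upper(), call)


def _verdict_from_counts(
    n_additive: int,
    n_parent_a: int,
    n_parent_b: int,
    n_usable: int,
    thresholds: VerdictThresholds,
) -> Verdict:
    a = n_additive / n_usable
    f_a = n_parent_a / n_usable
    f_b = n_parent_b / n_usable
    t = thresholds
    if f_a >= t.pure_parent_min and a <= t.pure_additive_max:
        return Verdict.PURE_A
    if f_b >= t.pure_parent_min and a <= t.pure_additive_max:
        return Verdict.PURE_B
    if a == 1.0:
        return Verdict.HYBRID_FULL
    if a >= t.hybrid_min:
        return Verdict.HYBRID
    if min(f_a, f_b) >= t.chimeric_minor_min:
        return Verdict.CHIMERIC
    if t.partial_additive_min <= a and max(f_a, f_b) >= t.partial_parent_min:
        return Verdict.PARTIALLY_RESOLVED
    return Verdict.AMBIGUOUS


def diagnose(
    alignment: Alignment,
    parent_a: SampleGroup,
    parent_b: SampleGroup,
    query: SampleGroup,
    policy: ConsensusPolicy | None = None,
    thresholds: VerdictThresholds | None = None,
) -> AdditivityReport:
    """Run the full additivity analysis for a single query sequence."""
    if len(query.sequence_ids) != 1:
        raise HybdiagError("query group must contain exactly one sequence")
    policy = policy or ConsensusPolicy()
    thresholds = thresholds or VerdictThresholds()
    alignment.validate_groups([parent_a, parent_b, query])
    sites = find_diagnostic_sites(alignment, parent_a, parent_b, policy)
    query_seq = alignment[query.sequence_ids[0]]
    calls = [classify_site(s, query_seq.symbol_at(s.column)) for s in sites]

    tally = {c: 0 for c in Call}
    for sc in calls:
        tally[sc.call] += 1
    n_diag = len(sites)
    n_usable = n_diag - tally[Call.MISSING]
    if n_usable == 0:
        return AdditivityReport(
            n_diagnostic=n_diag,
            n_additive=tally[Call.ADDITIVE],
            n_parent_a=tally[Call.PARENT_A],
            n_parent_b=tally[Call.PARENT_B],
            n_other=tally[Call.OTHER],
            n_missing=tally[Call.MISSING],
            additivity_index=None,
            verdict=Verdict.AMBIGUOUS,
            site_calls=calls,
            thresholds=thresholds,
            policy=policy,
            note="no usable diagnostic sites (all missing or none found)",
        )
    verdict = _verdict_from_counts(
        tally[Call.ADDITIVE], tally[Call.PARENT_A], tally[Call.PARENT_B],
        n_usable, thresholds,
    )
    return AdditivityReport(
        n_diagnostic=n_diag,
        n_additive=tally[Call.ADDITIVE],
        n_parent_a=tally[Call.PARENT_A],
        n_parent_b=tally[Call.PARENT_B],
        n_other=tally[Call.OTHER],
        n_missing=tally[Call.MISSING],
        additivity_index=tally[Call.ADDITIVE] / n_usable,
        verdict=verdict,
        site_calls=calls,
        thresholds=thresholds,
        policy=policy,
    )
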