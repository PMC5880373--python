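"""Diagnostic-site finding, per-site calls and the verdict table."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hybdiag.additivity import (
    Call,
    ConsensusMode,
    ConsensusPolicy,
    DiagnosticSite,
    PolymorphicSiteRule,
    Verdict,
    classify_site,
    diagnose,
    find_diagnostic_sites,
    parent_consensus,
)
from hybdiag.alignment import AlignedSequence, Alignment, Role, SampleGroup
from hybdiag.errors import HybdiagError
from hybdiag.iupac import GAP, STATES, from_states, parse_symbol
from hybdiag.simulate import partition_case


def make_alignment(rows):
    return Alignment([AlignedSequence(i, s) for i, s in rows])


def groups_for(a_ids, b_ids, q_ids=()):
    g = {
        Role.PARENT_A: SampleGroup(Role.PARENT_A, list(a_ids)),
        Role.PARENT_B: SampleGroup(Role.PARENT_B, list(b_ids)),
    }
    if q_ids:
        g[Role.QUERY] = SampleGroup(Role.QUERY, list(q_ids))
    return g


class TestParentConsensus:
    def test_strict_union_of_identical_members(self):
        aln = make_alignment([("a1", "A"), ("a2", "A")])
        g = SampleGroup(Role.PARENT_A, ["a1", "a2"])
        assert parent_consensus(aln, g, 1).states == {"A"}

    def test_strict_union_merges_ambiguity(self):
        aln = make_alignment([("a1", "A"), ("a2", "R")])
        g = SampleGroup(Role.PARENT_A, ["a1", "a2"])
        assert parent_consensus(aln, g, 1).states == {"A", "G"}

    def test_majority_picks_most_frequent(self):
        # frequency-count oracle: C appears 2/3 times
        aln = make_alignment([("a1", "C"), ("a2", "T"), ("a3", "C")])
        g = SampleGroup(Role.PARENT_A, ["a1", "a2", "a3"])
        policy = ConsensusPolicy(mode=ConsensusMode.MAJORITY)
        assert parent_consensus(aln, g, 1, policy).states == {"C"}

    def test_majority_tie_unions_tied_symbols(self):
        aln = make_alignment([("a1", "C"), ("a2", "T")])
        g = SampleGroup(Role.PARENT_A, ["a1", "a2"])
        policy = ConsensusPolicy(mode=ConsensusMode.MAJORITY)
        assert parent_consensus(aln, g, 1, policy).states == {"C", "T"}

    def test_single_reference_uses_first_id(self):
        aln = make_alignment([("a1", "C"), ("a2", "T")])
        g = SampleGroup(Role.PARENT_A, ["a2", "a1"])
        policy = ConsensusPolicy(mode=ConsensusMode.SINGLE_REFERENCE)
        assert parent_consensus(aln, g, 1, policy).states == {"T"}

    def test_all_gap_column_is_missing(self):
        aln = make_alignment([("a1", "-A"), ("a2", "-A")])
        g = SampleGroup(Role.PARENT_A, ["a1", "a2"])
        assert parent_consensus(aln, g, 1) is None


class TestFindDiagnosticSites:
    def test_simple_disjoint_column(self):
        aln = make_alignment([("a", "A"), ("b", "G")])
        g = groups_for(["a"], ["b"])
        sites = find_diagnostic_sites(aln, g[Role.PARENT_A], g[Role.PARENT_B])
        assert [(s.column, s.state_a.symbol, s.state_b.symbol) for s in sites] == [
            (1, "A", "G")
        ]

    def test_overlapping_states_not_diagnostic(self):
        aln = make_alignment([("a", "A"), ("b", "R")])
        g = groups_for(["a"], ["b"])
        policy = ConsensusPolicy(polymorphic_site_rule=PolymorphicSiteRule.KEEP)
        assert find_diagnostic_sites(aln, g[Role.PARENT_A], g[Role.PARENT_B], policy) == []

    def test_one_sided_polymorphism_omitted(self):
        # Y vs A is disjoint, but only one side is polymorphic -> omitted
        aln = make_alignment([("a", "Y"), ("b", "A")])
        g = groups_for(["a"], ["b"])
        assert find_diagnostic_sites(aln, g[Role.PARENT_A], g[Role.PARENT_B]) == []
        policy = ConsensusPolicy(polymorphic_site_rule=PolymorphicSiteRule.KEEP)
        kept = find_diagnostic_sites(aln, g[Role.PARENT_A], g[Role.PARENT_B], policy)
        assert [s.column for s in kept] == [1]

    def test_two_sided_polymorphism_kept_when_disjoint(self):
        aln = make_alignment([("a", "Y"), ("b", "R")])
        g = groups_for(["a"], ["b"])
        sites = find_diagnostic_sites(aln, g[Role.PARENT_A], g[Role.PARENT_B])
        assert [s.column for s in sites] == [1]

    def test_gap_in_any_parent_member_excludes_column(self):
        aln = make_alignment([("a1", "A"), ("a2", "-"), ("b", "G")])
        g = groups_for(["a1", "a2"], ["b"])
        assert find_diagnostic_sites(aln, g[Role.PARENT_A], g[Role.PARENT_B]) == []


def brute_force_sites(aln, a_ids, b_ids, rule=PolymorphicSiteRule.OMIT_IF_ONE_SIDED):
    """Independent per-column oracle, written from the definition."""
    found = []
    for col in range(1, aln.length + 1):
        sym_a = [aln[i].symbol_at(col) for i in a_ids]
        sym_b = [aln[i].symbol_at(col) for i in b_ids]
        if "-" in sym_a or "-" in sym_b:
            continue
        set_a = set().union(*(STATES[s] for s in sym_a))
        set_b = set().union(*(STATES[s] for s in sym_b))
        if rule is PolymorphicSiteRule.OMIT_IF_ONE_SIDED and (
            (len(set_a) > 1) != (len(set_b) > 1)
        ):
            continue
        if set_a & set_b:
            continue
        found.append((col, frozenset(set_a), frozenset(set_b)))
    return found


@given(data=st.data())
def test_site_finder_equals_brute_force_oracle(data):
    alphabet = "ACGTRYSWKMN-"
    n_cols = data.draw(st.integers(20, 60))
    rows = []
    for sid in ("a1", "a2", "b1", "b2"):
        rows.append((sid, "".join(
            data.draw(st.sampled_from(alphabet)) for _ in range(n_cols)
        )))
    try:
        aln = make_alignment(rows)
    except HybdiagError:
        return
    g = groups_for(["a1", "a2"], ["b1", "b2"])
    got = find_diagnostic_sites(aln, g[Role.PARENT_A], g[Role.PARENT_B])
    expected = brute_force_sites(aln, ["a1", "a2"], ["b1", "b2"])
    assert [(s.column, s.state_a.states, s.state_b.states) for s in got] == expected


class TestClassifySite:
    @pytest.mark.parametrize(
        "query,call",
        [("Y", Call.ADDITIVE), ("C", Call.PARENT_A), ("T", Call.PARENT_B),
         ("G", Call.OTHER), ("-", Call.MISSING), ("H", Call.OTHER)],
    )
    def test_c_vs_t_site(self, query, call):
        site = DiagnosticSite(5, parse_symbol("C"), parse_symbol("T"))
        assert classify_site(site, query).call is call

    def test_additive_against_polymorphic_parents(self):
        site = DiagnosticSite(1, parse_symbol("M"), parse_symbol("T"))
        assert classify_site(site, "H").call is Call.ADDITIVE
        assert classify_site(site, "M").call is Call.PARENT_A


class TestDiagnoseVerdicts:
    def run(self, *counts, **kw):
        aln, g = partition_case(*counts, **kw)
        return diagnose(aln, g[Role.PARENT_A], g[Role.PARENT_B], g[Role.QUERY])

    def test_full_additivity_is_hybrid_full(self):
        report = self.run(28, 0, 0, seed=11)
        assert report.n_diagnostic == 28
        assert report.n_additive == 28
        assert report.additivity_index == 1.0
        assert report.verdict is Verdict.HYBRID_FULL

    def test_mosaic_toward_both_parents_is_chimeric(self):
        report = self.run(8, 13, 18, seed=12)
        assert report.counts()["n_parent_a"] == 13
        assert report.verdict is Verdict.CHIMERIC

    def test_mosaic_toward_one_parent_is_partially_resolved(self):
        report = self.run(10, 1, 17, seed=13)
        assert report.verdict is Verdict.PARTIALLY_RESOLVED

    def test_query_identical_to_parent_is_pure(self):
        report = self.run(0, 25, 0, seed=14)
        assert report.verdict is Verdict.PURE_A
        report = self.run(0, 0, 25, seed=15)
        assert report.verdict is Verdict.PURE_B

    def test_no_usable_sites_is_ambiguous(self):
        aln = make_alignment([("parentA", "AAAA"), ("parentB", "AAAA"),
                              ("query", "AAAA")])
        g = groups_for(["parentA"], ["parentB"], ["query"])
        report = diagnose(aln, g[Role.PARENT_A], g[Role.PARENT_B], g[Role.QUERY])
        assert report.verdict is Verdict.AMBIGUOUS
        assert report.additivity_index is None
        assert report.note

    def test_query_must_be_single_sequence(self):
        aln = make_alignment([("a", "A"), ("b", "G"), ("q1", "A"), ("q2", "G")])
        g = groups_for(["a"], ["b"])
        with pytest.raises(HybdiagError, match="exactly one"):
            diagnose(aln, g[Role.PARENT_A], g[Role.PARENT_B],
                     SampleGroup(Role.QUERY, ["q1", "q2"]))


@given(seed=st.integers(0, 10_000))
def test_counts_partition_and_swap_symmetry(seed):
    """Calls partition the diagnostic sites; relabelling the parents swaps
    PARENT_A/PARENT_B counts and PURE verdicts but leaves the additivity
    index and HYBRID/CHIMERIC verdicts unchanged."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 12, size=5)  # additive, pA, pB, other, missing
    if counts[:4].sum() == 0:
        counts[0] = 3
    aln, g = partition_case(*map(int, counts), seed=seed)
    rep = diagnose(aln, g[Role.PARENT_A], g[Role.PARENT_B], g[Role.QUERY])
    c = rep.counts()
    assert (
        c["n_additive"] + c["n_parent_a"] + c["n_parent_b"]
        + c["n_other"] + c["n_missing"] == c["n_diagnostic"]
    )
    swapped = diagnose(aln, g[Role.PARENT_B], g[Role.PARENT_A], g[Role.QUERY])
    sc = swapped.counts()
    assert sc["n_parent_a"] == c["n_parent_b"]
    assert sc["n_parent_b"] == c["n_parent_a"]
    assert sc["n_additive"] == c["n_additive"]
    assert swapped.additivity_index == rep.additivity_index
    mapping = {Verdict.PURE_A: Verdict.PURE_B, Verdict.PURE_B: Verdict.PURE_A}
    assert swapped.verdict is mapping.get(rep.verdict, rep.verdict)


def test_report_serialization_round_trip(tmp_path):
    aln, g = partition_case(5, 2, 3, n_other=1, seed=9)
    rep = diagnose(aln, g[Role.PARENT_A], g[Role.PARENT_B], g[Role.QUERY])
    payload = rep.to_json()
    assert '"verdict"' in payload and '"additivity_index"' in payload
    frame = rep.per_site_frame()
    assert len(frame) == rep.n_diagnostic
    assert set(frame["call"]) <= {c.value for c in Call}
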