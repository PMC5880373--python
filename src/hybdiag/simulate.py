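"""Synthetic parental haplotypes, hybrid/pure/chimeric reads, and traces.

The generator emulates the statistical structure the diagnosis assumes for a
pair of candidate parental taxa in a multi-copy nuclear marker:

- two parental haplotypes at a per-site divergence *d* (default 0.05 over
  600 bp, yielding ~30 diagnostic sites — the density at which diagnostic
  counts in the tens arise from ~600-bp spacer alignments);
- two 1-bp indels between the parents, one early and one late, so that a
  minor component in a mixed trace produces a frame shift and a later
  backshift in the secondary peak train;
- intra-individual polymorphism: with rate ρ a position carries the union
  of its base and one random other base (bi-allelic ambiguity), as
  incomplete concerted evolution produces even in non-hybrid species;
- query categories: PURE_A / PURE_B (a parental read), HYBRID (a mixed
  trace at minor fraction *f*, read off as the sensitive IUPAC call) and
  CHIMERIC (a balanced mixture resolved winner-take-all per column).

Every operation is deterministic under the scenario seed; truth records
match the emitted files exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .alignment import (
    AlignedSequence,
    Alignment,
    Role,
    SampleGroup,
    write_alignment,
    write_manifest,
)
from .additivity import (
    AdditivityReport,
    ConsensusPolicy,
    VerdictThresholds,
    diagnose,
)
from .errors import ParameterError
from .iupac import GAP, union_symbol
from .trace import (
    CallPolicy,
    TraceMatrix,
    call_sequences,
    simulate_mixture_trace,
    winner_take_all_call,
)

BASES = "ACGT"


class Category(str, Enum):
    PURE_A = "PURE_A"
    PURE_B = "PURE_B"
    HYBRID = "HYBRID"
    CHIMERIC = "CHIMERIC"


@dataclass
class ScenarioSpec:
    """Parameters of one simulated study condition.

    ``indels`` holds (position, signed length) pairs in parent-A
    coordinates: negative = deletion in parent B at that position,
    positive = insertion in parent B after that position. The default —
    a 1-bp deletion at L/6 and a 1-bp insertion at 5L/6 — reproduces the
    shift-then-backshift signature of two compensating 1-bp indels.
    """

    length: int = 600
    divergence: float = 0.05
    indels: tuple[tuple[int, int], ...] | None = None
    intra_polymorphism_rate: float = 0.05
    minor_fraction: float = 0.5
    noise_sd: float = 0.1
    artifact_mode: str = "none"  # none | winner_take_all
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ParameterError("length must be positive")
        if not 0 <= self.divergence <= 1:
            raise ParameterError("divergence must be in [0, 1]")
        if not 0 <= self.intra_polymorphism_rate <= 1:
            raise ParameterError("intra_polymorphism_rate must be in [0, 1]")
        if not 0 < self.minor_fraction <= 0.5:
            raise ParameterError("minor_fraction must be in (0, 0.5]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.artifact_mode not in ("none", "winner_take_all"):
            raise ParameterError(f"unknown artifact_mode {self.artifact_mode!r}")
        if self.indels is None:
            self.indels = ((max(self.length // 6, 1), -1),
                           (max(5 * self.length // 6, 1), 1))
        self.indels = tuple(tuple(i) for i in self.indels)
        for pos, delta in self.indels:
            if not 1 <= pos <= self.length or delta == 0:
                raise ParameterError(f"bad indel spec ({pos}, {delta})")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ScenarioSpec":
        data = yaml.safe_load(Path(source).read_text())
        if "indels" in data:
            data["indels"] = tuple(tuple(x) for x in data["indels"])
        return cls(**data)


@dataclass
class ParentPair:
    """Two parental haplotypes plus their (known) pairwise alignment."""

    hap_a: str
    hap_b: str
    aligned_a: str
    aligned_b: str

    @property
    def aligned_length(self) -> int:
        return len(self.aligned_a)

    def diagnostic_columns(self) -> list[int]:
        """Aligned columns where both parents have (differing) bases."""
        return [
            i + 1
            for i, (a, b) in enumerate(zip(self.aligned_a, self.aligned_b))
            if a != GAP and b != GAP and a != b
        ]


@dataclass
class TruthRecord:
    category: Category
    sample_id: str
    pair: ParentPair
    diagnostic_columns: list[int]
    scenario: dict = field(default_factory=dict)
    sample_seed: int = 0


def generate_parent_pair(spec: ScenarioSpec, seed: int | None = None) -> ParentPair:
    """Draw a parental haplotype pair under the scenario.

    Parent A is i.i.d. uniform over A/C/G/T; parent B substitutes each site
    to a different base with probability ``divergence`` and then applies the
    scenario's indels. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.length
    a = rng.integers(0, 4, size=L)
    sub = rng.random(L) < spec.divergence
    # a different base: add 1..3 mod 4
    b = np.where(sub, (a + rng.integers(1, 4, size=L)) % 4, a)
    hap_a = "".join(BASES[i] for i in a)
    b_bases = [BASES[i] for i in b]

    deletions = {pos for pos, delta in spec.indels if delta < 0}
    insertions = {pos: "".join(rng.choice(list(BASES), size=delta))
                  for pos, delta in spec.indels if delta > 0}

    al_a, al_b = [], []
    for p in range(1, L + 1):
        al_a.append(hap_a[p - 1])
        al_b.append(GAP if p in deletions else b_bases[p - 1])
        if p in insertions:
            for ins_base in insertions[p]:
                al_a.append(GAP)
                al_b.append(ins_base)
    aligned_a = "".join(al_a)
    aligned_b = "".join(al_b)
    return ParentPair(
        hap_a=hap_a,
        hap_b=aligned_b.replace(GAP, ""),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
    )


def inject_polymorphisms(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Replace bases, at the given per-site rate, with a bi-allelic code.

    Each hit site becomes the IUPAC union of its base and one random other
    base — the ambiguity pattern intra-individual polymorphism leaves in a
    direct read.
    """
    if rate == 0:
        return sequence
    out = list(sequence)
    hits = np.flatnonzero(rng.random(len(sequence)) < rate)
    for i in hits:
        other = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
        out[i] = union_symbol(out[i], other)
    return "".join(out)


@dataclass
class Sample:
    """One generated query read (and its trace, where one exists)."""

    read: str  # ungapped IUPAC sequence
    frame: str  # 'A' or 'B': which parent's coordinates the read indexes
    trace: TraceMatrix | None
    truth: TruthRecord


def generate_sample(
    spec: ScenarioSpec,
    category: Category | str,
    sample_id: str = "query",
    pair: ParentPair | None = None,
    seed: int | None = None,
) -> Sample:
    """Generate one query read of the requested category.

    PURE_*: the parent haplotype with ambiguity codes injected at rate ρ.
    HYBRID: sensitive IUPAC call of a simulated mixture at fraction *f*.
    CHIMERIC: winner-take-all call of a balanced mixture under peak-height
    jitter of sd ``noise_sd``.
    """
    category = Category(category)
    base_seed = spec.seed if seed is None else seed
    if pair is None:
        pair = generate_parent_pair(spec, seed=base_seed)
    rng = np.random.default_rng(base_seed + 1)
    trace: TraceMatrix | None = None

    if category in (Category.PURE_A, Category.PURE_B):
        hap = pair.hap_a if category is Category.PURE_A else pair.hap_b
        read = inject_polymorphisms(hap, spec.intra_polymorphism_rate, rng)
        frame = "A" if category is Category.PURE_A else "B"
    elif category is Category.HYBRID:
        trace = simulate_mixture_trace(
            pair.hap_a, pair.hap_b, spec.minor_fraction, spec.noise_sd,
            seed=base_seed + 2,
        )
        _, read = call_sequences(trace, CallPolicy())
        frame = "A"
    else:  # CHIMERIC
        trace = simulate_mixture_trace(
            pair.hap_a, pair.hap_b, 0.5, 0.0, seed=base_seed + 2
        )
        read = winner_take_all_call(trace, jitter_sd=spec.noise_sd, seed=base_seed + 3)
        frame = "A"

    truth = TruthRecord(
        category=category,
        sample_id=sample_id,
        pair=pair,
        diagnostic_columns=pair.diagnostic_columns(),
        scenario=asdict(spec),
        sample_seed=base_seed,
    )
    return Sample(read=read, frame=frame, trace=trace, truth=truth)


def place_on_frame(read: str, gapped_frame_row: str) -> str:
    """Lay an ungapped read onto its parent's gapped alignment row."""
    n_bases = sum(1 for c in gapped_frame_row if c != GAP)
    if len(read) != n_bases:
        raise ParameterError(
            f"read length {len(read)} != frame base count {n_bases}"
        )
    it = iter(read)
    return "".join(next(it) if c != GAP else GAP for c in gapped_frame_row)


def build_case_alignment(
    sample: Sample,
    parent_a_id: str = "parentA",
    parent_b_id: str = "parentB",
    query_id: str = "query",
) -> tuple[Alignment, dict[Role, SampleGroup]]:
    """Parents + query as one alignment with its role manifest."""
    pair = sample.truth.pair
    frame_row = pair.aligned_a if sample.frame == "A" else pair.aligned_b
    aln = Alignment([
        AlignedSequence(parent_a_id, pair.aligned_a),
        AlignedSequence(parent_b_id, pair.aligned_b),
        AlignedSequence(query_id, place_on_frame(sample.read, frame_row)),
    ])
    groups = {
        Role.PARENT_A: SampleGroup(Role.PARENT_A, [parent_a_id]),
        Role.PARENT_B: SampleGroup(Role.PARENT_B, [parent_b_id]),
        Role.QUERY: SampleGroup(Role.QUERY, [query_id]),
    }
    return aln, groups


def diagnose_sample(
    sample: Sample,
    policy: ConsensusPolicy | None = None,
    thresholds: VerdictThresholds | None = None,
) -> AdditivityReport:
    """Run the additivity diagnosis on one generated sample."""
    aln, groups = build_case_alignment(sample)
    return diagnose(
        aln,
        groups[Role.PARENT_A],
        groups[Role.PARENT_B],
        groups[Role.QUERY],
        policy=policy,
        thresholds=thresholds,
    )


def partition_case(
    n_additive: int,
    n_parent_a: int,
    n_parent_b: int,
    n_other: int = 0,
    n_missing: int = 0,
    n_background: int = 60,
    seed: int = 0,
) -> tuple[Alignment, dict[Role, SampleGroup]]:
    """Construct a parents+query alignment realising a given site partition.

    Useful for rebuilding published re-analyses from their printed counts:
    the returned alignment has exactly ``n_additive + n_parent_a +
    n_parent_b + n_other + n_missing`` diagnostic columns, at which the
    query shows the requested call, embedded among invariant background
    columns in seeded random order.
    """
    rng = np.random.default_rng(seed)
    columns: list[tuple[str, str, str]] = []  # (parentA, parentB, query)

    def draw_pair() -> tuple[str, str]:
        i = int(rng.integers(0, 4))
        j = (i + int(rng.integers(1, 4))) % 4
        return BASES[i], BASES[j]

    for _ in range(n_additive):
        a, b = draw_pair()
        columns.append((a, b, union_symbol(a, b)))
    for _ in range(n_parent_a):
        a, b = draw_pair()
        columns.append((a, b, a))
    for _ in range(n_parent_b):
        a, b = draw_pair()
        columns.append((a, b, b))
    for _ in range(n_other):
        a, b = draw_pair()
        third = next(x for x in BASES if x not in (a, b))
        columns.append((a, b, third))
    for _ in range(n_missing):
        a, b = draw_pair()
        columns.append((a, b, GAP))
    for _ in range(n_background):
        x = BASES[int(rng.integers(0, 4))]
        columns.append((x, x, x))

    order = rng.permutation(len(columns))
    rows = ["".join(columns[k][r] for k in order) for r in range(3)]
    aln = Alignment([
        AlignedSequence("parentA", rows[0]),
        AlignedSequence("parentB", rows[1]),
        AlignedSequence("query", rows[2]),
    ])
    groups = {
        Role.PARENT_A: SampleGroup(Role.PARENT_A, ["parentA"]),
        Role.PARENT_B: SampleGroup(Role.PARENT_B, ["parentB"]),
        Role.QUERY: SampleGroup(Role.QUERY, ["query"]),
    }
    return aln, groups


def generate_benchmark(
    spec: ScenarioSpec,
    n_per_category: int,
    out_dir: str | Path,
) -> dict:
    """Write a benchmark of known-truth cases; returns the manifest.

    Each sample is an independent draw (its own parent pair and query) under
    seeds derived from the scenario seed; files are FASTA case alignments,
    role manifests, trace TSVs where a trace exists, plus one ``truth.json``.
    Regeneration with the same scenario is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(spec.seed)
    manifest: dict = {"scenario": asdict(spec), "samples": []}
    for category in Category:
        for rep in range(n_per_category):
            sid = f"{category.value.lower()}_{rep:03d}"
            child_seed = int(master.integers(0, 2**31 - 1))
            sample = generate_sample(spec, category, sample_id=sid, seed=child_seed)
            aln, groups = build_case_alignment(sample)
            fasta = out / f"{sid}.aln.fasta"
            write_alignment(aln, fasta)
            groups_tsv = out / f"{sid}.groups.tsv"
            write_manifest(groups.values(), groups_tsv)
            entry = {
                "sample_id": sid,
                "category": category.value,
                "seed": child_seed,
                "alignment": fasta.name,
                "manifest": groups_tsv.name,
                "diagnostic_columns": sample.truth.diagnostic_columns,
            }
            if sample.trace is not None:
                trace_tsv = out / f"{sid}.trace.tsv"
                sample.trace.to_tsv(trace_tsv)
                entry["trace"] = trace_tsv.name
            manifest["samples"].append(entry)
    (out / "truth.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
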