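# Methods

## Model

A direct Sanger read of a multi-copy nuclear marker from an individual
carrying two ribotypes is modelled as a column-wise mixture of the two
template sequences: at output column *i* (indexed on the dominant template)
the four-channel intensity vector is

    I(i) = (1 − f) · e(major_i) + f · e(minor_j) ,

where `e(b)` is the unit vector of base *b*, `f ∈ (0, 0.5]` is the minor
ribotype's share of the signal, and *j* is the minor-template position
aligned to *i*. The alignment cursor *j* shifts by ±1 at each 1-bp indel
between the templates, so every secondary peak downstream of an indel is
displaced by the accumulated offset — the shift/backshift signature that a
pair of compensating 1-bp indels produces. At columns where the minor
template is gapped its mass joins the major base (no secondary peak).

Noise is **multiplicative log-normal per channel** (sd σ), then columns are
renormalised. This was chosen over additive noise because what varies
between sequencing reactions is the *relative height* of peaks, not a
baseline offset; it also guarantees that truly absent bases stay absent,
which matches clean capillary traces. Modelling baseline noise (spurious
low-level peaks at all four channels) is deliberately out of scope; see
Limitations.

### Base calling

Two reads are derived from a trace, per column:

- **major**: the IUPAC union of channels with fraction strictly > 0.30 of
  the total (fallback: the tallest channel). The 30 % boundary reflects the
  practice of ignoring small secondary peaks when producing a low-noise
  sequence for phylogenetic use; it is configurable
  (`CallPolicy.major_threshold`), and the strict inequality at the boundary
  is a documented convention.
- **sensitive**: the union of channels with fraction ≥ 0.02. The 2 % floor
  is taken from the signal range at which a rare second ribotype remains
  readable by eye in good traces (2–5 %); there is no community-standard
  value, so it is exposed as `CallPolicy.sensitive_floor`.

The major states are a subset of the sensitive states at every column by
construction.

### Winner-take-all artifact

The chimera generator multiplies each channel by independent log-normal
jitter (sd σ) and emits the argmax base. Applied to a balanced mixture this
reproduces the failure mode of automatic base callers that "resolve" every
polymorphic position toward the locally taller peak: each diagnostic site
independently takes one parent's state, yielding a mosaic that belongs to
neither parent.

### Minor-component detection

Secondary signal is defined as channels with fraction in
[sensitive_floor, major_threshold]. Each candidate template is scored, for
each frame offset in [−2, +2], by the fraction of secondary-signal columns
whose band contains the offset-shifted candidate base; the best candidate is
the one with the highest single-offset score. The trace is then segmented
into constant-offset stretches by a forward scan with a 20-column sliding
window: a new segment opens when a different offset outscores the current
one over the window *and* the current column itself no longer matches the
current offset; the boundary is placed immediately after the last column
supporting the previous offset. Ties between offsets prefer the smaller
|offset|. With noiseless input and a difference site adjacent to the indel,
the reported boundary coincides with the indel position.

## Diagnostic sites and the verdict

Parental consensus per column defaults to **strict union** of the group
members' state sets; `majority` (most frequent symbol, ties unioned) and
`single_reference` (first listed accession) are available because published
re-analyses do not always state which accessions backed a consensus. Columns
are dropped when any parental member is gapped (indels are handled by the
indel-coding module, not as additivity characters) and, under the default
`omit_if_one_sided` rule, when exactly one parental set is ambiguous — the
convention that sites polymorphic in only one species are uninformative for
diagnosing hybrids. Two-sided polymorphic columns are kept only if the
unions are still disjoint.

With a = additive fraction and fA, fB = parent-specific fractions over
usable (non-missing) diagnostic sites, the default verdict table is:

| verdict | condition |
|---|---|
| PURE_A / PURE_B | fA (fB) ≥ 0.95 and a ≤ 0.05 |
| HYBRID_FULL | a = 1 |
| HYBRID | a ≥ 0.8 |
| CHIMERIC | a < 0.8 and min(fA, fB) ≥ 0.2 |
| PARTIALLY_RESOLVED | 0.1 ≤ a < 0.8 and max(fA, fB) ≥ 0.5 |
| AMBIGUOUS | otherwise |

The cutoffs are design choices, not fitted quantities; they were set so that
the three qualitative read types seen in practice map to distinct verdicts:
full additivity → HYBRID_FULL, a mosaic pulled toward both parents
(≈ 20 % additive, the rest split between the parents) → CHIMERIC, and a
mosaic pulled toward one dominant parent with residual polymorphism →
PARTIALLY_RESOLVED. All thresholds are exposed via `VerdictThresholds` and
comparisons use ≥/≤ exactly as written. The additivity index is reported to
3 decimals.

## Indel coding

Simple indel coding: one binary character per distinct internal
(start, end) gap range; a taxon scores 1 for the exact range, `?` when its
own longer gap properly contains the range, 0 otherwise. Terminal gap runs
are treated as missing data (`?` for every character they span) rather than
deletion events — standard practice where the underlying method is silent.

## RFLP screen design

Recognition sites are matched under IUPAC semantics on both strands with
overlapping matches counted; palindromic sites are reported once. Digestion
is linear-molecule only (PCR products). Cut coordinates use the enzyme's
top-strand `cut_offset`; where an offset is uncertain the fragment sizes are
convention-dependent, but site presence/absence — the quantity a
discriminating screen actually reads on a gel — is offset-independent. The
bundled enzyme table is a deliberately small, self-contained TSV (16 common
enzymes including PaeI/GCATGC with an SphI-type offset); users can supply
their own library.

Clone-screen sizing uses the geometric closed form
P(detect) = 1 − (1 − f)ⁿ, i.e. n = ⌈ln(1−p)/ln(1−f)⌉. This assumes clones
are independent draws with the minor ribotype at constant frequency f
(no PCR drift or cloning bias).

## Synthetic data: what it emulates, and what not

Parent A is i.i.d. uniform over A/C/G/T; parent B substitutes each site with
probability d (default 0.05 over 600 bp, giving ~30 diagnostic sites — the
regime in which published diagnostic counts of 28–39 sites over ~600-bp
spacers sit) and carries two 1-bp indels, a deletion at L/6 and an insertion
at 5L/6. Intra-individual polymorphism is injected at per-site rate ρ
(default 0.05) as the union of the resident base with one random other base
(bi-allelic double peaks). The generator does **not** model coalescent
structure, rate heterogeneity, PCR recombination, or sequence-quality decay
along the read; conclusions from passing tests are about the diagnostic
procedure, not about evolutionary realism.

The internal pairwise alignment used by the trace simulator and detector is
a global Needleman–Wunsch with gaps costlier than mismatches (match +1,
mismatch −1, gap −3), so substitutions are never explained away by spurious
indel pairs. When a substitution sits immediately adjacent to a true indel,
equally scoring gap placements exist and the realised alignment may shift
the indel by one column; the affected column then reads as parent-specific
rather than additive. This is an inherent ambiguity of mixed traces, is rare
(it requires a difference adjacent to an indel), and at worst moves a
verdict from HYBRID_FULL to HYBRID.

### Benchmark conditions

The verdict-recovery benchmark (tests and `scripts/acceptance.py`) runs 200
replicates per category at L = 600, d = 0.05: balanced hybrids at f = 0.5
with σ = 0.1, chimeras with jitter σ = 0.2, and pure parental reads with
ρ = 0. The pure category is generated without polymorphism injection on
purpose: the benchmark isolates the category signal (mixture vs artifact vs
pure), while the ρ > 0 regime is exercised separately in unit tests — a
heavily polymorphic pure accession can legitimately fail the strict
fA ≥ 0.95 cutoff and fall to AMBIGUOUS, which is the honest answer for such
a read. Minor-ribotype detection is benchmarked at f = 0.05 and f = 0.10
with σ = 0.1 over 100 seeded replicates. These problem sizes keep the whole
suite and the acceptance run in the tens of seconds while staying in the
regime the procedure is meant for.

## Numerical and degenerate-input conventions

- All column coordinates are 1-based inclusive in every interface.
- `U` is silently normalised to `T`; `?` is rejected in input FASTA
  (reserved for indel-coding output); parsing is case-insensitive and
  output uppercase.
- An all-gap parental column is MISSING; a query gap at a diagnostic site
  is counted MISSING and excluded from the index denominator; zero usable
  sites yields AMBIGUOUS with an explanatory note rather than an error.
- All-zero trace columns are rejected with the offending column named.
- Every stochastic operation takes an explicit seed; there is no global RNG
  state, and regeneration of a benchmark with the same scenario is
  byte-identical.

## Known limitations

- No parsing of real AB1/SCF chromatograms and no Phred-quality model; the
  TSV trace format is a stand-in abstraction.
- Detection assumes at most one minor component; three-way mixtures are not
  modelled.
- The verdict table is heuristic; with very few diagnostic sites (< ~10)
  single-site changes move fractions by > 10 % and verdicts become
  accordingly coarse.
- Circular molecules, methylation sensitivity and gel-migration modelling
  are out of scope for the RFLP module.
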