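# Methods

## Coordinates and conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
SAM (1-based POS) are converted on ingest, BED6 is used as-is, and tabular
output reports 1-based positions.  On the minus strand a read's 5′ end is
its highest genomic coordinate, and every window or interval defined
"upstream"/"into the gene" is mirrored about the gene's 5′ anchor.
Replicons are independent namespaces.  Reads are assumed uniquely aligned
upstream (ambiguous alignments discarded by the aligner); every aligned
record is counted, with no collapsing of identical sequences — identical
full-length reads are precisely the TSSaRNA signal.

## TSSaRNA detection

Per gene, the search window runs from 50 bp upstream of the translation
start to ⌊0.20 × CDS length⌋ bases inside the CDS (the 50 bp upstream part
is kept even for tiny CDSs, where the floor yields 0).  The TSS is the
window coordinate with the maximal read 5′-start count, accepted only when
that count is strictly greater than `min_tss_count` (20).  Reads starting
at the TSS are grouped into species by exact (5′, 3′) extent; among species
shorter than `max_read_len` (151 nt, the sequencing-cycle limit, exposed as
a parameter) the most abundant is the TSSaRNA full-length sequence,
retained when it has at least `min_tssarna_count` (10) copies.  The two
thresholds deliberately follow their wording: strict for the TSS total,
inclusive for the species count.

Open choices resolved here: ties in the TSS arg-max break to the coordinate
closest to the start codon, then to the more upstream one (TSSs cluster at
start codons in leaderless transcriptomes); ties between equally abundant
species break to the shorter (conservative TSSaRNA boundary).  One TSSaRNA
at most is called per gene.  Overlapping genes whose windows claim the same
TSS are not adjudicated: every claim is kept and flagged `multi-assigned`
in the audit table, which also records a per-gene rejection stage
(`no-window-signal`, `below-tss-threshold`, `no-short-species`,
`below-tssarna-threshold`).

## Primary classification

"95 % reads enrichment in TEX+ relative to TEX−" is implemented as the
depth-normalized TEX+ share: with *n± = count±/library size±*, enrichment
is *n₊/(n₊+n₋)*, primary iff ≥ 0.95.  This reading is symmetric, invariant
to rescaling either library, and reduces to "≥ 95 % of the signal is
TEX-resistant" at equal depths; normalization can be disabled.  0/0 is
defined as 0 — absence of evidence never creates a primary call, and no
pseudocounts are added.  Counting demands exact 5′-end equality with the
TSS; a fuzz window (± bp) is exposed and defaults to 0, since single-base
resolution is the point of the method.

## Differential expression

Inputs are processed probe intensities over a growth curve (13 time points
in the compendium this mirrors) plus a reference-condition intensity per
probe; no normalization or background correction is performed here.
Relative intensity is M = log₁₀(I_t/I_ref).  The representative probe
maximizes overlap with the TSSaRNA while covering no base beyond its 3′
end (ties: most 5′ probe).  The cognate reference is the per-time-point
median M over cognate-CDS probes whose 5′ start lies beyond the TSSaRNA 3′
end; the upstream reference is the median over probes in a 300-bp window
120 bp upstream of the TSS, replaced by the adjacent CDS's probes when an
annotated gene sits closer than 200 bp.

V(t) = M_probe − M_cognate is evaluated at the time point with the
second-largest |V| (`rank_select` = 2; |V| ties break to the earlier time
point), so a single-time-point spike can never qualify.  The upstream
statistic is evaluated at its own second-ranked time point by the same
rule.  A call is differentially expressed when |V| ≥ 1 (10-fold) and the
upstream |V| ≥ log₁₀2 (2-fold); the absolute value is used and the sign
reported as direction, since both up- and down-regulation occur.  Calls
with no admissible probe, no cognate probe or no upstream probe are
reported as unevaluable with the reason, never silently dropped.

## The pausing model

A gene of L bp is traversed at v bp per time unit (default 1).  A new
polymerase enters position 1 every Δτ units; pause position L′ᵢ holds a
polymerase for Δtᵢ units in total before it moves on; a polymerase whose
next base pair carries a stalled polymerase terminates immediately,
releasing a transcript of its current length; reaching L releases the
full-length transcript.  Within a time step polymerases update from the
most 3′ to the most 5′ (so a pause vacated in a step can be entered in the
same step, and no polymerase passes through another), then initiation is
attempted; an initiation onto an occupied first base is counted as blocked
and produces no transcript.  The census satisfies, exactly and by
construction: initiations = full-length + truncated + blocked + in-progress.

Because a blocked polymerase terminates instead of queueing, arrivals at a
pause occur on the grid set by the upstream cycle c (initially Δτ), and the
pause multiplies the cycle by ⌈Δt/c⌉.  The exact steady state is therefore

- full-length rate = 1/C with C = Δτ·∏ᵢ⌈Δtᵢ/cᵢ₋₁⌉ (cycle propagated
  through the pauses in order),
- truncated rate at length L′ᵢ−1 = 1/cᵢ₋₁ − 1/cᵢ,

which reduces to the continuum forms 1/max(Δτ, Δt) and
1/Δτ − 1/max(Δτ, Δt) whenever Δt ≤ Δτ or Δt is a multiple of Δτ, and
deviates from them by at most (Δτ−1)/Δt otherwise.  Both forms are
validated in the test suite against an independent brute-force event-log
simulator; the continuum-form comparison samples the commensurate family
where it is exact, while arbitrary configurations are checked against the
quantized form.  A consequence worth noting: with one global stall time the
first pause throttles flux so that downstream pauses never block, and only
one truncated band appears.  Multi-band patterns (e.g. 26/62/90/106 nt from
pauses at 27/63/91/107) require retention times increasing along the gene,
which is how multi-pause scenarios are parameterized here.

Rate estimates exclude a burn-in (default 10 × the slowest interval;
steady-state helpers add 2L so the pipeline is full) and count release
events in the remaining window.  In parameter scans the TSSaRNA level is
the truncated-transcript production rate and the cognate level the
full-length rate; a coverage-style alternative (per-base signal over the
first TSSaRNA-length bases, which tracks the initiation rate 1/Δτ instead)
is exposed via `level_mode="coverage"`.  Growth-curve rhythm simulation
runs one steady-state simulation per time point from a per-point
(Δτ, pauses) schedule and reports log₂(I_t/I_ref) profiles in the shape
the differential-expression module consumes.  Transcript degradation and
turnover between time points are not modelled; production rates are the
level proxy.  The stepper is JIT-compiled with numba when available; the
pure-Python fallback is the same exact kernel.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
sequencing physics (no base qualities, errors or FASTQ output).

- **Genome**: non-overlapping CDSs of 300–1500 bp on both strands with
  ≥ 600 bp intergenic gaps, leaving room for upstream control regions.
- **Reads**: per planted TSSaRNA, `tssarna_count` identical reads of the
  planted length plus `cognate_read_count` reads with lengths uniform on
  (tssarna_length, 151], all sharing the 5′ start; lengths are redrawn if a
  cognate species would rival the planted one, so the truth table is
  recoverable by construction.  Planted lengths default to a triangular
  distribution on [16, 146] with mode 27, echoing observed archaeal
  TSSaRNA sizes; TSS offsets sit within ±10 bp of the start codon
  (leaderless).  Background noise reads are uniform in position, length
  and strand at a per-kb rate — a conservative null for false positives.
- **TEX pair**: primary plants keep their TEX+ count and are depleted
  100-fold in TEX−; processed plants appear equally in both.  Each library
  also receives a uniform processed-RNA background (default 2000 reads)
  away from planted TSSs: real TEX− libraries retain abundant processed
  RNA, and without it depth normalization of a mostly-primary truth set
  would cancel the depletion.
- **Probes**: tiling probes (default 20 bp every 12 bp, both strands).
  Probes wholly inside a planted TSSaRNA follow its profile — flat for
  co-varying plants, `de_fold` (default 16, within the observed dynamic
  range) up or down at 3 seeded time points for DE plants — while cognate
  and upstream probes stay flat; multiplicative log-normal noise
  (σ = 0.05 on log₁₀) is applied everywhere.  Generation fails loudly if a
  DE plant admits no wholly-contained probe.

All generators are deterministic per seed.  Passing recovery tests on this
data shows the procedures implement their rules exactly; it does not show
robustness to features real data add (overdispersed backgrounds, correlated
probe noise, partial TEX digestion, overlapping transcription units).

## Problem sizes and numerical choices

The test and acceptance workloads are sized for interactive runs: 20-gene
50-kb fixtures, ~8 000 probes, simulator runs of 10⁴–10⁶ time steps
(≥ 1000 full-length releases for headline fold estimates, 500 slow cycles
for closed-form comparisons, at 1–2 % tolerance).  Degenerate inputs are
defined rather than special-cased: empty annotation or read sets yield
empty outputs; zero-signal enrichment is 0; fewer time points than
`rank_select` is an error; a pause with Δt ≤ 1 is a normal base.
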