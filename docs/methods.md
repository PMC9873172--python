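# Methods

## The genotyping problem

Shotgun ancient genomes are usually sequenced below 1× coverage from
fragments of 34–139 bp (mean ~69 bp, median ~66 bp after adapter removal
and merging). Read-depth CNV *discovery* needs far more signal than that,
but *genotyping* — asking whether a known candidate deletion or
duplication is present in a particular sample — only requires comparing
one interval's read count against its expectation. `conga` implements that
comparison as a three-state Poisson likelihood test.

## Read-depth likelihood and the C-score

For a candidate with breakpoints (B_l, B_r), the observed statistic O is
the number of reads aligned fully within [B_l, B_r) after quality
filtering (mapped, primary, non-duplicate, MAPQ ≥ 30 by default).
Containment rather than overlap counting makes the window statistic used
for normalisation and the interval statistic the same estimator.

The expectation under no event, E0, is `rate(chrom, GC) * (L - m + 1)`
where `m` is the mean read length estimated from the BAM and `L - m + 1`
is the number of start positions from which an average read is fully
contained. State expectations are E1 = E0/2 and E2 → 0 for deletions
(a homozygous deletion should contain no reads), E1 = 1.5·E0 and
E2 = 2·E0 for duplications. Copy numbers above 2 are not modelled: a
multicopy locus will simply look homozygous-duplicated.

Counts are treated as Poisson. With log-likelihoods ll_k = log P(O | E_k),
the C-score is `max(ll_1, ll_2) / ll_0`, in [0, ∞), lower meaning stronger
variant evidence; the ratio is invariant to the logarithm base. Decision
rules (all configurable, defaults shown):

| rule | default |
|---|---|
| call deletion / duplication (depth) | C < 0.5, zygosity by argmax(ll_1, ll_2) |
| reference genotype 0/0 | C > 2 |
| indeterminate band | C in [0.5, 2] → NA |
| duplication split-read rescue | C < 10 and read-pair support > 10 |

For duplications the rescue clause keeps a locus undecided up to C = 10,
so 0/0 is only emitted beyond that bound; the (2, 10) band without rescue
is NA. On an exact ll_1 = ll_2 tie the call is heterozygous (the smaller
copy-number change).

### Numerical choices

* Every expected depth is clamped to `epsilon_floor = 0.01` reads so the
  degenerate homozygous-deletion expectation keeps a finite likelihood;
  with O = 0 this yields ll_2 ≈ −0.01 and a near-zero C-score.
* Log-likelihoods are clamped to ≤ −1e−9 before forming the ratio, so the
  C-score is always finite and non-negative.
* log P is computed as `O·ln E − E − lgamma(O+1)`, stable beyond 10^6
  counts.
* The C-score is *not* exactly monotone in O: for deletion expectations
  E0 = 10 the minimum sits at O = 3, with c(3)=0.4020 < c(2)=0.4064 <
  c(1)=0.4405, because the diploid denominator also shrinks as O drops.
  The called region {O : C < cutoff} is nevertheless downward-closed at
  the cutoffs in use (0.3, 0.5, 1, 2), which is what calling relies on.

## GC normalisation

Per chromosome, windows of 1000 bp (tiling by default; `--gc-step 1`
gives maximally overlapping windows at ~1000× the cost for <5% change in
bin means) are binned by integer GC percentile — G+C over A+C+G+T,
N bases excluded, `floor(100·gc + 0.5)`. Per-percentile mean contained
counts are divided by the window's effective length to give per-bp rates,
then LOESS-smoothed (span 0.3) across percentiles. Unpopulated percentiles
fall back to the nearest populated bin; chromosomes without qualifying
reads fall back to the genome-wide rate; an interval that is entirely N
uses the genome rate. The profile is exactly reproducible from identical
inputs and serialises to a three-column TSV.

## Candidate filters

Applied in a fixed order before any likelihood is computed, each input
candidate keeping a record of why it was dropped:

1. **Minimum size** (default 1 kb) — smaller events carry too little
   depth signal at these coverages.
2. **Mappability** (default mean ≥ 0.9 over the interval, uncovered bases
   scored 0) — low-mappability loci mimic deletions whenever upstream
   BAMs were MAPQ-filtered. Any 4-column BED with values in [0, 1] works.
3. **Overlap removal** — of two same-type candidates overlapping by more
   than 50% of the smaller one's length, the smaller is dropped (on a
   length tie, the later in sort order), re-scanned to a fixed point.
   This prevents one physical event from being called multiple times
   through nested or shifted input entries. Note this predicate
   (>50% of the smaller) is deliberately distinct from the evaluation
   matching predicate (≥50% reciprocal).

## Split-read support for tandem duplications

Single-end ancient libraries carry no insert-size signal, so paired-end
evidence is emulated: every qualifying read overlapping a breakpoint
±100 bp (and not overlapping an optional satellite mask) is split at its
midpoint; the half covered by the existing alignment keeps its mapping
(anchor), the other half is remapped within ±10 median read lengths of
the breakpoints using exact 13-mer seeds and ungapped ±1/−2 extension.
A placement is accepted as a clean full-length hit (score ≥ 0.9 × segment
length) or as a local matched run scoring ≥ 17 — the latter is essential
because a midpoint-split half of a junction-spanning read is typically a
chimera of the two breakpoint sides, and only the run on one side should
be placed. Anchor and segment then count as support when, in read order,
the first element ends within 1 kb of B_r, the second starts within 1 kb
of B_l, and the everted span between them covers at least half the event
(which excludes the collinear placements produced by ordinary reads).
Each read is counted once, and once only across candidates.

**Regime limitation, quantified.** The only reads that can produce the
everted signature are those spanning the novel junction, so support is
bounded by junction depth ≈ coverage: about 5 reads at 5×, of which
roughly half survive the midpoint split with a placeable run. Support
values of true homozygous tandem duplications at 5× are therefore small
single digits — clearly separated from null intervals (which stay at 0)
but far below the rescue threshold of 10. The rescue clause consequently
matters only for deep data or much longer reads; at desk scale,
duplication calls come from read depth. Deletion results are entirely
independent of this channel (split evidence is not used for deletions).

## The simulator

The generator produces the study conditions the accuracy claims are made
under, directly as aligned records:

* **Reference** — random sequence with isochore-like GC structure: 5 kb
  blocks with GC ~ N(0.41, 0.08) clipped to [0.20, 0.70].
* **Events** — deletions and tandem duplications in three size classes
  (small 100 bp–1 kb, medium 1–10 kb, large 10–100 kb), sizes log-uniform
  within class, non-overlapping with ≥1 kb gaps, half heterozygous by
  default (het events land on one random haplotype).
* **Reads** — `coverage × genome / 69` single-end fragments, lengths from
  a discretised lognormal truncated to [34, 139] and moment-matched to
  mean 69.0 / median 66 (µ = ln 66, σ = 0.302438); terminal deamination
  C→T (5′) and G→A (3′) at rate 0.2 decaying as exp(−0.3·position), which
  with equal end rates is strand-symmetric in reference orientation;
  uniform 0.1% sequencing error. Reads are emitted as coordinate-sorted
  BAM records placed by projecting donor coordinates back to the
  reference; fragments crossing a novel junction are soft-clipped at it,
  as a short-read mapper would output. A FASTQ path exists for users who
  prefer to run a real aligner.
* **Candidates** — truth events plus ~10× background events of matched
  type and size class, placed so no candidate overlaps another by more
  than 50% of the smaller. At high density (10:1 matched-size background
  on a 10 Mb genome) this constraint jams slightly below the requested
  count; the achieved ratio (~9.5:1) is logged, and placement errors out
  below half the request.

What the simulator deliberately does **not** emulate: mapping error and
mapping bias (reads are placed at their true origin, so MAPQ filtering
and the mappability filter are exercised structurally, not
stochastically), adapter contamination, reference bias from damage
(damage is present in the bases but placement ignores it), satellite and
segmental-duplication repeat structure, and inter-library variability.
Passing benchmarks here therefore demonstrate the statistical engine
under its own assumptions — real-genome performance additionally depends
on alignment artefacts the simulation bypasses.

## Evaluation

A call (0/1 or 1/1 only; 0/0 and NA are non-calls) matches a truth event
when both are the same type and min(overlap/|call|, overlap/|truth|) ≥ 0.5,
computed exactly on integer coordinates. Matching is greedy one-to-one,
best overlap first (ties to the leftmost truth event), so nested truth
events cannot both be credited to one call. Reported per type and size
class (by truth length): recall (TPR), precision, FDR = 1 − precision,
F = 2PR/(P+R), with precision = 0 when nothing is called, plus a HET/HOM
confusion matrix over matched pairs. The zygosity F-score is strict: a
prediction counts as true only if it matches *and* assigns the right
zygosity.

## Benchmark scale

The shipped benchmarks run on a 10 Mb single-chromosome genome with 60
medium + 40 large deletions (≈19% of the genome in events — far denser
than real genomes, which makes GC normalisation slightly conservative
because event regions depress the profile) and a ~10:1 candidate mix,
i.e. ~145k reads at 1×. One full simulate→genotype→evaluate pass takes
well under a minute on one CPU; the three-target acceptance run about
20 s.

## Known limitations

* Poisson dispersion: real libraries are over-dispersed; a
  negative-binomial extension would temper C-scores at high coverage.
* Copy number saturates at 2; multicopy duplications are reported as 1/1.
* Whether the original depth statistic counts reads by containment or by
  overlap is unspecified in its description; containment was chosen for
  estimator consistency and is validated only against this simulator.
* The split-read orientation rules are the standard tandem-duplication
  signature; they are an interpretation, and their yield is intrinsically
  limited by junction depth with short single-end fragments (see above).
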