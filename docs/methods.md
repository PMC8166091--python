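# Methods

## The question and the procedure

The pipeline quantifies whether genes that respond transcriptionally to a
condition (e.g. spheroid culture enriching cancer stem cells, or treatment
with an oligomer that targets poly-A tracts) differ from non-responding
genes in the amount of perfect mononucleotide A/T repeat sequence around
their transcription start sites (TSSs). It couples four operations:
homopolymer scanning, TSS-anchored bin profiling, per-gene differential
expression calls with cross-experiment intersection, and a group-level
density comparison. Nothing in the chain is fitted; every step is a
deterministic transformation or a classical two-sample test, so the
package's guarantees are correctness and calibration rather than
goodness-of-fit.

## Repeat model

A *run* is a maximal, mismatch-free stretch of a single base: the flanking
bases (where they exist) differ from the run base, so a 15-mer inside a
30-mer is never counted separately. `N` terminates runs and never belongs
to one — an ambiguous base cannot create repeat sequence. Runs touching a
chromosome end are maximal by construction and count. The scorable length
window is 13–27 bp inclusive at both ends; runs longer than 27 bp are
**excluded entirely, not clipped**, because downstream sums add whole run
lengths and clipping would corrupt that bookkeeping. Both bounds are
configurable (`--min-len/--max-len`), as is the base set.

Runs are detected on the reference strand. Scanning uses numpy boundary
detection for the exhaustive all-lengths case and a seed-and-extend search
(`str.find` on a 13-mer seed, then extension to maximality) for
genome-scale scans, where qualifying runs occur at a rate of roughly
(1/4)^13 per bp and materialising every length-1 run would dominate the
cost. The test suite checks both routes against an independent greedy
regular-expression oracle.

## Window geometry and proportional assignment

Each gene's window is defined purely by distance from its TSS: 10,000 bp
upstream and 10,000 bp downstream, cut into 200 bins of 100 bp, numbered
in transcription direction with bin 1 farthest upstream; bins 1–100 are
exactly the upstream half. Coordinates are 0-based, half-open everywhere
(BED-native). For a minus-strand gene the window is the mirror image —
reference span [tss − 10,000 + 1, tss + 10,000 + 1) with bins numbered
right to left — so "upstream" is always 5′ of the TSS on the gene's
strand. The window deliberately ignores the gene's length: a short gene
still gets a 10-kb "intragenic" half, since the binning is a distance
profile, not a gene-body average.

A run contributes to each bin exactly the number of its base pairs whose
genomic positions fall in that bin (positionwise counting, equivalent to
length-proportional splitting for contiguous runs; integer by
construction). Base pairs outside the window are dropped. Assignment is
applied to length-filtered runs, so the per-bin sums are sums of intact
13–27 bp run lengths.

Windows truncated by a chromosome end keep reduced per-bin coverage
(`covered_bp`); genes whose window loses more than half its span are
dropped from profiling with a warning (threshold configurable). Densities
are always 10⁶ × repeat bp / covered bp ("bp/Mbp"), per gene over the
whole window, or pooled per bin over a gene group. Both the pooled per-bin
curve and the mean of per-gene densities are reported, since they answer
slightly different questions (bp-weighted vs gene-weighted).

**Strand and base orientation.** Whether an "A repeat" means the reference
strand or the gene's sense strand is genuinely ambiguous; since upstream
is transcription-directional here, the default (`strand_mode=sense`)
reports bases as read on the gene's strand — a reference T run is an A run
of a minus-strand gene — and `strand_mode=reference` preserves the literal
reading. The two modes differ only in the A/T labelling of minus-strand
genes.

## Expression calls and intersection

Per gene and experiment: a two-sided pooled-variance (Student's) t-test of
test vs control replicates. Calls are Up (p ≤ α and test mean higher), Dn
(p ≤ α and lower), else Nu; α = 0.05, comparisons inclusive. The three
calls always partition the gene universe. With the emulated design of two
replicates per group the test has 2 degrees of freedom — intentionally no
variance moderation and no multiple-testing correction, since the calls
are defined on raw per-gene P-values; df is surfaced per gene and
Benjamini–Hochberg values can be emitted for information. Zero
pooled variance is handled explicitly (equal means: t = 0, p = 1; unequal:
p = 0 with a logged degenerate flag).

Two experiments are combined by set intersection of same-direction calls
over their shared gene universe. Candidate lists are refined by requiring
p ≤ p_cut in *both* experiments (p_cut ≤ α). As an extension, a
hypergeometric tail probability quantifies whether the observed overlap
exceeds chance in the shared universe; it is reported, never used as a
filter.

Probe-to-gene collapsing and intensity normalisation are upstream burdens:
the input matrix is assumed gene-level and already on a log-intensity
scale, and the pipeline never transforms values.

## Density comparison between classes

The unit of observation is the gene; its statistic is the whole-window
density in bp/Mbp. Dn-vs-Nu and Up-vs-Nu are tested per base with the same
pooled-variance Student's t-test (Welch's variant behind a flag), and the
direction ("increased"/"reduced") follows the sign of the class-minus-Nu
mean difference. A per-bin variant of the same test exists for exploratory
profile plots; it applies no multiplicity correction and is flagged as
such. Classes with fewer than two profiled genes are skipped with a
warning.

Panel-level P-values obtained on real data depend on the genome assembly
and expression matrices supplied; this package verifies the *procedure* on
synthetic data with planted truth, and when run on real inputs it emits
the corresponding statistics in `density_comparisons.json` (one entry per
experiment × base × contrast).

## The synthetic-data generator

The generator emulates the study's inputs, not the human genome's
composition (no isochores, no real intensity distributions):

* **Genome**: i.i.d. uniform ACGT per chromosome. All background A/T runs
  ≥ 13 bp are destroyed during generation (a break every 12 bases of such
  a run), so the planted truth table is exhaustive; the generator re-scans
  its own output and refuses to emit a genome whose scan differs from the
  truth table. Planted runs receive C/G flanks, guaranteeing maximality
  without creating new A/T adjacency.
* **Genes**: one TSS per gene on a regular grid (spacing = window extent
  + 1,000 bp, small jitter), windows mutually disjoint so each planted run
  belongs to exactly one gene; strands Bernoulli(0.5).
* **Planted runs**: per gene, Poisson(rate) runs with lengths uniform on
  13–27 bp and uniform A/T base, placed uniformly (or bin-aligned, or
  boundary-straddling, to exercise the proportional-assignment path) with
  a 1-bp exclusion gap. The default rate is 5 runs per 20-kb window —
  a realistic order of magnitude for scorable poly-A/T tracts near
  promoters — and the Dn class's rate is multiplied by `enrichment_factor`.
* **Expression**: log2-scale baselines ~ N(8, 1), replicate noise
  SD 0.25, two replicates per group. Planted Dn/Up genes shift the test
  mean by ∓/± `effect_size` (default 1.0 = a two-fold change = 4 noise
  SDs). Experiment 2 keeps `shared_fraction` (default 0.8) of each planted
  set and replaces the rest with previously-null genes, giving the
  intersection a known expected membership.

Identical config + seed ⇒ byte-identical outputs; the committed demo
bundle under `tests/fixtures/demo` is regenerated and checksummed in the
test suite. What passing synthetic tests does *not* show: behaviour under
real base composition (GC skew, repeat families beyond homopolymers),
array-specific noise (probe effects, heavy tails), or biological
confounding between repeat density and expression class — the generator
plants clean effects by design.

## Calibration and recovery studies

`repeatdensity.validation` runs three replicated studies end to end
through the public pipeline surface (sizes chosen as reasonable desk-scale
defaults and stated here because they are part of the result):

* **Null calibration** — 200 replicates of 300 genes with shuffled class
  labels on homogeneous genomes (enrichment 1); the Dn-vs-Nu p-value falls
  below 0.05 in ≈ 5% of replicates. These replicates use 2-kb half-windows
  (40 bins): calibration of a t-test on per-gene densities does not depend
  on the window size, and the smaller geometry keeps 200 fresh genomes
  cheap.
* **Enrichment recovery** — 50 replicates of 300 Dn vs 1,500 Nu genes at
  enrichment factor 2 under the full 200-bin geometry; recovery means
  direction "increased" with p ≤ 10⁻³. The realized Dn/Nu mean-density
  ratio tracks the planted factor.
* **Classifier calibration** — 100 pure-null matrices of 400 genes (null
  Up+Dn call rate ≈ α) plus 30 replicates with 100 planted 4-SD effects
  (sensitivity ≈ 0.55–0.60 at df = 2 — the price of two replicates per
  group, reported rather than hidden).

`scripts/acceptance.py` re-runs all of the above from a single seed and
writes the resulting numbers as JSON.

## Numerical and degenerate-input choices

* All thresholds are inclusive (p ≤ α, p ≤ p_cut, 13 ≤ length ≤ 27).
* t-tests are computed by an explicit vectorised pooled-variance formula
  (validated against `scipy.stats.ttest_ind` to 12 significant digits in
  the tests) so degenerate variances are handled deterministically.
* Interval queries against the run index are two binary searches (runs of
  one base cannot overlap, so starts and ends are both sorted).
* A gene whose window has zero covered bp cannot have a density and must
  be dropped before density computation; the pipeline's truncation filter
  does this.
* Ties in direction (exactly equal means) are called "flat" and can never
  be Up/Dn regardless of p.

## Known limitations

* Only perfect single-base runs; no interrupted or composite repeats.
* One TSS per gene is required input; choosing among alternative
  transcripts is upstream of this package.
* Two replicates per group means df = 2 tests with modest sensitivity;
  the package reports this honestly rather than moderating variances.
* The per-bin comparison is exploratory (200 uncorrected tests).
* The generator's background suppression makes the truth table exhaustive
  but slightly depletes near-threshold (12-bp) runs relative to i.i.d.
  sequence; irrelevant to the statistics tested, but worth knowing when
  using it for other purposes.
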