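# Methods

## Fragment reconstruction

Paired-end alignments (text SAM via pysam, or BEDPE) become *mapped
fragments*: the half-open reference interval
`[min(pos1, pos2), max(end1, end2))` covering both mates and the
unsequenced region between them. A pair survives when

1. both mates map **uniquely** — operationalized as mapped, primary and
   mapping quality ≥ `mapq_threshold` (default 20; aligner-published
   uniqueness criteria vary, so the threshold is a parameter);
2. both mates lie on one chromosome, on opposite strands, pointing inward;
3. the fragment **span** is ≤ `max_span` (default 400 bp).

The span is measured outer-edge to outer-edge by default, matching a
~200 bp shearing target with generous tails; `span_metric="start_distance"`
measures between mate start positions instead, since either reading of a
"within 400 bp" pairing rule is defensible. Filtering is not an error:
per-filter rejection tallies (non-unique, cross-chromosome, improper
orientation, over-span) are logged and exposed through `FilterTally`, and
satisfy `kept + Σ rejected = input pairs` by construction.

Duplicates are fragments with identical `(chrom, start, end)`; they are
presumed PCR copies of one captured molecule and collapsed into a single
fragment whose multiplicity is the copy count (total multiplicity is
conserved). Mate orientation needs no part in the key — the pairing filter
already fixed it.

## Yield accounting

`yield_summary` reports sequenced, uniquely-mapped and non-duplicate
fragment counts with percentages rounded half-away-from-zero to one
decimal (`Decimal`-exact, so printed tables reproduce bit-for-bit). A zero
denominator yields a missing percentage rather than an error. The
interpretation rule: low unique yield with a *high* non-duplicate fraction
suggests sequencing inefficiency; low yield with a *low* non-duplicate
fraction indicts the capture itself, because a small pre-amplification pool
resequences as duplicates.

## The Fragment CpG-plot

CpGs are counted on the forward strand only — the dinucleotide is its own
reverse complement, so counting both strands would double every site — as
case-insensitive `CG` matches wholly inside `[start, end)`. A `CG` whose G
falls outside the interval is not counted; `N` never matches. Soft-masked
repeats carry real CpGs, hence case-insensitivity by default.

For `F_i` fragments with `i` CpGs the plot is `F_i / Σ_i F_i` versus `i`.
Default histograms use non-duplicate fragments (each distinct fragment
once); `dedup=False` weights by multiplicity. Since the fractions sum to
one, uniform replication of the fragment set changes nothing — the
diagnostic is yield-free. Display truncation of the x-axis is a plotting
option only; the table always carries the full histogram.

Fragment length confounds between-study comparison (longer fragments carry
more CpGs); the package documents this rather than correcting for it.

## Methylation tables and enrichment profiles

RRBS-like tables carry `(chrom, pos, strand, meth_count, total_count)`.
Under `strand_mode="merge"` the forward-C and reverse-G records of one CpG
are summed and keyed to the forward-strand C position; reverse records
without a partner are kept as singletons (logged). Degrees are
`meth_count / total_count`; zero-coverage records are dropped as
unobserved. Array-like tables carry betas in `[0, 1]`, are treated as
already strand-combined, and get an "unlimited" coverage sentinel so the
coverage filter (default ≥ 20, RRBS only — resolution of a degree needs
reads) passes them untouched.

Degrees are binned per 2 % (RRBS) or 5 % (array) into half-open bins with
a closed top; a degree exactly at an edge goes to the upper bin
(epsilon-robust floor — the deterministic tie-break). Each deduplicated
fragment contributes one incidence to every *distinct* bin among its
contained assessed CpGs (a CpG is contained when its C position lies in
`[start, end)`); per-bin fractions are incidences over total incidences.
`semantics="cpg"` counts every assessed CpG instead.

The background profile is the binned distribution of all assessed CpGs.
Dividing kit fractions by background fractions gives per-bin enrichment
ratios; zero-background bins are *missing*, not infinite. The **onset bin**
is the lowest bin from which the ratio is ≥ 1 in every higher occupied bin
(missing bins neither block the run nor hold the onset); it is `None` when
even the topmost occupied bin is depleted.

**Semantics caveat.** Under set semantics, bins whose CpGs cluster several
per fragment (CpG islands) are deflated relative to the per-CpG background
even under methylation-blind capture — a fragment with three same-bin CpGs
counts once against three background entries. The identity "uniform
capture ⇒ kit profile = background profile" is exact only CpG-oriented,
so calibration checks and onset comparisons use `semantics="cpg"`; set
semantics remains the default for kit profiles, where it bounds any single
fragment's influence by the number of bins.

## The capture simulator

The generator states a small world with the features the QC keys on:

* **Genome** (default 200 kb): first-order dinucleotide chain. Background
  is AT-rich with `P(G | C) = 0.04` (CpG depletion); islands — gamma
  lengths with mean 1000 bp and dispersion (CV) 0.5, covering ~10 % of the
  genome — are GC-rich with `P(G | C) = 0.25`. Island positions are
  reported for ground-truth stratification.
* **Methylation**: background CpGs draw from Beta(9, 1) (mean 0.9 — most
  non-island CpGs methylated). Each island is independently methylated
  with probability `pi_m = 0.3`; a methylated island draws an island-level
  mean from Beta(2, 1) (graded, intermediate-to-full), an unmethylated one
  from Beta(1, 9), and its CpGs scatter around that mean with
  concentration 20. The component is drawn **per island**, not per CpG:
  methylation is spatially coherent, and per-CpG draws would let
  high-component neighbours rescue the fragments of low-degree CpGs,
  inverting the depletion of unmethylated bins that real capture shows.
* **Capture**: molecules get uniform starts and truncated-normal lengths
  (mean 200 bp, sd 50, bounds [50, 400] — sonication to ~200 bp). Each
  molecule re-samples its methylated-CpG count `m` as Bernoulli(degree)
  per contained CpG (allelic/cellular heterogeneity), then is captured
  with `p(m) = ε + (1 − ε)(1 − (1 − q)^m)`: a nonspecific floor ε plus
  one independent binding chance per methylated CpG. The `(ε, q)` pair is
  a *kit archetype* — ε proxies (non)specificity, q sensitivity. No real
  kit's affinity curve is published; this two-parameter monotone form is a
  stand-in.
* **Sequencing**: `n_reads` draws with replacement from the captured pool
  (a single knob standing in for PCR amplification plus flow-cell
  sampling); mates are emitted as the first/last 45 bp of each fragment.
  Small pools resequenced deeply produce the high duplicate fractions that
  yield accounting flags.
* **Bisulfite observation**: per CpG, coverage ~ Poisson(mean, default
  30), methylated reads ~ Binomial(coverage, degree); zero-coverage CpGs
  are unobserved and omitted.

All draws flow from one seeded `numpy` generator per experiment, so a
(parameters, seed) pair reproduces every output bit-exactly.

**What a green test does not establish.** The simulator emulates CpG
density contrast, bimodal island methylation, fragment-scale capture and
sampling noise. It does not model sequence-specific shearing or mapping
bias, chromosome structure, copy-number variation, base-call errors,
non-CpG methylation, or salt-dependent elution chemistry; agreement on
synthetic data validates the statistical machinery, not any claim about a
specific commercial kit.

## Numerical choices

* Percentages: `Decimal` ratio, `ROUND_HALF_UP`, one decimal.
* Bin assignment: `floor(degree / width + 1e-9)`, clamped to the last bin;
  the epsilon routes values within float error of an edge upward.
* Bin count: `ceil(1/width)` (epsilon-guarded), so 2 % → 50 bins, 5 % →
  20 bins.
* Coordinates 0-based half-open throughout; SAM input converted from
  1-based by pysam, BED/BEDPE passed through.
* Histogram and profile fractions are exact integer-count ratios; the
  normalization checks use 1e-9 slack purely for float summation.

## Known limitations

* "Unique mapping" from BEDPE uses the score column as a MAPQ stand-in
  when present; BEDPE carries no per-mate quality.
* The onset bin is a max-type statistic over occupied bins and is noisy
  when sparse bins (few assessed CpGs) carry few fragment incidences;
  compare kits at matched depth on the same methylation table.
* Single-end or very short reads are out of scope: the diagnostic needs
  fragments that span their capture unit.
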