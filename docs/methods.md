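# Methods

## Reconstruction model

The package treats local-ancestry calls as given.  Each phased haplotype of
an admixed cohort arrives as an ordered sequence of genomic windows, each
with a posterior distribution over ancestry labels.  Reconstruction then has
four stages.

**Posterior filter and fragment merging.**  A window is kept iff its
target-ancestry posterior is strictly greater than `min_posterior`
(default 0.8).  Within one haplotype, each maximal run of kept windows that
are *adjacent in the window sequence* becomes one fragment spanning the
run's first start to its last end.  Two consequences are deliberate: a kept
window separated from the next kept window by a discarded window is never
merged with it, even if they touch in base pairs; and a merged fragment
includes any base pairs that fall between windows of the grid, since the
windows tile the chromosome and the run is one continuous stretch of
target-ancestry sequence.

**Greedy tiling.**  Per autosome, fragments are sorted by start position;
fragments sharing a start are ordered uniformly at random — the only
randomness in a tiling pass.  A left-to-right sweep places the first
fragment and then any fragment whose start strictly exceeds the end of the
last placed one.  Placed fragments are consumed; passes repeat on the
remaining pool (restarting from its lowest start) until the pool is empty,
so every fragment is placed on exactly one rearranged chromosome per
iteration.  Uncovered stretches are gaps and become missing genotypes.  A
chromosome is retained when coverage >= `coverage_threshold` (default
0.95).  Fragments of below-threshold chromosomes stay consumed within the
iteration: the procedure optimizes by selection *across* iterations, not by
re-tiling within one.

**Iteration selection.**  `n_iter` (default 100) independent iterations are
run; the winner maximizes the number of retained chromosomes, ties broken
by lowest iteration index so the result is deterministic.

**Diploid assembly.**  Across autosomes, min(retained) sets the
population's chromosome count N; floor(N/2) individuals are assembled by
pairing a seeded random shuffle of each autosome's retained chromosomes
(excess chromosomes are discarded).  If N < 2 the run ends with an explicit
"no reconstruction possible" outcome rather than an empty result.

Materialized genotypes copy each placed fragment's alleles from its source
haplotype site by site, preserving within-fragment phase exactly; gap sites
are missing.  Output VCFs use phased half-calls (`0|.`) plus a per-haplotype
gap BED, so downstream tools that reject half-calls can mask instead.  No
re-phasing is attempted: fragment-internal phase is already exact, and
between-fragment phase on a rearranged chromosome is not meaningful.

**Coverage denominator.**  "The chromosome" must have a length for coverage
to be a fraction.  By default the span runs from the first to the last
panel site of the autosome (array data define the observable span); any
span can be passed explicitly, as the simulation workflows do when the
simulated chromosome's full extent is known.

**Provenance diagnostic.**  Because one real individual's sequence can be
split across several reconstructed individuals, `source_overlap` reports,
for each pair of reconstructed individuals, the fraction of span base pairs
where both carry fragments from the same source sample (the diagonal applies
the measure between an individual's own two haplotypes).  High values warn
that kinship-sensitive downstream analyses (IBD, relatedness) may see
artifacts.

## Seeds

All randomness flows from one master seed through
`numpy.random.SeedSequence` with a spawn key derived from context labels
(stage name, iteration index, population), strings hashed by CRC32.  Equal
master seeds give bit-identical outputs end to end.

## Validation statistics

* **Per-site diversity** `pi = 2c(n - c)/(n(n - 1))` over observed alleles
  (missing excluded; sites with n < 2 skipped) — the per-site form used by
  `vcftools --site-pi`.
* **f-statistics** `f4(A,B;C,D) = mean (pA - pB)(pC - pD)` and
  `f3(T;A,B) = mean (pT - pA)(pT - pB)` over sites, with a weighted
  delete-one-block jackknife over genetic-map blocks (default 0.5 cM at the
  simulator's scale — roughly 200 blocks on a 1-Morgan chromosome;
  configurable for genome-scale data).  The residual-ancestry verdict is
  |Z| < 4 for f4(reconstructed, target source; distractor1, distractor2).
  Note that this f4 contrasts the two distractors: foreign ancestry entering
  *symmetrically* from both distractors largely cancels, so the built-in
  positive control injects one distractor's windows only.
* **Painting surrogate.**  Recipient haplotypes are cut into windows of
  `window_sites` sites (default 25; a trailing window shorter than half the
  width is folded into its neighbour) and each window is assigned to the
  donor population containing the minimum-mismatch haplotype over jointly
  observed sites, ties split equally.  Window lengths are measured between
  window start boundaries on the genetic map, so each recipient's donor
  totals sum to the painted map length.  This is not a Li–Stephens copying
  model; it is used only for rank/direction comparisons, which are robust to
  that simplification.
* **Differential-ancestry test.**  Per donor and unordered pair of recipient
  groups, a two-sided Wilcoxon rank-sum test (exact for small samples
  without ties, normal approximation otherwise) on donor totals; Bonferroni
  correction over all performed donor x pair tests (the family is the set of
  tests in one run — configurable, since other family definitions are
  defensible); significant iff corrected p < 0.005.  Groups with fewer than
  3 members are skipped with a warning.

## Simulator

Source panels follow the Balding–Nichols model: per site a base frequency
uniform on (0.05, 0.95); each source's frequency is
Beta(p(1-F)/F, (1-p)(1-F)/F) for its FST F to the base; haplotypes are
independent Bernoulli draws.  Admixed haplotypes follow the single-pulse
Markov tract approximation: switch points as a Poisson process of rate G
per Morgan (default G = 20 generations), ancestry redrawn independently
from the deme's admixture vector at the left end and after each switch, and
alleles copied from one uniformly chosen donor haplotype per tract.
Switches that redraw the same ancestry are invisible; expectations used in
calibration account for this via G·L·(1 − Σ alpha²).

Ground-truth tracts convert to window calls on a 0.2 cM grid: each window's
posterior mass sits on its majority-bp true ancestry, with an optional
symmetric noise rate epsilon and a mislabeling knob that relabels windows of
one chosen ancestry as target (the contamination positive control).

Default desk scale is one chromosome of 1 Morgan with 2,000 SNPs and
40-haplotype source panels; the clean-reconstruction study condition uses
200 admixed diploids with 30% target ancestry, and the differential
scenario uses two demes of 240 diploids drawing their target ancestry 80/20
vs 20/80 from two target sources (FST 0.10 and 0.15) — sized to yield about
50 reconstructed individuals per deme.  The symmetric-null replicates of the
differential check run at a reduced scale (80 diploids per deme, 600 sites,
5 tiling iterations) since a false-positive-rate check does not depend on
reconstruction fidelity.  Smaller sizes appear in unit tests where only a
property, not power, is at stake.

What the simulator does *not* emulate: demographic history within sources
(growth, bottlenecks, drift since admixture), linkage disequilibrium within
source panels (sites are independent given frequencies), genotyping error
and phasing switch errors, and local-ancestry miscalling beyond the epsilon
and mislabeling knobs.  Passing tests therefore demonstrate the correctness
and calibration of the algorithms, not the accuracy of any particular
local-ancestry tool on real data.

## Numerical choices

* Coordinates are 1-based inclusive everywhere except BED output (0-based
  half-open, per the format).
* The posterior threshold is a strict inequality: a posterior of exactly
  0.8 is discarded.
* Coverage is an exact ratio of integer base-pair counts.
* Posteriors must sum to 1 within 1e-6; window-call and fragment TSVs round
  floats through `%.17g`, so both round-trip exactly.
* Window majority ties (exact 50/50 bp split) resolve to the earlier
  ancestry label in the configuration's label order, for determinism.
* f4/f3 skip sites where any population has no observed allele; a zero
  jackknife SE with a zero estimate reports Z = 0.

## Known limitations

* Greedy tiling is not optimal interval scheduling; the iterate-and-select
  strategy is the method being implemented, and it is kept as such rather
  than replaced by an optimizer.
* Only one target ancestry per run; the X chromosome is out of scope.
* The painting surrogate's absolute chunk lengths are not comparable to
  Li–Stephens-based tools; only relative comparisons between recipient
  groups are supported.
* Reconstructed "individuals" are statistical composites: diversity and
  frequency estimates are meaningful, but kinship- and IBD-based analyses
  inherit the fragment-reuse artifact quantified by `source_overlap`.
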