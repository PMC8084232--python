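# Methods

## Problem and overall design

`sweepscan` detects candidate selective-sweep regions in multi-population
diploid SNP data. For one *target* population contrasted against the pool of
all remaining populations it computes, in 50-kb windows slid every 25 kb:

* **Nucleotide diversity (π)** per window for target and reference,
* a **diversity score** −log10(π_target + ε) so that high score = low diversity,
* **Weir–Cockerham F_ST** between target and pooled reference,

and flags as *candidates* the windows that fall simultaneously in the top 5%
of the F_ST distribution and the top 5% of the diversity-score distribution
(i.e. the low end of target diversity). Overlapping candidate windows are
merged into regions, genes overlapping the regions are extracted from a GFF3
annotation, and enrichment of gene-set terms is tested with a one-sided
hypergeometric test under Benjamini–Hochberg FDR ≤ 0.05.

## Estimators

**Per-site π.** For k ALT alleles among n called alleles,
π = 2k(n−k)/(n(n−1)) — the unbiased expected pairwise difference; 0 when
n < 2. **Per-window π** sums the per-site values and divides by the *full
window span* in bp (not the number of variant sites), so unobserved and
monomorphic positions contribute zero. This is the convention of VCFtools
`--window-pi` and matches what windowed in-house scan scripts typically
report.

**F_ST.** Weir & Cockerham (1984) variance components a (among
populations), b (between individuals within populations), c (within
individuals) computed per site from the two sample sets' sizes, allele
frequencies and observed heterozygosities; missing calls are excluded from
the counts and a site with zero called genotypes in either set is skipped.
Windows combine sites as the ratio of averages Σa/Σ(a+b+c). Negative window
estimates are retained (they populate the lower tail and never reach the
upper cut); a window with an empty or zero denominator has *undefined* F_ST
(NaN), never 0. Hudson's estimator is available (`popgen.hudson_fst`) for
sensitivity checks. Note that for a single site with identical finite
samples the W&C a component is generally nonzero (it subtracts a
finite-sample correction and is zero only in expectation); the test suite
pins the exact-zero balanced-heterozygote configuration and the many-site
average.

**Diversity score.** ε = 1e−8 by default. Any window with at least one
segregating site at these sample sizes has per-bp π ≥ ~1e-6, three orders of
magnitude above ε, so the guard only affects literally zero-π windows and
never reorders nonzero ones.

## Scan conventions and numerical choices

* Coordinates: VCF positions are 1-based internally; windows, BED output and
  gene intervals are 0-based half-open. A site at 1-based p belongs to
  [start, end) iff p−1 ∈ [start, end); with a 25-kb step every interior site
  falls in exactly two 50-kb windows.
* Window grid: starts at 0, step, 2·step, … with a window emitted iff its
  start lies inside the chromosome; the terminal window is truncated.
* Outlier cutoff: empirical (1−q) quantile with linear interpolation
  (NumPy's default, "type 7"). Windows **equal** to the cutoff are kept —
  a window that ties the threshold is never silently dropped.
* Windows with fewer than `min_sites_per_window` SNPs (default 3) or with
  undefined F_ST are excluded from *both* outlier distributions; otherwise
  empty windows would flood the low-π tail with π = 0 artifacts. Setting the
  threshold to 1 mimics a naive script.
* Candidate = F_ST outlier ∧ low-diversity outlier (intersection, not
  union). Overlapping or book-ended candidate windows merge into maximal
  regions.
* The low-diversity rule operates on the **target** population's π (sweeps
  deplete diversity in the selected population). π_ref and π_ref/π_target
  are computed and reported for inspection but do not enter the default
  rule.

## Variant filter

Cohort-wide (all samples at once), one pass before any contrast:
keep a site iff MAF > 0.05 **and** missing-call fraction < 0.25, both
strict, evaluated over the whole cohort. Half-calls (`0/.`) and non-diploid
genotypes are treated as missing with a warning; multi-allelic and non-SNP
records are dropped, not decomposed. Sites equal to either boundary are
removed. Missing genotypes are never imputed.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) for k selected genes carrying
a term, K universe genes carrying it, n selected genes, N universe genes;
BH step-up FDR across all tested terms; significant ⇔ FDR ≤ 0.05
(inclusive). The universe defaults to *every* gene in the supplied GFF3 —
not only genes with ≥1 term — because this choice changes N and therefore
every p-value; it is exposed as the `universe` argument. Gene–region
overlap requires ≥1 bp of the gene body (no promoter flank; strand
ignored). Term databases are deliberately not bundled: a term map is a
plain 4-column TSV (`gene_id  term_id  term_name  category`), usable with
real GO/KEGG exports or the simulator's synthetic terms. Per-category term
counting (`annotate.term_category_counts`) provides the bar-chart style
summary without any ontology graph.

## Synthetic data generator

The generator produces the study-shaped dataset every system test runs on:

* **Populations:** seven, of 7/7/7/5/7/7/7 diploids (47 samples), codes
  NJ, BJ, DJ, HX, QH, ALS, SNT.
* **Genome:** two 2-Mb chromosomes; 5,000 biallelic SNPs placed uniformly
  without replacement; ~1.25 SNP/kb, so a 50-kb window holds ~60 SNPs.
* **Differentiation:** Balding–Nichols — ancestral frequency p from a
  Beta(0.6, 0.6) rescaled to [0.02, 0.98] (an L-shaped spectrum with mass
  on both sides of the MAF-0.05 filter boundary), population frequencies
  from Beta(p(1−F)/F, (1−p)(1−F)/F) with background F = 0.05.
* **Sweeps:** ten 200-kb intervals (five per chromosome, targets assigned
  round-robin) with F raised to 0.4 for the target population and the
  target's expected heterozygosity calibrated to pi_scale = 0.1 × the
  background expectation for the same ancestral frequency (the frequency is
  pushed deterministically toward the nearer boundary). The calibration is
  relative to the *background* expectation, not to the sweep-F draw, so the
  realized in-sweep/background heterozygosity ratio equals pi_scale. A
  sweep spans 200 kb so that the windows fully inside the ten sweeps fill
  the top-5% outlier slots of a 160-window scan on their own; candidate
  regions then track the swept intervals rather than half-overlapping edge
  windows, keeping candidate-base precision high at this window size.
* **Missingness:** i.i.d. at rate 0.10 per genotype call (a per-locus
  dropout mode would be more RAD-faithful; see limitations).
* **Fixture bundle:** VCF 4.2, sample map TSV, chromosome-length TSV, GFF3
  with genes tiled every 40 kb (20 kb long), a term map containing one
  *planted* term (exactly the genes overlapping sweep intervals) plus 20
  random 15-gene decoy terms, and a ground-truth table with realized
  in-sweep F_ST and target π. All outputs are byte-identical for a given
  seed.

**What the generator does not emulate:** linkage disequilibrium (sites are
exchangeable within windows, which is sufficient because the scan
aggregates sites additively), RAD locus structure in missingness, mutation-
model detail, demography/kinship, and sweep dynamics (diversity depression
is imposed directly rather than arising from hitchhiking). Passing tests
therefore demonstrate that the statistics, ranking and intersection logic
behave correctly under controlled differentiation and diversity signals —
not that the pipeline's power on real RAD data matches the simulation.

## Problem sizes used in tests

System tests run the full pipeline (7 contrasts) on the 5,000-SNP fixture —
about half a second per run — over five fixed seeds, and the null-control
comparison over twenty seeds in memory. Estimator oracles use exhaustive
enumeration up to n = 8 alleles and 1,000 random sites against an
independently coded W&C implementation; calibration checks use 10⁴–10⁵
sites. These sizes give Monte-Carlo error comfortably inside each asserted
tolerance while keeping the whole suite around ten seconds.

## Known limitations

* The W&C estimator is implemented for the two-sample contrast (target vs
  pooled reference) only; the pooled reference is treated as one sample set,
  as in the mirrored study design, which inflates its within-"population"
  heterozygosity relative to a structured multi-population estimator.
* Empirical top-quantile outliers are not significance tests; no
  permutation p-values are provided by design.
* The per-target reference pool changes with the target, so per-target
  window tables are not directly comparable across targets at a fixed
  window.
* With whole-genome candidate input the enrichment reduces to k = K for
  every term (p = 1 unless n = N); enrichment is only meaningful when the
  selected set is a strict subset of the universe.
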