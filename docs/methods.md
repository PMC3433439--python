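# Methods

## The design being modelled

The package targets genetical genomics in outbred full-sib factorials:
a few highly heterozygous parents crossed in a 2×2 (expression) or 3×2
(phenotype) factorial, progeny genotyped at a consensus map of SNPs in
expressed genes, expression measured on two-color cDNA arrays, and field
traits scored over several seasons. Because the parents are outbred,
mapping is done **per parent**: at each informative marker the progeny
split by which of that parent's two alleles they inherited
(pseudo-testcross logic), and association is tested between this
transmission class and the trait.

## Single-marker LOD mapping

For one parent at one marker, let the transmission classes have means
m₁, m₂ and let RSS₁ be the pooled within-class residual sum of squares,
RSS₀ the sum of squares about the grand mean. Under a Gaussian model
with a common within-class variance, the profile log-likelihood ratio is

    LOD = (n/2) · log10(RSS0 / RSS1)

with allele effect (m₁−m₂)/2 and percent variance explained
100·(1−RSS₁/RSS₀). The Gaussian two-class form is the standard
single-marker choice; interval mapping and multi-QTL models are out of
scope by design (the single-marker model is what makes scanning tens of
thousands of transcripts practical).

Numerical choices:

* A perfect fit (RSS₁ = 0) is reported at a LOD cap of 300; a
  zero-variance trait gives LOD 0.
* Missing transmissions are dropped pairwise per marker; a marker is
  skipped for a parent when either class has fewer than two progeny.
* Crosses sharing a parent are pooled in that parent's scan after the
  trait is centered within cross, which removes the family main effect
  without modelling it.
* Significant records (default threshold 3.84) are thinned to the
  maximum-LOD marker per (trait, parent, linkage group, 10 cM bin), ties
  broken toward the smaller cM position, so adjacent markers linked to
  one QTL yield one record.
* The default threshold is applied on the log10-LOD scale exactly as
  printed. Note the numerical coincidence with the χ²₍₁₎ 5% critical
  value 3.84: a log10 LOD of 3.84 corresponds to a likelihood-ratio χ²
  of 2·ln10·3.84 ≈ 17.7 (pointwise p ≈ 2.6×10⁻⁵), so the scan is very
  conservative per test — appropriate when ~10⁴ transcripts × 252
  markers × parents are scanned. The threshold is a parameter
  everywhere; readers who take 3.84 as the χ² critical value can pass
  the equivalent log10 threshold 3.84/(2·ln 10) ≈ 0.83 instead.
* Ordinal attack/oviposition traits enter as numeric class codes; how
  the classes are coded is a generator config option, and mapping is
  invariant to affine recodings.

## Hotspots and hubs

With N_e eQTLs over m markers, the expected uniform count is e = N_e/m.
The package reports

* a χ² goodness-of-fit against uniformity, χ² = Σ(oᵢ−e)²/e, df = m−1;
* a randomization null: each of 1,000 replicates drops N_e eQTLs
  uniformly and independently over the m loci (one multinomial draw) and
  records the maximum per-locus count. Both the overall maximum across
  replicates and the 95th percentile of per-replicate maxima are
  reported, since "the largest chance cluster" can reasonably mean
  either;
* a hotspot cutoff round(1.5·e) — the expected average exceeded by 50% —
  with strictly-greater flagging;
* hubs: hotspot markers with ≥3 pQTL records in their 10 cM bin. Sign
  concordance between growth and resistance allele effects is assessed
  within each parent separately, because the labelling of a parent's two
  alleles is arbitrary and signs are only comparable within a parent.

## Collocation candidates

Markers are assigned to half-open bins [k·w, (k+1)·w) from each linkage
group's origin, w = 10 cM by default (the default synthetic map gives
about 2 markers per bin, 130 bins). For transcript g and trait t, the
observed statistic is the fraction f of g's eQTLs whose bin contains a
pQTL of t. The null places the same number of eQTLs independently and
uniformly over all map bins and recomputes f; because the placements are
iid over bins, the null hit count is drawn directly as a
Binomial(n_eqtls, k/B) variable (k = trait pQTL bins, B = total bins),
which is the same distribution as placing each eQTL and recounting.
With the finite-sampling correction p = (1+#{f* ≥ f})/(n_perm+1), so
p is never 0. Null draws are shared between transcripts with equal eQTL
counts for a trait; this changes nothing statistically and makes 10,000
permutations cheap. A candidate requires **both** f ≥ 0.4 and p ≤ 0.05,
reading the two published clauses as joint requirements.

Composite candidates for a trait group (growth: ldr_99, hgt_1995,
hgt_1997, hgt_1999; resistance: atk_2000, atk_2001, sum_atk, egg_2000,
egg_2001, sum_egg) are transcripts significant for *every* group member
at α = 0.1 per trait. Significance here is the permutation p-value
alone, matching the p ≤ 0.1 listings that define the published composite
candidate tables; the 40% clause remains part of the per-trait candidate
flag.

"QTL correlations" between traits are not operationally defined in the
source literature; here they are Pearson correlations between traits'
collocation profiles — the per-transcript vectors of collocation
fractions — computed over all transcripts with at least one eQTL. The
growth-vs-resistance aggregate correlates the per-transcript mean
profile of each group. This definition is one choice among several
(counts or binary collocation indicators would also be defensible) and
is isolated in `colloc.qtl_correlation_matrix` so it can be swapped.

## Distant-pair design

The genetic distance between two progeny is the proportion of shared
segregating loci (stacked over both parents' transmission matrices) at
which their transmitted-allele combinations differ; the original
distant-pair literature does not fix a metric and this mismatch
proportion is the simplest one consistent with "direct comparisons
between different alleles". Pairing within each cross is an exact
maximum-weight perfect matching (blossom algorithm via networkx) —
maximizing total distance is an optimization claim, and exact matching
is cheap at ≤60 progeny per cross. Odd crosses leave one progeny
unpaired with a warning. The improvement statistic compares the optimal
total distance with the mean of uniformly random within-cross perfect
matchings; on default simulated data it lands near 24%, of the same
order as the 25% reported for the real design, but it is data-dependent
and not asserted anywhere. Dye orientation is randomized subject to the
Cy3-first/Cy5-first counts differing by at most one within every block
and every batch (random restarts; an unbalanceable stratum raises an
error naming it).

## Preprocessing

Channels are calibrated to the first channel by median/MAD affine
matching and transformed with arsinh: h = asinh((x−a_c)/b_c). This is a
robust generalized-log variance stabilization: any affine-arsinh family
member satisfies the downstream contract (roughly constant variance
across intensity strata), and the robust calibration avoids the full
maximum-likelihood machinery of model-based VSN while keeping its
functional form. The technical model h_i = μ + dye + block + batch +
person + ε is then fit per gene by least squares with sum-to-zero
contrasts; aliased columns are dropped deterministically in sample-sheet
column order, and a multi-level factor losing all its contrasts (fully
confounded) is an error. All four effects are fitted per gene — the dye
effect is gene-specific in the modelled experiment, and fitting the
others per gene costs nothing and nests the global model. Residuals are
re-indexed from channels to individuals (each tree is profiled on
exactly one channel in this design) and become the expression traits.

## The synthetic generator

Defaults are the conditions of the emulated study: 13 linkage groups,
252 SNPs (five groups of 20, eight of 19) evenly spaced over 97 cM per
group (~1,260 cM, ~5 cM spacing, ~2 markers per 10 cM bin); a 2×2
factorial of four parents with 48/36/50/54 progeny (188 profiled, 94
arrays); expression scaled down from tens of thousands of spots to 300
transcripts; residual noise SD 1 with planted effects defaulting to 1
noise-SD.

* **Transmissions** follow a first-order Markov walk per linkage group
  with Haldane's map function r = (1−e^(−2d/100))/2 between adjacent
  markers — no crossover interference, the simplest model consistent
  with an unspecified mapping function. Parents segregate independently
  and are fully informative by default; a config switch masks a fraction
  of markers per parent as uninformative, mimicking the ~75% confirmable
  loci of real SNP panels.
* **Traits** are sums of (effect × signed transmission code ±1) plus
  Gaussian noise. Growth traits get cm-scale baselines (presentation
  only — mapping is affine-invariant). Attack is cut into three classes
  (no attack / failed attack / top kill) and oviposition into class 0
  plus five egg-count classes by liability cutpoints chosen to give
  non-degenerate class frequencies at the default architecture;
  `sum_atk`/`sum_egg` are sums of the yearly class codes, and all
  ordinal traits are analyzed downstream as numeric codes.
* **The default architecture** plants 30 cis eQTLs, 30 trans eQTLs, one
  hotspot regulator driving 60 transcripts in trans that is also
  pleiotropic for growth and resistance traits with same-sign effects (a
  hub by construction), a second pleiotropic locus, and one private QTL
  per remaining trait. For smaller `n_transcripts` the planted counts
  scale down proportionally, keeping ~40% of transcripts genetically
  driven.
* **Arrays**: channel intensity is exp(per-gene baseline + signal + dye
  + block + batch + person + noise) + additive background, with the
  technical effects drawn per gene and level. Making them additive on
  the log scale renders the preprocess linear model exactly correct,
  which isolates later stages for testing. The generator returns the
  planted technical effects alongside the intensity table and sample
  sheet so tests can verify recovery.

What the generator does **not** emulate: SNP ascertainment and
genotyping error, crossover interference, linkage-map estimation error
(the truth map is the input map), spot-level array artifacts (spatial
trends, background images, quality flags), distributional quirks of real
ordinal field scores, and selection/survival structure in the pedigree.
Passing tests therefore demonstrate that the statistics are implemented
correctly and behave as designed under a faithful idealization, not that
they are robust to those real-data complications.

## Problem sizes and reproducibility

The bundled test suite and the pipeline default to the scaled-down
transcriptome (hundreds of transcripts); the power, false-positive and
calibration checks use 50–500 Monte-Carlo replicates, and the
study-scale randomization (132,100 eQTLs × 252 loci × 1,000 replicates)
runs in seconds as vectorized multinomial draws. Every random stage
draws from a `numpy` Generator seeded from one pipeline seed through
`SeedSequence.spawn`, so a fixed seed reproduces every output file
byte for byte; reseeding changes the noise but leaves strongly planted
structure (the hotspot regulator, the hub) detected.

## Known limitations

* The LOD threshold convention (log10 LOD vs χ² critical value printed
  on a LOD axis) is genuinely ambiguous in the emulated study; the
  package defaults to the printed value on the log10 scale and exposes
  it everywhere.
* Collocation p-values are discrete (permutation-based) and shared-null
  caching assumes the uniform bin null; a marker-density-weighted null
  would need per-transcript draws.
* The per-gene technical model assumes each individual appears on
  exactly one channel; duplicate profiles are averaged rather than
  modelled with a random effect.
* `find_hubs` reports sign concordance but no significance for it; with
  ≤3 pQTLs per hub a sign test would be uninformative.
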