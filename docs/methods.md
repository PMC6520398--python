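# Methods

`modelfidelity` evaluates how faithfully in-vitro cancer models — cell
lines and patient-derived organoids — recapitulate a metastatic tumor
cohort, along three molecular axes: somatic mutation, gene-level copy
number, and the transcriptome. This note describes the statistical
procedures, the synthetic study the package generates to exercise them,
the numerical choices made where the design was genuinely open, and the
known limitations.

## The evaluation procedures

### Differential mutation (metastatic vs primary cohort)

For each gene on the commonly genotyped panel, let `n` be the number of
metastatic samples carrying a qualifying (non-silent coding) variant, `N`
the metastatic cohort size, and `q̂` the gene's mutation frequency in a
primary-tumor reference cohort. The right-tailed p-value is the binomial
upper tail

    p = 1 − Σ_{i=0}^{n} Pr(i; N, q̂),

i.e. `P(X > n)`, with the observed count *excluded* from the tail; the
left-tailed p-value is its complement `1 − p`. Genes with zero reference
frequency borrow the minimum *nonzero* frequency across the panel so the
binomial is always defined. Benjamini–Hochberg is applied to the
right-tailed and left-tailed families separately.

Two properties of this test matter in practice:

* **Discreteness.** Because the observed count is excluded from the tail,
  the test is *anti-conservative* at small cohort sizes: the realized
  type-I rate at level α is the tail probability just above α, which
  exceeds α by up to one probability-mass term. At `N = 60` and
  `q ∈ U(0.01, 0.08)` the measured rejection rate at α = 0.05 is ≈ 0.086.
  The excess shrinks like the pmf jump (∝ 1/√N); our calibration check
  therefore probes the regime `N = 20 000`, where the excess (~0.0015)
  falls below Monte-Carlo resolution. An `inclusive` flag switches to the
  conventional `P(X ≥ n)` (conservative) tail. Calibration is checked over
  200 simulated cohorts of 25 genes each — small cohorts keep the
  Monte-Carlo standard error of the pooled rate above the residual
  discreteness excess, so the check is informative rather than vacuous.
* **Reference-frequency noise.** The test treats `q̂` as known. When `q̂`
  is estimated from a reference cohort, estimation noise enters the tail
  exponentially and inflates the realized FDR of the BH calls; with a
  1000-sample reference the measured empirical FDR of calls at
  `q_right < 0.001` is ≈ 0.005 (vs ≈ 0.017 at 500 samples). A reference
  cohort of at least ~1000 samples is recommended, and is the synthetic
  default.

Candidate panels merge the highly mutated genes (metastatic frequency
strictly > 0.05) with the differentially mutated genes (right-tailed
FDR < 0.001), ordered by descending metastatic frequency. Cell-line
hypermutation calls flag culture artifacts: genes mutated in ≥ 50 % of
model samples yet rare (< 5 %) in the tumor cohort.

### Copy-number comparison

Segmented copy number (log-ratio scale) is mapped to genes by
overlap-length-weighted averaging of the overlapping segment values
(invariant to splitting segments; genes without overlap stay missing; an
alternative `max_abs` rule keeps the largest-magnitude overlapping
segment). Sample sets are summarised by per-gene median profiles (genes
missing in more than half the set are dropped). Profiles are compared by
Spearman correlation; profile genes are partitioned into loss
(median < 0), gain (the complement) and high gain (median ≥ 0.4), and
differences on a partition are tested with the two-sided Wilcoxon
rank-sum. Model-level CNV similarity is the median per-tumor Spearman
correlation over the whole common panel (no marker selection), with
pairwise-complete handling of missing genes.

### Transcriptome-correlation (TC) analysis

Marker genes are selected on the model reference panel: each reference
sample is rank-transformed (average ranks), the per-gene dispersion of
ranks across samples is computed, and the top `k = 1000` genes are kept.
The dispersion statistic is the standard deviation by default
(configurable: variance, MAD, IQR), with ties broken by gene symbol. A
model's similarity with a sample set is the *median* of its per-sample
Spearman correlations over the marker genes; even counts use the midpoint
and undefined correlations are dropped, not zero-filled. Because every
step is rank-based, the similarity is invariant to any per-sample monotone
transform of abundance (FPKM vs TPM vs log is immaterial).

Rankings sort by descending similarity with ties broken by model
identifier (duplicated models occupy adjacent positions). Stratified
analyses repeat the computation within metastatic-site or subtype strata
that hold at least 9 samples; cross-stratum agreement is the pairwise
Spearman correlation of per-model similarity vectors.

### Significance calling against a fitted null

Within a stratum, the similarity scores of a large off-lineage background
panel are approximately normal. The null is fitted by moment matching
(mean and n−1 standard deviation; a median/MAD option exists), each
candidate model receives a right-tailed p-value
`1 − Φ((s − μ)/σ)`, and BH runs over the candidate family within the
stratum only. Significance flags use `q ≤ 0.01` and `q ≤ 0.05`. With a
background of ≥ 300 models the fitted-null p-values of null-drawn
candidates are uniform to Kolmogorov–Smirnov distance < 0.05 (checked on
2000 pooled p-values); smaller backgrounds inflate the tails through
parameter-estimation error.

### Gene-set differential activity

Per-sample gene-set activity is the single-sample enrichment running-sum
integral: order genes by decreasing expression (average-rank magnitudes
for ties, walking order fixed by gene identifier), accumulate the
weighted in-set ECDF (weights = rank magnitude^α, α = 0.25 by default)
against the uniform out-of-set ECDF, and sum the differences over all
positions. An optional rescaling by the score range across samples mirrors
a variant some implementations apply; the default reports raw integrals.
Differential activity between the tumor cohort and each model class is a
per-set two-sided rank-sum test, BH-adjusted across the collection, called
at FDR < 0.001. The two class comparisons fold into four categories
(1 = organoid-only, 2 = cell-line-only, 3 = both, 4 = neither), and sets
with the same category in every stratum form the consensus classification.

Note that the activity score is *rank-compositional*: shifting one group
of genes displaces the ranks — and hence the scores — of gene sets that
contain none of the shifted genes. This is a genuine property of the
score, not an artifact; it is why the synthetic generator's control sets
are placed on displacement-neutral genes (below).

## The synthetic study

The generator emulates the statistical structure the analyses assume:

* **Cohorts.** 60 metastatic tumors (15 per subtype: LuminalA, LuminalB,
  Her2, Basal) with metastatic sites liver (27), lymph node (18) and bone
  (15); 1000 primary tumors (mutation data only, the `q̂` reference); 40
  breast and 200 non-breast cell lines; 26 organoids. 2000 genes, of which
  600 form the genotyped panel (with a handful of planted
  annotation-filter failures: no-HGNC, no-RefSeq, Y-chromosome).
* **Expression** is log2-scale Gaussian: per-gene baseline `N(6, 2²)` plus
  subtype, lineage, site and culture effects plus `N(0, 0.3²)` noise,
  exponentiated to abundance scale. Every downstream statistic is
  rank-based, so the abundance family is immaterial; the Gaussian
  log-model keeps generation fast and transparent. Subtype directions are
  drawn orthonormal with fixed norms (0.6, Basal 2.0) so every pair of
  subtypes sits at the same distance — no subtype is accidentally central
  in a given draw. The bone site effect leans onto the Basal axis (0.6×)
  plus its own direction, making bone the planted divergent stratum.
* **Culture effect.** A fixed ±1 direction on 700 genes (sign-balanced;
  500 of them on lineage-informative genes so the effect is visible to
  marker selection, none on subtype genes so the penalty is
  subtype-neutral), scaled per model: cell lines `N(1.0, 0.1²)`, organoids
  `N(0.5, 0.03²)` — organoids are closer to tumors by construction. One
  faithful line per subtype has its magnitude reduced (0.05 for LuminalA —
  the planted global best — and 0.3 for the others), and one unfaithful
  line per subtype keeps its subtype *label* but lacks the subtype
  expression program entirely (magnitude 2.5) — the mislabeled-subtype
  phenomenon observed in real panels.
* **Mutations** are per-gene Bernoulli draws: baseline frequencies
  `U(0.01, 0.08)`, 15 differential genes lifted to 0.45 in the metastatic
  cohort, 8 hypermutated genes at 0.9 in cell lines but 0.005 in both
  tumor cohorts. Non-qualifying (Silent) records are sprinkled on top to
  exercise the class filter. With a 60-sample metastatic cohort a planted
  hypermutated gene's observed frequency lands exactly on the 0.05
  boundary in ~3 % of seeds — exact recovery is a per-seed event with
  ≈ 97 % probability, not a certainty.
* **Copy number** is generated as segments per sample: a shared recurrent
  profile `N(0, 0.3²)` plus per-gene noise, averaged within random
  segmentations whose breakpoints always include the planted region
  boundaries. The gain region (30 genes) sits at +0.6 in tumors, +0.55 in
  metastatic-derived models and +0.25 in primary-derived models; the loss
  region (40 genes) at −0.3 in tumors but −0.8 in cell lines (the
  exaggerated-loss pattern). A per-model distortion scaled by the same
  culture magnitude ordering makes CNV similarity decrease with the
  culture effect.
* **Gene sets.** Culture sets are drawn from up-shifted culture genes away
  from the subtype/site programs; control sets from effect-free genes
  whose baseline rank is minimally displaced by the class shifts (see the
  compositionality note above).
* **Determinism.** One RNG stream per modality, all seeded from the master
  seed; identical (config, seed) produces byte-identical files.

### What passing the synthetic checks does and does not show

The generator reproduces the *relational* structure real cohorts exhibit
(subtype geometry, culture shifts, planted genomic lesions) but not their
marginal realism: no negative-binomial count noise, no gene–gene
correlation beyond the planted factors, no linkage between a gene's
mutation and its own expression, schematic genome coordinates, and
perfectly balanced subtype composition. Recovery of planted truth
demonstrates that the pipeline's statistics rank, test and call what they
claim to under known conditions — it does not certify performance on any
real cohort, where effect sizes, confounding and batch structure are
unknown.

## Numerical choices

* Average-rank ties everywhere (Spearman, rank-sum, marker ranks,
  enrichment magnitudes); tie-breaks on identifiers make every ordering
  deterministic.
* Wilcoxon rank-sum uses exact enumeration when the smaller group has < 8
  observations, otherwise the normal approximation with tie and continuity
  corrections (agrees with the exact tail to ≈ 0.01, worst case near
  p = 0.5).
* Binomial tails go through the scipy survival function (no naive
  factorials); BH is a vectorised step-up with running minimum, clipped at
  1.
* Missing CNV values are excluded pairwise from correlations and never
  imputed; genes missing in > 50 % of a sample set are dropped from its
  median profile.
* Median of an even number of values is the midpoint of the central pair.
* Degenerate inputs raise typed errors (`DomainError`,
  `DegenerateDataError`, `FormatError`) rather than returning NaN;
  aggregating callers catch-and-count undefined per-sample correlations.

## Problem sizes used by the test suite and acceptance script

Planted-truth recovery runs the full pipeline on 100 generator seeds at
the default configuration above (the acceptance script uses 50 seeds
derived from its `--seed`); calibration uses 200 cohorts × 25 genes at
N = 20 000 for the binomial type-I rate and 20 strata × (300 background +
100 candidates) for the fitted-null uniformity check; oracle equivalence
covers every (n, N ≤ 50) pair at five reference frequencies, 1000 random
p-vectors, and 200 random enrichment instances. These sizes make each
Monte-Carlo bound meaningful at the tolerances tested while keeping a full
run in the minutes range.

## Limitations

* The evaluation is correlational: a model can rank first yet still lack a
  specific lesion of interest, which is why the mutation and CNV reports
  are emitted alongside the rankings rather than folded into one score.
* The fitted-null procedure assumes the background class is a fair null
  for the candidate class on the same stratum; backgrounds that share the
  candidates' lineage shrink p-values toward 1 and hide real signal.
* The exclusive-tail binomial p-value is liberal at small cohort sizes
  (see above); interpret per-gene calls at small N accordingly or use the
  inclusive tail.
* DE-table intersection is plumbing over externally produced tables; the
  package does not compute differential expression itself.
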