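# Methods

This note documents the statistical models, default parameters and design
decisions of circscape. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Catalog rules

A circRNA id is the normID `chrom__start__end` with 1-based inclusive
coordinates on both ends; the parse/format codec is a bijection and rejects
`start > end`. All internal coordinates stay 1-based; only the BED exporter
converts to 0-based half-open.

* **Consensus**: exact intersection of the id sets of all detection tools
  (at least two required). Order- and duplicate-invariant.
* **Prevalence filter**: keep circRNA *i* when
  |{s : c_is > min_reads}| ≥ max(1, ⌊frac·n⌋), defaults min_reads = 4,
  frac = 0.01. Both the read rule and the literal "more than" reading are
  strict: a count of exactly 4 does not qualify. The floor-with-clamp form of
  the patient threshold is the only reading under which a 1% rule yields 3
  patients in a 315-patient cohort.
* **True negatives**: in the poly-A cohort, circRNA *i* is an artifact when
  |{s : c_is > 4}|/n > 0.25, again both inequalities strict. The filtered
  catalog is the set difference.
* **FPM**: c_is / L_s × 10⁶ with L_s the sample's total sequenced fragments
  from the sample metadata — read-depth normalization, deliberately *not* the
  circRNA column sum, which would be dominated by a handful of loci.
* **Locus class**: exonic when both BSJ ends fall in exons of one common gene;
  intronic when both ends fall in one gene body but not exons of a common
  gene; intergenic otherwise. Strand is ignored. Ties across overlapping genes
  break by smallest gene span, then lexicographic id. Reported circRNA length
  is the genomic span end − start + 1; spliced length is not computed.

## Differential expression engine

A deliberately simple, fully documented NB Wald workflow (no shrinkage, no
outlier refitting); its operating characteristics are established by
simulation, not by matching any external engine bit for bit.

* Size factors: median-of-ratios over features with all-positive counts;
  optional pseudo-reference fallback (+0.5) when none exists.
* Dispersion: method-of-moments α̂ = max(10⁻⁸, (s² − m̄)/m̄²) on normalized
  counts, NB parameterization Var = μ + αμ².
* Test: per-feature NB log-link GLM with intercept + condition. Because the
  design is saturated, the fit factorizes into two one-dimensional score
  equations Σ(y − μ)/(1 + αμ) = 0 per group, solved by vectorized Newton
  steps; the Wald statistic uses the Fisher information Σ μ/(1 + αμ) per
  group. Features with all counts zero in one group and fewer than 4 total
  reads are reported untestable (missing p). Swapping labels negates every
  log₂FC exactly.
* Volcano categories and the ranked-recall curve: ranking is ascending p,
  ties by descending |log₂FC|, then id. recall@k divides by the *full*
  reference size even when reference ids are absent from the universe; the
  expected curve and the upper-tail hypergeometric p account for the
  restriction through |reference ∩ universe|. The analytic hypergeometric
  null (rather than permutation) is an implementation choice, verified by
  exhaustive enumeration in the tests.

Null calibration at 2,000 features (50 vs 50 samples) keeps the fraction of
p < 0.05 inside [0.03, 0.07]; sensitivity for planted |log₂FC| = 2 at 150
samples per group exceeds 0.9 at FDR < 0.05 (both recomputed by
`scripts/acceptance.py`).

## Two-statistic subgroup discovery

Expression enters as log₂(FPM + 1). For target group g:

* T1 = Welch t of g versus all remaining samples with per-group variances
  floored at 10⁻⁶ (the "robust" element — it prevents 0/0 on constant
  features and caps the influence of near-degenerate variances); one-sided
  (up-regulation) p with Welch–Satterthwaite df. The published form of the
  robust t in the method's antecedents is not fully specified; Welch with a
  variance floor is this package's definition, stated here prominently.
* T2 = Σⱼ nⱼ(x̄ⱼ − x̄_w)²/s²_pool over the remaining groups (pooled weighted
  mean, pooled within-group variance, floored), referred to chi-square with
  (#remaining − 1) df. For two equal-size remaining groups it equals the
  squared pooled-variance z statistic.
* Host-gene veto: two-sided Welch on log₂ of median-of-ratios-normalized gene
  counts (a CPM-like scale). Plain total-count CPM is *not* used: a handful
  of strongly shifted genes inflates the group's library sizes and makes
  every null host gene look down-regulated (composition bias); the robust
  size factors remove this. Intergenic circRNAs have no host gene and pass
  the veto vacuously.
* Verdict: T1 FDR < 0.01 (BH within each group's screen, i.e. one screen per
  group) ∧ T1 > 0 ∧ T2 p > 0.05 ∧ host p > 0.05. Down-specific features are
  out of scope by construction (the rule targets up-regulation in one group).

## Survival analysis

* Stratification: low = value ≤ median (ties to low, configurable in
  principle; a constant vector is not stratifiable and raises).
* KM product-limit and a two-group log-rank (O−E/V with the hypergeometric
  variance at tied event times), implemented as a single vectorized pass so a
  5,000-circRNA screen costs one risk-table traversal; verified against
  lifelines and a literal term-by-term oracle.
* Screens: BH across the circRNAs actually screened in a subset (non-constant
  expression, subset ≥ 20 patients); FDR cutoffs (0.2 for risk-group screens,
  0.1 for subtype screens) are reporting conveniences — full tables are always
  written.
* Cox: lifelines `CoxPHFitter`, Efron tie handling; categorical covariates
  dummy-coded; constant and collinear columns dropped with warnings. The
  classical identity (score test at β = 0 equals log-rank on tie-free data) is
  property-tested numerically.
* Clinical association: Pearson chi-square without continuity correction;
  2×2 odds ratio with Woolf log-OR ± 1.96·SE CI, 0.5 added per cell only when
  a cell is zero; continuous features by Wilcoxon rank-sum; BH across
  features.

## Drug association and signature transfer

A drug is significant when Welch p < 0.05 AND |median(high) − median(low)| > 1
in response units — the median difference is taken in absolute value because
drugs may favor either stratum. The favored group maps the sign through the
orientation contract (DSS higher = better; AUC lower = better); negating all
responses and flipping the orientation provably leaves verdicts unchanged.

The transfer signature takes genes with FDR < 0.05, |log₂FC| > 1 and mean
normalized expression above the median of all genes' means; each gene carries
the sign of its discovery log₂FC. In the validation cohort each signature gene
votes a patient toward high-like when d_g·sign(expr − median_g) > 0, using the
**validation cohort's own per-gene median** — the wording of the source method
is ambiguous between discovery and validation medians; the validation median
is chosen because it needs no cross-cohort scale alignment and is exactly what
makes the labels invariant to additive per-gene batch shifts (the mechanism
behind the batch-robustness claim, tested directly). Exact-median expression
abstains; labels need a strict majority of cast votes; ties and all-abstain
patients stay unassigned — determinism over coverage. Validation of a drug
finding requires two-sided Welch p < 0.05 *and* direction concordance with the
discovery claim after orientation mapping (the source's sidedness is unstated;
two-sided plus a direction check is this package's rule).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
nothing more. Defaults (the desk-scale study conditions):

| parameter | default | rationale |
|---|---|---|
| patients / controls | 300 / 100 | same order as a large AML cohort, desk scale |
| circRNAs / genes | 5,000 / 2,000 | ditto |
| risk groups | Adverse .35 / Intermediate .35 / Favorable .30 | roughly balanced tripartition |
| BSJ counts | NB, Var = μ + αμ²; μ lognormal(median 2, σ=1.2); α lognormal(median 0.4, σ=0.5) | low-abundance, overdispersed BSJ support |
| library sizes | lognormal, median 3·10⁷, σ=0.3 | exercises FPM / size-factor code |
| planted DE | 100 circRNAs, log₂FC ±2 (half up, half down) | balanced so median-of-ratios stays unbiased |
| subgroup shift | 50 circRNAs +1.5 log₂ in Adverse; 10 more with co-shifted hosts (veto set) | |
| prognostic circRNA | 1, log HR = log 2.5 on the high/low indicator | chosen among mid-expressed circRNAs so the median split is informative |
| survival | exponential PH, h₀ = 0.02/month, 30% independent exponential censoring | |
| tools | detection .95/.90/.90, 150 private false positives each | the planted prognostic circRNA is always called by all tools so the survival stage's target survives the consensus step; attrition applies to everything else |
| poly-A cohort | 40 samples; 50 artifact ids at NB mean 20, background Poisson(0.05) | artifacts exceed the TN thresholds essentially surely |
| drugs | 45 patients × 100 drugs; 10 hits, effect +3 DSS units, noise σ=1.5 | effect comfortably above the Δmedian > 1 rule |
| validation cohort | 150 patients; 30 signature genes at |log₂FC| = 2; per-gene batch shift N(0, 1) on the log₂ scale | the additive shift is the structure the vote scheme is claimed to absorb |

Every component draws from its own child stream of the master seed
(`SeedSequence.spawn`), so changing the drug block never perturbs the count
matrix; the whole bundle is byte-reproducible from (config, seed).

**What the generator does not emulate** — and hence what passing tests do not
show about real data: read-level artifacts and mapping ambiguity, isoform
structure and spliced lengths, correlated expression between circRNAs and
their host genes, non-proportional hazards, informative censoring,
batch structure beyond an additive per-gene shift, and dose–response curve
shape (DSS/AUC are taken as given). The acceptance measurements are
statements about the implementation's operating characteristics under this
model, not about any particular cohort.

## Numerical choices and degenerate inputs

Dispersion floor 10⁻⁸; variance floors 10⁻⁶ (T1/T2); Newton steps clipped to
±2 on the log scale with a 10⁻¹² convergence tolerance; group log-means
floored at log 10⁻⁸ so all-zero groups yield huge SEs (p → 1) rather than
infinities; BH propagates missing p-values; constant expression vectors are
unstratifiable (error); subsets below 20 patients refuse to screen; empty
transfer signatures raise in the library, and the pipeline records the stage
as "empty signature" with empty output tables rather than aborting the run.

## Known limitations

The DE engine deliberately omits dispersion shrinkage and LFC moderation, so
per-feature estimates are noisier than a production engine's at small n — the
planted-recovery margins absorb this. The chi-square reference for the
log-rank statistic is mildly anticonservative in the far tail at moderate
event counts, which can push the global-null screen's family-wise hit rate
slightly above the nominal BH bound. Locus classification ignores strand and
transcript structure. The pipeline's `--threads` flag is accepted for
interface stability but the implementation is single-threaded (results are
trivially independent of it).
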