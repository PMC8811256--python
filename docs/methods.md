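# Methods

This note records the statistical models, default parameters, numerical
choices and known limitations of the `trlim` pipeline, and what its
synthetic-data generators do and do not emulate.

## Tier 1: inhibitor-screen indices

A weighing record is one (genotype, set, replicate, phase) observation:
flask mass before and after a timed interval. Transpiration rate is mass
loss over time, canonically **mg min⁻¹ per shoot**; when a leaf area (m²)
accompanies a record the rate is converted to mg m⁻² s⁻¹. Leaf-area
measurement is rarely available in this assay, so the per-shoot unit is
the internal canon and area normalization is opt-in. Negative rates
(condensation, weighing error) are flagged and excluded from index
computation by default, never silently accepted.

The decrease indices DTR, RTR and NDTR are algebraically linked:
NDTR = (RTR−1)/(RTR+1) and DTR = 100(1−1/RTR). These identities hold to
1e-9 (relative) for all positive rate pairs and are enforced by property
tests. The parent-relative indices divide by the reference parent's value;
a parent with a zero index is an error naming the parent, not a NaN.

**Least-square means.** Genotype values are fitted by ordinary least
squares on genotype indicators plus sum-to-zero set contrasts, with
replicates as observations. The study design this mirrors used a mixed
model (sets and replicates-within-set random); the fixed-effects LSM is
identical in balanced designs and deterministic, dependency-free in
unbalanced ones. The difference only matters under strong imbalance,
where a mixed model would shrink set effects.

**Wilting classes.** RDTR_K ≤ 0.50 slow, 0.50 < RDTR_K ≤ 1.00 moderate,
> 1.00 fast. The stated ranges (0.00–0.50 vs 0.51–1.00) leave (0.50, 0.51)
undefined for continuous values; the half-open convention above closes the
gap and keeps classification total and monotone.

**Heritability.** Variance components come from the balanced two-way
ANOVA expected mean squares: σ²_e = MS_error, σ²_GE = (MS_GxS − MS_e)/r,
σ²_G = (MS_G − MS_GxS)/(S·r). Negative moment estimates truncate to zero
with a warning. Entry-mean broad-sense heritability is
H² = σ²_G/(σ²_G + σ²_GE/E + σ²_e/(E·R)). Mildly unbalanced cell counts
use the mean count in the EMS coefficients (warned); an empty cell is an
error because the coefficients are then undefined. Skewness and kurtosis
in summaries follow the Fisher bias-corrected conventions (excess
kurtosis 0 for a normal sample).

## Tier 2: segmented VPD response

The model is two straight lines constrained to intersect at the
breakpoint: with basis y = b0 + b1·min(v, BP) + b2·max(v − BP, 0),
continuity is automatic and the fit is linear given BP. BP is profiled
over 200 candidates between the second-smallest and second-largest
observed VPD (each candidate must leave ≥ 3 points per segment — two
parameters per line plus one), then refined by bounded scalar
minimization between the neighbouring grid candidates (xatol 1e-6 kPa).
This matches an exhaustive 0.001-kPa grid to within one grid step and is
fully deterministic — no random restarts.

**Model selection.** Two candidate tests are computed on every fit:

* the conditional-on-BP t test of Slope1 = Slope2, with n − 4 residual
  degrees of freedom (one charged for BP), and
* the extra-sum-of-squares F test of the broken line against the single
  line (2 numerator df: the extra slope and the breakpoint).

Because BP is chosen to maximize the apparent slope change, the
conditional t is strongly anti-conservative: on pure straight lines
(n = 24, σ = 0.05) it rejects at ~21% for nominal α = 5%. The F
comparison measures ~7% under the same conditions with power
indistinguishable from the t at the effect sizes of interest, so the F
test drives selection by default (`criterion="extra_ss"`); the t statistic
and its p-value are still reported on every fit, and `criterion="slope_t"`
restores the conditional test. Neither test accounts fully for the
breakpoint search, so both remain slightly liberal; exact calibration
would need a Davies-type bound or simulation, out of scope here.

A genotype expresses TRlim iff the segmented model is retained **and**
Slope2 < Slope1. A steepening break (Slope2 > Slope1) is biologically the
opposite of limited transpiration and is reported as "Linear" in
classification output while the raw fit is retained. All replicate plants
of a genotype pool into one regression. Breakpoints print at full
precision; table output may round to 0.1 kPa.

## QTL mapping

**Genotype probabilities.** ABH-coded genotypes (AA = "Jackson"
homozygote, BB = "KS4895" homozygote) are treated under F2-intercross
transition probabilities with Haldane map distances — the effective
treatment of an early-selfing RIL set carrying residual heterozygosity
(observed AB ≈ 25–34%), and the treatment that keeps an exact enumeration
oracle. Probabilities at off-marker positions condition on the nearest
informative (non-missing) flanking markers; at an observed marker they
collapse to the indicator. No genotyping-error model is applied — error
correction is assumed upstream.

**Scans.** Haley–Knott regression on the expected additive score
P(AA) − P(BB) and dominance score P(AB); LOD = (n/2)·log10(RSS0/RSS1).
Exact expected scores replace stochastic imputation draws: deterministic
and oracle-checkable. The scan grid is every marker plus every `step`
(default 1 cM); ties at equal LOD break toward the lower position.
Projections use an SVD basis so rank-deficient designs (e.g. no
heterozygotes) degrade gracefully. CIM forward-selects up to 3 marker
cofactors by partial-F p-value (entry threshold 0.05) and drops cofactors
within 10 cM of the test position on the same chromosome; with zero
cofactors CIM is bit-identical to the standard scan. Cofactor count and
window are unstandardized in the field; both are configurable and logged.

**Permutation thresholds** permute the phenotype across lines (default
1,000 permutations, α = 0.05) and take the empirical upper quantile
(`method="higher"`, marginally conservative) of the genome-wide maximum
LOD of standard scans. Cofactors are not re-selected inside permutations;
CIM LODs compared against this threshold are therefore slightly
anti-conservative, a standard trade-off.

**QTL model.** Candidate positions (per-chromosome scan maxima) are
refined to local LOD maxima, QTL closer than 1 cM merge, and a joint
additive + dominance linear model is fitted. Per-QTL type III SS come from
drop-one refitting; %var = 100·SS_QTL/TSS; the allelic effect is the
fitted AA-minus-BB difference (twice the additive coefficient); the
reported per-QTL LOD is the drop-one likelihood ratio — the same quantity
a refine-and-refit workflow reports, and the one used to judge a QTL
against the permutation threshold. Support intervals use the 1.5-LOD drop
convention (configurable).

## Synthetic data

Generators are pure functions of (parameters, seed) and serialize their
ground truth as JSON sidecars. Defaults mirror the study conditions where
cheap: 120 lines, 6 sets × 3 replicates, VPD grids of 24 points over
0.5–4.0 kPa with Gaussian noise σ = 0.05, planted QTL at 27.6% and 14.3%
of line variance with opposite parental directions; the genetic map
scales down to 5 chromosomes × 50 markers at 2 cM (the analysis is
map-agnostic).

* RIL genotypes: F1 selfed for 2 (F3) or 4 (F5) generations; gametes
  switch parental strand between adjacent markers with the Haldane
  recombination fraction (no interference), at marker resolution.
* Phenotypes: line genetic values from planted QTL; with `pct_var`
  parameterization, effects are scaled from realized genotype-score
  variances so planted fractions refer to a unit per-line phenotypic
  variance. The non-genetic line-mean budget splits between G×E and
  residual by `ge_share` (default 0.3); set main effects (SD 0.1) sit
  outside the heritability denominator, as in the H² formula.
* Weighing records: two phases per plant (60 min water, 180 min AgNO3
  from 150 g flasks), inhibitor sensitivity s giving an AgNO3 rate of
  (1 − s)× the water rate; multiplicative mass-loss noise (default 2%).
  Zero noise recovers DTR = 100·s exactly through the full tier-1 path.
* Annotations: non-overlapping genes, a planted fraction carrying GO
  names that embed the drought keywords.

What the generators do **not** emulate: genotyping error and missingness
patterns, segregation distortion, crossover interference, heteroscedastic
or heavy-tailed measurement noise, diurnal VPD drift, and leaf-area
variation. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to those realities.

## Numerical conventions and degenerate inputs

Sample SD uses n − 1; 95% bounds are two-sided t intervals. Dispersion
statistics of n < 2 vectors are NaN markers, never zero. A zero-variance
phenotype yields an all-zero scan with a warning; collinear covariates
are dropped with a warning; an exactly-fitting broken line with unequal
slopes reports p = 0 with an exact-fit flag, and an exactly-fitting
single line forces the linear model. Candidate-gene coordinates are
1-based inclusive with ≥ 1 bp overlap (a gene ending at the interval
start is included); keyword matching is case-insensitive substring on GO
term names, with an opt-in description search. Seeds propagate explicitly
through every stochastic entry point; equal seeds give byte-identical
outputs.

## Known limitations

The F2-style genotype model approximates, rather than tracks, the
F3/F5 selfing pedigree; the LSM is fixed-effects, not REML; permutation
thresholds do not re-select CIM cofactors; the segmented-model tests are
mildly liberal as noted; and candidate-gene counts depend entirely on the
annotation's GO-name vocabulary, so counts from different annotation
snapshots are not comparable.
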