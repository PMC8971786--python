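# Methods

## Repertoire metrics

A repertoire is a table of unique TCR-β CDR3 clonotypes with positive integer
read counts. With counts c_i, total T, frequencies p_i = c_i/T and N unique
clonotypes:

- **D50**: counts are sorted descending (ties broken by clonotype id so the
  selected set is reproducible; the D50 *value* is tie-invariant) and D50 is
  the smallest k with Σ_{top k} c_i ≥ T/2. The boundary is inclusive ("greater
  than or equal to 50%"), implemented on integers (2·cumsum ≥ T) so no
  floating-point boundary artefact is possible. 1 ≤ D50 ≤ ⌈N/2⌉, the upper
  bound attained by perfectly even repertoires.
- **Normalized Shannon entropy**: HNorm = −Σ p_i ln p_i / ln N, natural log in
  numerator and denominator (the base cancels only if consistent). N is the
  number of unique clonotypes — the Pielou-evenness reading — because only
  this denominator makes the stated range [0, 1] attainable with equality for
  even repertoires. A `denominator="reads"` switch divides by ln T instead for
  sensitivity analysis. At N = 1 the formula is 0/0; we define HNorm = 0: a
  monoclonal repertoire has no evenness.
- **Clonal proportion**: N/T. **Abundance groups**: read fractions in rank
  decades 1–10, 11–100, 101–1000, 1001–10000, 10001+ (configurable edges; the
  decade convention of common repertoire toolkits).

## Synthetic cohorts

The generator emulates the statistical structure a paired pre/post-NAC
analysis assumes, not any patient's data.

**Pre-treatment repertoires.** Clone r of n has sampling probability
∝ r^(−s) (truncated Zipf; s = 0 is uniform); counts are multinomial at the
configured depth. Any zero-count clone is re-seeded with one read taken from
the largest clone(s), so the unique count is exactly n and reads are exactly
conserved — a deterministic repair preferable to rejection sampling because
it leaves tail shape intact. Defaults: 1,000 clones, exponent 1.5, 50,000
reads — a depth and concentration at which a handful of clones hold half the
reads, matching the power-law picture of bulk tumor TCR data.

**Post-treatment perturbation.** The ⌈f·n⌉ highest-count clones are removed
(default f = 0.01), reads are resampled multinomially at 70% of the original
depth from the survivors' empirical frequencies, and 200 novel clonotypes
enter at the minimum surviving-clone frequency (new clones are rare when they
appear). Clones drawn with zero reads at the shallower depth drop out — no
re-seeding here, since losing marginal clones to reduced depth is part of the
phenomenon being emulated. With every parameter at its null value
(f = 0, influx = 0, depth = 1) the function returns the pre table unchanged:
a full-depth resample would still drop singletons and therefore would not be
a null treatment, which matters for calibration tests. These defaults produce
lower total reads, higher unique count, higher D50 and higher HNorm post- vs
pre-treatment in ≥ 90% of simulated pairs; no quantitative effect sizes are
claimed beyond this direction.

**Cell and core tables.** mIF cells are assigned a compartment (tumor nest vs
stroma, 50/50 by default) and then a phenotype category per configured
(combination, compartment) fraction; marker flags follow the combination.
Below 11 fields a warning reproduces the >10-fields-per-slide acquisition
convention without blocking small fixtures. IHC cores draw a
malignant-epithelial-cell fraction from a Beta distribution and binomial
positive counts; three cores per case mirrors the standard TMA triplicate.

**Clinical covariates.** Responders (configurable fraction, default 0.5) get
TRG 0/1, non-responders 2/3. Marker densities are
clip(Normal(pre-mean + post-shift·1[post] + responder-shift·1[responder],
σ = 3), 0, 100) percent; defaults make FOXP3 fall after treatment and sit
higher pre-treatment in responders, CD8 rise after treatment. TMB is Poisson
(mean 80) pre and Poisson(pre + 20) post; neoantigen counts are binomial
thinning of TMB at rate 0.1 (positive coupling). Overall survival is
exponential with log-hazard −0.03 per percent of post-treatment CD8 density
(HR ≈ 0.97/%, the scale typical of per-percent density covariates), baseline
scaled so the cohort median is ≈ 32 months at the expected CD8 level, with
administrative censoring at 60 months. No survival-distribution detail beyond
"exponential + administrative censoring" is claimed.

All randomness flows from one integer seed through named per-table
sub-streams (numpy `SeedSequence`-style keyed generators), so any table can
be regenerated independently and identical config + seed gives byte-identical
tables.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: V/D/J recombination and CDR3 sequence realism (clone
identity is an opaque id), PCR amplification bias and sampling overdispersion
beyond multinomial, spatial correlation of cells within fields, inter-marker
correlation of densities within a patient, non-exponential hazards, and any
quantitative pre/post effect size. Conclusions about real cohorts require the
real tables.

## Density quantification

IHC: cores with tumor-cell fraction < 0.5 are excluded (inclusive boundary at
exactly 0.5); per-core immunoreactivity is 100·pos/(pos+neg); the per-case
value is the unweighted mean over retained cores; cases with no retained core
are dropped listwise per comparison, never imputed — mirroring
analyzable-n reporting rather than imputation. mIF: density of a phenotype
combination (conjunction of marker states, negation via `CD8+FOXP3-`) is the
percentage of matching cells among all nucleated cells of the compartment,
pooled over fields by default; a per-field-average variant is exposed because
acquisition protocols are ambiguous on this point, and the two agree closely
for balanced fields. Densities are percentages, not cells/mm²; the protocol
defines only the percentage. Figure-scale values use log2(density + 1).

## Association statistics

- Paired contrasts: Wilcoxon signed-rank, two-sided, zeros dropped; all-zero
  differences give p = 1 by convention; ≥ 3 complete pairs required. scipy's
  exact null is used whenever there are no ties/zeros and n ≤ 50, the tie- and
  continuity-corrected normal approximation otherwise.
- Group contrasts: Mann-Whitney rank-sum, exact when both groups are ≤ 25
  with no ties (paired-cohort group sizes straddle the exact/asymptotic
  boundary, so the exact path is forced well past scipy's default switch).
- Multiplicity: Benjamini-Hochberg step-up applied separately within each
  biomarker's family of contrasts (a marker's compartment and responder
  contrasts form one family; repertoire metrics form one; TMB one). This
  controls FDR per family; it does not bound the probability that *some*
  family rejects, which grows with the number of families.
- ROC: AUC by the Mann-Whitney rank formulation with midranks (identical to
  the trapezoidal integral), 95% CI by class-stratified percentile bootstrap
  (2,000 resamples, seeded) — chosen over asymptotic formulas to avoid a
  distributional assumption at n = 30.
- Survival: Kaplan-Meier product-limit medians and the log-rank test;
  two-stage Cox — univariable screening, then a multivariable model on
  variables with univariable p ≤ 0.05 pruned by backward elimination, where
  at each step the term whose removal has the largest likelihood-ratio p is
  dropped if that p > 0.05. Continuous covariates enter on their supplied
  scale (densities per percent), so hazard ratios read "per unit". Fits that
  fail to converge are flagged per variable, not fatal. Fewer than 10 events
  warns.
- Contingency: Fisher's exact for 2×2, chi-square for larger tables,
  Cochran-Mantel-Haenszel for stratified 2×2 collections.

## Pipeline

Stages run simulate → repertoire → density → compare → survive; every
figure-like output is a tidy CSV with a JSON column-schema sidecar validated
on load, and `manifest.json` records config hash, seed, per-stage n and
output checksums. Filters log their removal counts (e.g. cores excluded by
the ≥ 50% rule) so analyzable n is always visible. The CLI is a thin click
wrapper; exit status is nonzero on any error contract.

## Problem sizes

Default simulated cohorts follow the paired-cohort design: 30 patients,
1,000 clones, 50,000 reads. Test and calibration batteries use 100 simulated
pairs for the direction property, 2,000 replicates at n = 15 for type-I-error
calibration, 200 seeds at n = 300 with ~40% administrative censoring for
hazard-ratio recovery and CI coverage, and 1,000 mixed repertoires
(10–5,000 clones, Zipf exponents 0.5–2.0 mixed with uniform, 20 reads per
clone) for the D50/HNorm bound battery — sizes at which every Monte-Carlo
band in the tests is comfortably wider than its standard error.

## Known limitations

Percent-density and count data produce ties that push rank tests onto
approximate nulls at moderate n; the Cox stage assumes proportional hazards
and offers no diagnostics, time-varying covariates or competing risks; the
mIF path starts from called per-cell phenotypes and performs no segmentation,
unmixing or intensity thresholding; clinical hazard ratios and AUCs from real
cohorts are not reproducible from synthetic data — the pipeline reproduces
the analysis, not the patients.
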