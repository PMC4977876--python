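# Methods

This note documents the models, defaults, and numerical choices behind
`bxlink`, and what the synthetic-data generator does and does not
emulate.

## Genetic model and simulation

A backcross of (SPRET × FVB) F1 females to FVB males segregates two
genotype classes per autosomal locus: FVB/FVB (coded `AA`) and FVB/SPRET
(`AB`), each expected at frequency 1/2. Each chromosome is simulated as a
two-state Markov chain whose transition probability between markers at
genetic distance *d* cM is the Haldane recombination fraction
r = (1 − e^(−2d/100))/2. Haldane (no crossover interference) is the only
map function offered, deliberately matching the transition model of the
scan engine's hidden Markov chain so that simulation and inference share
one assumption set. On the X, females receive a paternal FVB X and a
maternal recombinant (AA/AB as on autosomes); males carry only the
maternal recombinant, coded hemizygous AY/BY. Genotyping error flips a
call with a configurable probability (default 0); missingness masks calls
at a configurable rate (default 0).

The default map is 19 autosomes of 130 cM plus a 90 cM X at 10 cM
spacing — 276 markers, the panel size of the emulated study — with
physical positions at 2 Mb/cM.

**Phenotypes.** Length and BMI are generated on standardized scales
(planted additive QTL contribute a·g with g ∈ {0,1}; residual SD 1, so a
planted effect a yields expected variance explained a²/4 / (a²/4 + 1)),
then mapped to natural units using per-sex anchors in the emulated
cohort's regime (length 9.83/9.41 ± 0.55 cm, BMI 0.27/0.23 ± 0.03 g/cm²
for males/females). Weight is derived as BMI·length², so the defining
identity BMI = weight/length² holds exactly; weight QTL are planted on
the derived scale (one "SD" = the realized within-sex weight SD) and BMI
is recomputed, so weight loci also move BMI as they do in a real animal.
Sex-restricted effects are added only in the configured sex.

**Expression.** Genes × individuals, log2-like scale (baseline 8, unit
noise). A co-expression module of *m* genes shares one standard-normal
latent factor with loading ℓ (every pairwise correlation ℓ²; the default
ℓ = 0.7746 plants rho ≈ 0.6, the regime of the lipid-metabolism
neighborhood the pipeline is designed to recover, with 32 members).
eQTL genes receive an additive genotype shift at their marker; cis genes
are placed at the marker's physical position. An optional coupling term
adds a direct (genotype-independent) phenotype association to a gene,
which is how a "driver" gene that should survive genotype adjustment is
planted.

**Tumors.** Papilloma counts at weeks 10–20 (biweekly) are gamma-Poisson:
a per-mouse gamma frailty (variance = the negative-binomial dispersion,
default 0.5) shared across timepoints, a linear ramp to week 20, and a
log mean linear in within-sex-standardized BMI with sex-specific
coefficients (defaults 0.40 male / 0 female, which reproduce a male
BMI–burden Spearman rho near 0.38 and a null in females). The count
distribution is a modeling choice — the study the generator emulates
reports overdispersed integer counts without naming a distribution.
Carcinoma-free survival is exponential with log hazard linear in the same
score (default male log-HR 0.338 per BMI SD ≈ ln(2.36)/2.54, the per-SD
rate under which the top-vs-bottom BMI quartile contrast is a ≈2.36-fold
risk; baseline 0.00268/day gives ~70% events by the 450-day follow-up).

**What the generator does not emulate:** probe-level microarray noise and
normalization artifacts, batch structure, linkage disequilibrium beyond
the marker Markov chain, litter effects, and genuinely non-proportional
hazards. Passing tests therefore demonstrate correctness and calibration
of the statistical machinery under the stated generative model, not
robustness to those real-data complications.

All randomness flows through NumPy's PCG64 `default_rng`; a fixed seed
gives bit-identical output. High-level entry points expand one seed into
per-stage child seeds via `SeedSequence` spawning (simulation) or a fixed
`SeedSequence([global_seed, stage_counter])` scheme (pipeline), so stages
are independently reproducible.

## Genotype calling and QC

Autosomal calls compare each sample's channel-normalized signal
(a, b)/(a+b) to FVB, SPRET, and F1 control centroids; the nearest class
wins, SPRET-like samples (impossible in this backcross) and samples whose
second-best/best distance ratio is below 1.2 are set missing — a
conservative stand-in for the manual curation such panels receive. X
calls are made per sex by two-class linear discriminant with pooled
covariance, seeded from the 10th/90th allele-fraction percentiles;
Mahalanobis outliers beyond 4 units are excluded from the class
statistics and set missing, and midplane points are missing.

QC thresholds are package defaults, configurable, since the emulated
protocol does not state its cutoffs: individuals are dropped at >10%
missing calls, at genome-wide crossover counts above 2× the expected
total map length/100, or as the more-missing member of a pair with >95%
genotype concordance. Markers are dropped at >10% missingness or when an
exact binomial test of SPRET-carrier frequency against 1/2 falls below
α = 10⁻⁶. QC is idempotent, and on clean simulated data it excludes
nothing (verified over 20 seeds).

## Genome scans

Conditional P(HET | observed markers) is computed by a two-state
forward–backward pass per chromosome with Haldane transitions and a
symmetric error emission, on a grid of markers plus pseudomarkers
(default step 2 cM; the source protocol is silent, and at this marker
density results are insensitive to the step). Probabilities at typed
markers with error 0 equal the calls exactly.

Haley–Knott regression fits, at each position,
LOD = (n/2)·log₁₀(RSS₀/RSS₁) with the alternative {covariates + genotype
(+ genotype × interactive covariates)} against the null {covariates};
interactive covariates enter the null additively. The implementation uses
Frisch–Waugh residualization so permutations reduce to matrix products.
On the X the four sex-specific classes are fitted with sex always in the
null. An extended mode reweights by conditional genotype variances
(one-step); with a dense map and low missingness it coincides with the
standard fit, which is the default. Constant-genotype positions yield
LOD 0 via a ridge-stabilized solve; ties at a peak resolve to the lowest
cM.

Permutation thresholds shuffle the phenotype (within sex strata whenever
sex is in the model or the X is scanned), record autosome and X maxima
separately, and split α by genetic length:
α_part = 1 − (1−α)^(L_part/L). The emulated configuration is 1000
autosome and 27,000 X permutations at α = 0.05; the acceptance
experiments use fewer with correspondingly widened calibration bands.

The 95% Bayes credible interval normalizes 10^LOD × grid-cell width on
one chromosome, absorbs grid points greedily outward from the peak
(larger posterior first, left on ties), and then widens by one grid step
on each side — the conventional conservative reporting, which reproduces
the standard hand-worked five-point toy ([10, 30] cM). Physical bounds
interpolate Mb linearly in cM between flanking markers.

Two-locus models evaluate additive and full (product-interaction) fits
over all position pairs ≥10 cM apart on one chromosome; a second locus is
declared when max additive LOD − max single LOD clears its permutation
threshold, an interaction when full − additive clears its own.
`refine_positions` is coordinate ascent on the joint additive model; the
joint LOD is non-decreasing by construction and single-locus refinement
equals the scan argmax. The sex-interaction test is the 1-df ANOVA F of
{g + sex + g×sex} over {g + sex}.

Variance explained uses r² = 1 − 10^(−2·LOD/n), with n the phenotyped
sample count entering the scan.

## Candidate genes

The sequence route takes the marker-bounded physical interval of the QTL
(not the credible interval), intersects gene start positions, and keeps
genes with ≥1 variant in {non-synonymous, nonsense, frameshift insertion/
deletion, splice site}; synonymous and non-coding variants never qualify.

The expression route computes the SAM d statistic
(x̄₁ − x̄₂)/(s + s₀) against the genotype at the marker nearest the peak
(minimal |ΔcM|, lower Mb on ties). s₀ follows the published recipe:
candidates at the 0,5,…,100 percentiles of s, choosing the one that
minimizes the coefficient of variation of the windowed MAD of d. On the X
the four sex-specific genotype classes use the multi-class (F-like) d.
FDR is permutation-based — per cutoff, the median permuted exceedance
count over the observed count, monotonized, with π₀ = 1 (conservative).
Flagged genes are then scanned genome-wide; a gene passes iff its eQTL
peak LOD ≥ 3 (boundary inclusive) and its Bayes interval overlaps the
phenotype QTL's interval on the same chromosome.

The union of routes is tested for expression ~ phenotype association with
an empirical-Bayes moderated t: per-gene OLS variances are shrunk toward
a scaled-F prior whose (d₀, s₀²) are fitted by method of moments on log
sample variances (trigamma equation solved by Newton; fewer than two
genes means no shrinkage information and ordinary t). Benjamini–Hochberg
FDR is applied across the union; survivors are refit with the peak-marker
genotype as covariate and the ordinary phenotype-term p at α = 0.05
decides. Congruency requires sign(QTL→phenotype) × sign(QTL→expression) =
sign(expression↔phenotype); triples with any zero/missing sign are
not evaluable and do not veto a hit, while evaluably incongruent genes
are reported but excluded from hits.

## Co-expression neighborhoods

Spearman correlations use average ranks (tie-corrected, Pearson on
ranks); constant genes are recorded missing. The GWER threshold is the
(1−α) quantile of the maximum |rho| attained when the sample labels of
one randomly chosen probe vector are shuffled against the whole matrix
(1000 permutations by default, per sex stratum). Significance is
two-sided on |rho|. The neighborhood is the seed's above-threshold
partners (first degree) plus every above-threshold correlation of those
partners; nodes introduced by those edges are second degree and are not
expanded further. GO enrichment is the one-sided hypergeometric tail
against the annotated universe — classic Fisher-style testing without
GO-graph decorrelation, a documented simplification. Export writes
name-sorted node and edge tables that round-trip exactly.

## Tumor statistics

Quartile groups use type-7 quantiles with membership v ≥ Q3 / v ≤ Q1.
Mann–Whitney is exact for tie-free groups of ≤20 and normal-approximate
otherwise. The interaction model is OLS counts ~ phenotype × sex with the
1-df interaction t-test. Cox proportional hazards is fit by
Newton–Raphson on the Breslow partial likelihood (step clipping at ±2;
monotone likelihood is flagged and the boundary estimate returned), with
Wald CIs and a standard hypergeometric two-group log-rank; the estimate
is cross-checked in tests against a likelihood grid search and the
lifelines implementation. ΔΔCt subtracts the reference-gene Ct per
sample, baselines to the control group, reports RQ = 2^(−ΔΔCt), and tests
groups by Welch t on per-sample ΔCt; a global Ct shift cancels exactly.
The ordinal 0–3 score test is an exact conditional (Fisher-type) r×c
test: all tables with the observed margins are enumerated and those no
more probable than the observed table are summed, with a seeded
Monte-Carlo fallback above an enumeration bound of ~2×10⁶ tables.

## Problem sizes in the validation experiments

The acceptance script and test suite run the calibration and recovery
experiments at reduced but statistically honest sizes chosen as package
defaults: 120–200 null cohorts with 200 permutations each for threshold
calibration (binomial bands widened accordingly), 100 seeds for QTL
localization, 30–50 seeds for two-locus, candidate, and survival
recovery, and 60–100 replicate datasets for GWER calibration. Each
experiment regenerates its cohorts from the supplied seed.

## Known limitations

Marker-bounded QTL regions depend on map density; with 10 cM spacing the
physical bounds are coarse. The permutation FDR for the d statistic uses
π₀ = 1 and is therefore conservative. The exact r×c test enumerates only
small tables. The extended Haley–Knott mode is a one-step reweighting,
not a fully iterated fit. X-chromosome dosage-compensation modeling is
limited to treating male hemizygous classes as distinct regression
levels.
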