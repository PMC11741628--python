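# Methods

`kirmod` implements, end to end and on synthetic data, an immunogenetic
analysis of how functional inhibitory-KIR gene dosage modifies HLA class II
associations in Type 1 Diabetes (T1D), together with the dynamical model
that rationalises the finding. This note documents the models, the choices
that were genuinely open, and what the synthetic studies do and do not show.

## The iKIR score

Inhibitory killer-cell immunoglobulin-like receptors (iKIRs) and the genes
encoding their HLA class I ligands segregate on different chromosomes. An
iKIR gene present together with its ligand gene is *functional*:
KIR2DL1 with C2-group HLA-C, KIR2DL2/KIR2DL3 with C1-group HLA-C, KIR3DL1
with Bw4-motif HLA-B/A alleles (80I and 80T subtypes), and, optionally,
KIR3DL2 with HLA-A*03/A*11. The iKIR score sums interaction-strength
weights over an individual's functional pairs.

Two packaged, versioned tables define the mapping:

* `ligand_groups.yaml` (lg-2024.1) — allele → ligand group, by editable
  name-prefix lists (HLA-C position-80 dimorphism for C1/C2; explicit Bw4
  lists). The cohort format carries allele names, not sequences, so a
  lookup table rather than motif parsing is the right primitive. The
  80I/80T subdivision of rare HLA-B alleles is approximate.
* `score_weights.yaml` (w-2024.1) — per-pair weights (KIR2DL1/C2 = 1.0,
  KIR2DL2/C1 = 0.5, KIR2DL3/C1 = 0.75, KIR3DL1/Bw4-80I = 1.0,
  KIR3DL1/Bw4-80T = 0.75; KIR3DL2/A3-A11 = 0.25, excluded by default).
  The attainable score range is [0, 3.25], so the stratification
  thresholds used throughout (1.5, 1.75, 2.0, 2.5) are all interior.
  Every profile records the weight-table version. With unit weights the
  score reduces exactly to the functional-iKIR count.

Ties at a threshold go to the "low" stratum.

## Synthetic cohorts

`syndata` generates case-control cohorts from an explicit logistic disease
model:

    logit P(case) = b0 + Σ_g β_g·carr_g + β_int·score·carr_g(protective)
                    + β_sex·male

Class II variation is simulated as phased DRB1–DQA1–DQB1 haplotypes drawn
i.i.d. from a pool; a configured genotype label's carriage probability p is
converted to a haplotype frequency h = 1 − sqrt(1 − p). Explicit phase
means cis/trans genotype predicates are exercised for real. KIR genes are
independent Bernoulli draws (separate chromosome); class I alleles are
drawn per locus, with linkage to class II injected as conditional odds
multipliers on allele sampling weights (`ld_links`). The intercept b0 is
solved numerically so the population case fraction matches
n_cases/(n_cases+n_controls), and records are filled by rejection
sampling — the case-control (not prospective) sampling scheme; logistic
slopes are invariant to it.

The default architecture (`default_cohort_config`) mirrors the structure of
a European T1D cohort: a strongly protective DQ6-like haplotype
(DQA1\*01:02-DQB1\*06:02, carriage 0.30, β = −2.5), a moderately protective
DQB1\*03:01 (0.30, −1.25), detrimental DR3 (0.25, +1.4) and DQB1\*03:02
(0.25, +1.6) haplotypes, and one linkage link (B\*08:01 enriched ×3 on the
DR3 haplotype, after the ancestral A1-B8-DR3 block). Frequencies
approximate control-group carriage; effect sizes are on the scale of
published whole-cohort estimates.

Two focused variants serve the statistical studies:

* *Null/calibration cohorts* clear `ld_links`. The linkage link couples
  the iKIR score to disease status even with a zero interaction (DR3
  carriers get B\*08:01-reweighted class I draws, shifting Bw4/C-group
  carriage and hence the score), so score exchangeability — the null the
  permutation test targets — genuinely fails under linkage. That is the
  same class I confounding the case-control analysis removes by excluding
  class I driver carriers; the calibration study removes it at the source.
* *Recovery cohorts* (`single_genotype_config`) carry one labelled
  genotype on a neutral background, so the fitted interaction model
  coincides with the generative model and CI coverage is interpretable.
  Under the four-genotype default, haplotype competition correlates
  carriage indicators and a one-genotype marginal fit is (correctly)
  biased for the conditional coefficient.

Family trios reuse the architecture: parents carry two full haplotypes
(class II plus linked class I), the child inherits one from each parent
plus independent KIR genes, and transmission choices are resampled until
the child is affected under the same logistic model. Under a null model
this leaves transmissions Mendelian (≈ 50:50); genotype effects distort
them exactly as a transmission-disequilibrium analysis expects.

What the generator does **not** emulate: recombination (LD is injected
multiplicatively at the haplotype level), allele-level KIR typing or copy
number, population stratification and relatedness, genotyping error or
missingness. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
those real-data features.

## Association analysis

Carriage is dominant-coded. Estimates are maximum-likelihood logistic
(statsmodels), reported as ln[OR] with Wald 95% CIs and p-values; a single
binary predictor with no covariates reproduces the closed-form 2×2
ln[(a·d)/(b·c)] to machine accuracy, which the tests assert to ≥6
significant digits. Perfect separation raises a diagnostic error rather
than returning a diverged fit. Zero 2×2 cells are an error unless the
Haldane–Anscombe +0.5 correction is explicitly enabled — silent correction
changes estimates. Stratified analyses fit each score stratum
independently with sex (optionally ligand) covariates and skip genotypes
with fewer than 10 case carriers. Interaction (dose) models support a
continuous or a stratified score term and report AIC = 2k − 2·max-log-lik
for model comparison; a backward step compares standardised score vs count
interactions. Power analysis resamples subcohorts with replacement
(cases = controls = s/2) and reports the fraction with interaction
p < 0.05.

## Permutation framework

The test statistic is S = Σ w_g (lnOR_high,g − lnOR_low,g) / Σ w_g with
w_g the genotype's carriage frequency in the analysed cohort (the only
frequency computable from the table without phase assumptions; recorded in
the output). The empirical null permutes the score vector across
individuals — preserving the score multiset and everything else — and
p = (#as-extreme + 1)/(n_perm + 1), which can never be zero. Direction is
set a priori: one-sided S > 0 for protective sets, two-sided for
detrimental ones; it is always recorded.

By default the per-genotype stratum estimates inside the permutation loop
are Haldane-corrected crude ln[OR]s. Counts for all permutations reduce to
one matrix product, so 10⁵ permutations on a 2,000-individual cohort take
well under a second; the +0.5 is applied identically to observed and
permuted data, so the test remains exact for the statistic actually used.
A sex-adjusted refit statistic (`statistic="adjusted"`) exists for spot
checks; it is O(n_perm) logistic fits and agrees in direction with the
crude path on the cohorts tested. Seeding uses one generator per test; in
replicate studies seeds are drawn from a meta-generator to avoid stream
collisions between data generation and permutation.

## Driver screen and multiplicity

Candidate genotypes are all class I alleles, class II alleles, and 2–3
allele class II combinations observed in at least `min_carriage`
individuals. A genotype is a *driver* if its sex-adjusted coefficient
keeps direction and p < 0.05 against every partner in pairwise co-fits.
Pairs with |r| ≥ 0.99 are not co-fitted; the member with the larger
marginal p is excluded in favour of the other, and the rule is logged —
the simplification needed for (near-)collinear genotypes. The output is
deterministic and independent of pair visit order.

The effective number of tests uses the Li & Ji eigenvalue estimator on the
Pearson correlation matrix of carriage indicators
(Meff = Σ [1(λ≥1) + (λ − ⌊λ⌋)]), with eigenvalues clipped at 0 and rounded
to 9 decimals before the floor to keep integer eigenvalues stable. The
significance cutoff is α/Meff. The estimator hits its limits exactly:
Meff = m for independent indicators, 1 for a rank-one matrix, and is
invariant to duplicating a column.

## Family transmission analysis

For each genotype, parents heterozygous for the genotype-bearing haplotype
are informative; trios are stratified by the affected child's iKIR score
(ties to "low", consistent with the case-control convention). The
statistic is D = log(T/NT)_high − log(T/NT)_low (a raw-ratio form is also
available), aggregated over genotype sets as the carriage-frequency-
weighted mean — mirroring the case-control statistic — and reducing to D
for a single genotype. Zero cells take +0.5 on all cells, always reported.
The null permutes children's scores across trios; parental data are
untouched, so the statistic's null distribution depends only on the
stratum-assignment exchangeability.

## Disease impact

Prevented fraction uses the counterfactual formula PF = f·(1 − RR), with
OR→RR conversion RR = OR/((1−p0) + p0·OR) where the non-carrier risk p0 is
solved from the population prevalence. The scenario contrast
100·(PF_low − PF_high)/PF_high is scale-invariant arithmetic on the two
scenario percentages. The "SNP-scale" odds ratio min-max rescales the
score over its attainable range [0, 3.25] (a pure reparameterisation:
the normalised coefficient equals the raw coefficient times the range) and
fits the genotype-positive subcohort with a sex covariate.

## The β-cell destruction model

State variables: β-cell mass B (normalised to B(0) = 1), islet-autoreactive
conventional T cells E, regulatory T cells R:

    dB/dt = −κ·E·B/(1 + q·R)
    dE/dt = σ_E + ρ_E·E·B/(s+B)·g − δ_E·E
    dR/dt = σ_R + ρ_R·R·B/(s+B)·g − δ_R·R

with g = 1 (model 1) or g = 1 − (E+R)/K (model 2, shared carrying
capacity K = 10); model 1 is the K → ∞ limit of model 2, verified
numerically. Tconvs kill β-cells, Tregs suppress killing, antigen (B)
drives proliferation of both with half-saturation s = 0.3. Initial T-cell
levels are the source/death homeostasis σ/δ. The functional-iKIR effect
is longer T-cell survival: the "high" arm multiplies both death rates by
(1 − ε), ε = 0.35. An individual develops T1D when B(t_end)/B(0) < θ with
θ = 0.1 and t_end = 25 (arbitrary time units); the outcome classification
necessarily depends on θ, so all defaults are versioned in code.

In-silico cohorts sample each parameter log-uniformly from default ranges
(κ ∈ [2, 20], σ_E, σ_R ∈ [0.02, 0.3], ρ_E ∈ [0.2, 1], ρ_R ∈ [1, 6],
δ_E, δ_R ∈ [0.2, 1], q ∈ [0.5, 3]); each parameter draw is simulated in
both arms (LSODA, rtol 1e-7). High Treg supply σ_R with ρ_R ≫ δ_R is the
proxy for a protective class II genotype: it drives Tregs toward the
capacity ceiling. The ranges were calibrated by simulation so that the
mechanism of interest is exhibited robustly at the cohort sizes used:

* individuals with weak regulation progress to T1D in both arms
  (strong killing, κ floor at 2), so the low-Treg bins carry no arm
  contrast;
* strongly regulated individuals below capacity gain survival in *both*
  compartments, with near-cancelling effect on killing (model 1 is flat);
* in model 2, individuals whose Tregs saturate at the ceiling cannot
  convert extra survival into more regulation, while Tconvs (kept
  subcritical by the same ceiling) scale up by 1/(1−ε) — these
  individuals concentrate the arm-dependent outcomes in the top Treg
  bins.

Treg and Tconv turnover parameters are sampled independently; if the two
compartments shared identical rates the ratio E/R would be pinned at
σ_E/σ_R and the saturation asymmetry would vanish — a structural
observation worth recording. Binned contrasts use quantile bins of the
mean Treg level with Haldane-corrected log-odds differences; empty or
degenerate bins are reported as NaN, never dropped. The trend statistic is
the Spearman correlation of the per-bin contrast against bin index.

## Problem sizes and numerical conventions

Replicate studies in the test suite and acceptance script use cohorts of
n = 2,000–4,000, 200 replicates for calibration/coverage, 50 for the
driver screen, 2,000 permutations per test, and 1,000–2,000 paired ODE
simulations per model — sizes at which every Monte-Carlo check has
comfortable resolution while the whole suite runs on one CPU in minutes.
Tolerances: logistic-vs-closed-form agreement asserted at ≥6 significant
digits; ODE closed-form limits at 1e-6 relative; Wald CI coverage judged
against the binomial band [0.93, 0.97] at 200 replicates.

## Known limitations

The weight table and ligand lists are plausible defaults, not measured
affinities; peptide-dependent binding is out of scope. The generator's LD
model is multiplicative at the haplotype level and cannot represent
recombination gradients. The driver screen is pairwise, as in the source
procedure — a genotype masked only by a *combination* of partners would
survive it. The prevented-fraction formula is the simple counterfactual
form; sophisticated attributable-fraction estimators exist. The ODE model
is a deliberately minimal stand-in whose parameter ranges were chosen for
qualitative mechanism demonstration, not fitted to patient data.
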