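# Methods

This package is a self-contained simulation laboratory for a question from
dairy-cattle genetic evaluation: when a population has been under genomic
selection (GS) for years, which statistical model and which slice of the
phenotype history still give unbiased estimates of the base-population
variance components?  Everything is simulated, so the "true" genetic
variance of any cohort is known exactly and estimation bias is measurable.

## The simulated breeding program

**Historical phase.**  A discrete-generation Wright–Fisher population
builds linkage disequilibrium before the pedigree begins.  Loci (markers
and QTL pools, uniformly spaced on each chromosome) start at an
intermediate allele frequency (default 0.5) and evolve under drift,
recurrent symmetric mutation (2.5 × 10⁻⁵ per locus per meiosis — applied in
this phase only), and Haldane recombination: per chromosome the crossover
count is Poisson with mean equal to the map length in Morgans, crossover
positions uniform, no interference.  The default scaled burn-in (Ne = 100,
200 generations) leaves roughly half the loci segregating with a U-shaped
frequency spectrum and material short-range LD; adjacent-marker r² is an
order of magnitude above the long-range background.  The historical
effective size and the initial state are not constrained by the study this
reproduces; both are configuration.

**Panel and trait.**  A marker panel and a QTL set are drawn uniformly
without replacement from the segregating loci.  QTL effects are drawn
standard normal and rescaled by a single constant so that the variance of
true breeding values (TBV) among the *founders* of the pedigree equals the
configured base genetic variance exactly (default 3.59 trait-units², with
residual 5.05, i.e. h² = 0.42).  This makes the P-base truth a configured
quantity rather than a random outcome, which is what permits
validation-by-truth.

**Conventional phase (default 10 scaled years; 20 at full scale).**  A herd
of `n_cows` is maintained; every cow calves once a year; 40 % of the herd
is replaced annually by two-year-old heifers chosen at random (the
published program's record counts imply a mean of ~2.5 lactations per cow,
and its dam path is not described as selected).  Each entering cow receives
one first-lactation record y = HYS + TBV + e with the herd–year–season
effect drawn once per class from N(0, 1) and e ~ N(0, 5.05).  Records per
HYS class (~8) are kept near the full-scale ratio by scaling the herd count
with the herd size.  Sires are young bulls truncation-selected on parent
average (PA) of BLUP breeding values from a pedigree evaluation refreshed
yearly with the true variances; selected bulls serve for up to four years.
The progeny-test lag is not modelled — selection information is PA in
either case, which is the ingredient that matters for the selection-bias
phenomenon.  At the end of the phase the selected (non-founder) bulls with
recorded daughters are the "proven bulls" and are genotyped; this matches
the published genotyped-bull count of one 50-bull cohort per year.

**GS phase (default 8 scaled years; 15 at full scale).**  Each year bull
and heifer calves are pre-selected on PA for genotyping (scaled quotas 20
and 60 per year), a single-step GBLUP evaluation with the current genotype
set ranks the genotyped bull calves, and the top bulls (scaled: 4) enter
service.  Evaluations during the scheme use the true variances and P-base
allele frequencies; the evaluation variance components are configurable.

**Truth cohorts.**  P-base = the founders (variance fixed at 3.59); G-base
= animals born in the last three conventional years; the final-cohort truth
is the variance of TBVs among animals born in the last GS year.  All
haplotypes are retained, so allele frequencies of any cohort are available
even for animals the program never genotyped.

## Estimation machinery

**Relationships.**  Sparse A⁻¹ by Henderson's rules with inbreeding from a
Meuwissen–Luo-style gene-flow recursion; a dense tabular A as an
independent O(n²) oracle; VanRaden's G = ZZ′/Σ2pⱼ(1−pⱼ) with covariates
centred on a configurable base cohort's frequencies; H⁻¹ = A⁻¹ +
[[0,0],[0,Gb⁻¹−A₂₂⁻¹]].  G is blended as Gb = 0.95 G + 0.05 A₂₂ by default
(weight configurable, 0 allowed) — standard single-step practice that keeps
Gb invertible for any genotyped-set size; disclosed because it perturbs the
H construction slightly.  The counted allele is allele 1 of the simulator
throughout.

**REML (P-AM and ssGBLUP).**  AI-REML on the marginal covariance of the
recorded animals, V = K_rr σg² + I σe², where K_rr is the A- or
H-submatrix of the phenotyped animals obtained by sparse solves (animals
without records marginalize out of the restricted likelihood exactly, so
this equals MME-based REML while keeping the average-information trace
terms dense and exact).  Updates are Newton steps on the AI matrix with an
EM-REML fallback whenever a step proposes a non-positive variance, and
step-halving so the restricted likelihood never decreases across accepted
iterates.  Convergence: relative parameter change < 10⁻⁸, at most 200
rounds; start values are half the phenotypic variance each; standard errors
come from the inverse AI matrix.  Fixed effects use cell-means coding of
the observed HYS classes (full rank without an explicit constraint).  The
sparse MME route (`assemble_mme`/`solve_blup`) is used for the in-scheme
BLUP/GEBV evaluations.

**ssBR (single-step Bayesian regression, BayesC with π = 0).**  Marker
covariates of non-genotyped animals are imputed as M₁ = A₁₂A₂₂⁻¹M₂ via the
block-inverse identity (only the sparse (1,1) block of A⁻¹ is factorized);
the imputation residual ε has covariance (A₁₁−A₁₂A₂₂⁻¹A₂₁)σ²_ε, whose
inverse is exactly that sparse block, so ε is Gibbs-updated single-site
from its sparse-precision full conditional — no dense covariance is ever
formed.  The unknown mean of the genotyped group is carried by the imputed
covariate J = [A₁₂A₂₂⁻¹1; 1] with a flat prior (an indicator version
degenerates to an all-zero column when no phenotyped animal is genotyped,
which is precisely the conventional-phase-only analysis).  Markers get
systematic-scan single-site updates with residual bookkeeping; variances
get scaled-inverse-χ² draws with the published hyperparameters (S²_α =
0.0002, S²_ε = 2, S²_e = 2.5, ν = 4).  Chains start at data-scale values
(half the phenotypic variance per genetic route) rather than at the prior
scales — starting σ²_α at 2 × 10⁻⁴ leaves the sampler in a near-absorbing
small-variance region for a long time at desk scale.  Scaled chains are
10,000 iterations with 4,000 burn-in (full scale: 50,000/20,000);
convergence is monitored by batch-means Monte Carlo error.  Two genetic
variances are reported: σ²_ε (total) and σ²_α·Σ2pⱼ(1−pⱼ) (marker-based);
heritability uses the total route.  The sampler was validated against an
independent dense-REML maximization of the same three-variance model on
model-generated data, and against AI-REML when markers are absent.

**Scenarios.**  pheno1 = conventional-phase records analysed as the
end-of-phase snapshot (pedigree truncated there; proven-bull genotypes
only; P-base frequencies); pheno12 = all records, full pedigree, all
genotypes, P-base frequencies; pheno2 = GS-phase records, full pedigree,
all genotypes, G-base frequencies.  Significance against the simulated
truth uses a paired two-sided t-test across replicates (df = replicates−1)
with stars at P < 0.01/0.005/0.001; pheno2 estimates are compared against
the G-base truth, the other windows against P-base.

## Problem sizes

The bundled experiment uses the `mini_scale` preset: 3 chromosomes × 100
cM, 600-marker/150-QTL panel, 250-cow herd, 100 records per year, 4 young
bulls per year, GS quotas 20 + 60 with the top 4 by GEBV, 10 + 8 years, 5
replicates.  Proportions selected on the sire path, the genotyped fraction
of the pedigree in the conventional phase (~1 %), and records per HYS class
track the full program so that the selection intensities driving the
variance erosion are preserved.  A `desk_scale` (1/10) and the full
`full_scale` preset are provided; all routines accept any of them.  One
mini replicate (simulation plus the full model × scenario grid) runs in
about a minute on one CPU.

## What the generator does and does not emulate

It emulates: LD from finite-population burn-in, Mendelian inheritance with
recombination, truncation selection on PA and on GEBV, overlapping cow
generations, contemporary-group fixed effects, selective genotyping, and
the two-base-population structure.  It does not emulate: genotyping errors,
non-additive QTL action, sex chromosomes, variable recombination maps,
economic indices or multi-trait selection, embryo transfer, or
heterogeneous residual variances.  Passing tests therefore demonstrate the
statistical phenomenon (which data windows and relationship matrices give
unbiased variance components under selection), not the absolute magnitudes
one would estimate from field data.

## Numerical choices and degenerate inputs

Empirical variances use the n−1 denominator; a cohort of one animal is an
error.  Truncation selection breaks ties randomly.  A blended G that is
still singular raises with advice to increase the blend weight.  REML
variances are floored at 10⁻⁸ of the phenotypic variance; a zero-signal
response drives the genetic variance to that boundary.  The Gibbs sampler
raises if any conditional variance becomes non-finite, naming the
iteration.  Seeded runs are bit-reproducible; every stochastic routine
takes an explicit seed and the orchestrator derives per-replicate seeds
from one master seed via `numpy.random.SeedSequence`.

## Known limitations at reduced scale

The qualitative full-scale patterns that depend on *many* selected
genotyped bulls weaken as the genotyped cohort shrinks.  In particular the
single-step GBLUP downward bias with conventional-phase data, which at full
scale rests on ~1,050 strongly selected genotyped bulls and about four
generations of selection-driven allele-frequency change, is muted at mini
scale (~40 proven bulls, ~2 generations): the sign of the deviation is
unstable across 5 replicates and its magnitude is within replicate noise.
The imputation-residual (total genetic) variance of ssBR in the pheno1
window is likewise noisier than at full scale because a 600-marker panel
fitted to ~40 genotyped sires trades variance between the marker and
residual routes more freely than a 40k panel fitted to 1,050.  Both effects
are properties of the scale, not of the estimators, and both shrink as the
preset grows toward `desk_scale`.
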