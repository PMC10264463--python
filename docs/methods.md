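# Methods

## Population model

The simulator emulates an advanced-generation composite of two
random-mating founder populations, each in linkage equilibrium, with
locus-wise allele-frequency differences. F1 individuals receive one
haplotype drawn from each founder population; mating F1 pairs produces
the composite base — 5000 individuals in 100 full-sib families — whose
haplotype disequilibrium equals the closed form

    Δ_ab = ((1 − 2θ_ab)/4)(p¹_a − p²_a)(p¹_b − p²_b),

with θ_ab the recombination fraction (this is checked in the tests by
averaging signed D over replicate simulations). Five discrete
generations of random mating follow (random parent pairs drawn from the
whole composite; constant size; no mutation, selection, migration or
selfing). From the advanced generation, 20 disjoint parent pairs each
produce 50 full sibs: the N = 1000 analysis cohort. Smaller populations
are nested random subsets removing 100 individuals at a time, always 5
per family, so family proportions are exact at every step.

Meiosis follows Haldane's model: the inheritance indicator along a
chromosome is a two-state Markov chain whose switch probability between
consecutive loci is θ(d) = (1 − e^(−2d/100))/2 — exactly the marginal
law of a Poisson crossover process, so there is no interference.
Chromosomes assort independently. Phase is tracked internally; all
downstream analysis sees dosages {0, 1, 2} only.

### Genome geometry

Default: 10 chromosomes of 200 cM; 200 SNPs per chromosome on a 0.1 cM
grid. The three stated design figures (2000 SNPs, 0.1 cM spacing,
200 cM chromosomes) are mutually inconsistent — 2000 × 0.1 cM covers a
tenth of such a genome — and we resolve the conflict in favour of
marker density: markers cover the first 19.9 cM of each chromosome,
because sub-centimorgan LD windows can only be estimated from
sub-centimorgan marker spacing. Counts, spacing and lengths are all
config fields. The 100 QTLs are placed uniformly at random inside the
marker-covered region (uniformly among chromosomes, at inter-marker
positions), freshly per replicate.

### Founder allele frequencies

The founder frequency law is the one genuinely free parameter of the
design. The default draws one population from U(0.72, 0.95) and the
other from U(0.05, 0.28) at every locus, swapping roles with
probability ½ — i.e. strongly divergent founders, as in a cross of
improved × unimproved germplasm. The divergence level was fixed once so
that the composite reproduces the LD regime the study design describes:
a decay curve starting just above the critical r² = 0.20 and crossing
it near 1 cM at N = 1000. Weaker divergence (e.g. both populations
i.i.d. U(0.05, 0.95), available as `{"name": "uniform"}`) leaves mean
short-range r² near 0.03 and the window calibration undefined — the
decay curve never reaches 0.20. Because the curve meets the threshold
at a shallow angle, the fitted window varies visibly between seeds
(roughly 0.6–1.1 cM at N = 1000); this is a property of the design, not
an estimation artefact.

## Trait model

Effects for the 100 QTLs are i.i.d. N(0, 1). Under `major3_plus97`,
three QTLs (drawn at random among polymorphic ones) are rescaled by the
positive root λ of ½λ²v_M − λc − ½v_m = 0 (v_M, v_m, c the realized
variances/covariance of the major and minor genetic components), making
the majors' realized share of genetic variance exactly ½ in the cohort,
LD covariance included. Genotypic values are additive, g = Xβ;
environmental noise is N(0, σ²_e) with σ²_e = var(g)(1 − h²)/h², so the
broad-sense heritability is exact by construction (and equals the
narrow-sense one — no dominance or epistasis). Effects are redrawn every
replicate.

## LD windows

r² is the squared Pearson correlation of dosage columns, computed for
all same-chromosome marker pairs (~199 000 by default; monomorphic
markers are skipped and counted). A local polynomial regression of r²
on distance — tricube weights, span 0.75 (as a fraction of the pair
mass), degree 2, the classical LOESS defaults — is fitted after
aggregating pairs by distinct distance (exact for locally weighted
least squares, since the weight depends only on the distance value).
statsmodels' lowess is degree-1 only, so the smoother is implemented
here. The detection window w is the smallest distance where the fitted
curve crosses r² = 0.20 (dense grid + bisection); if the curve never
reaches the threshold an explicit error is raised. Markers within w of
a target QTL are "associated"; target QTLs are the 3 major genes under
`major3_plus97` and all 100 under `infinitesimal_100`. The window is
recomputed per replicate and per population size.

## Structure correction

G is the VanRaden relationship matrix from frequency-centred dosages.
Covariates are the top-K eigenvectors of G scaled by √eigenvalue, with
each eigenvector's largest-magnitude entry made positive for
reproducibility. K defaults to 19 (3-QTL configuration) and 18
(100-QTL), the component counts the study adopted from its ΔK cluster
analysis, which is out of scope here; `select_k` offers an ≥85 %
variance rule instead. Reported variance-explained follows the PCA *of
the relationship matrix*: G is doubly centred, so the principal
components of G-as-data share G's eigenvectors with component variances
λ², and the share of the first K components is Σλ²_k / Σλ²_j (≈ 94 %
for K = 19 on the default cohort). Plain eigenvalue shares Σλ_k/Σλ_j
are also reported (≈ 58 % — full-sib relatedness of ½ caps the
between-family share near one half); only the λ² definition can produce
the 85–96 % range quoted for 20-full-sib-family designs.

## Association scans

One model per marker: intercept + marker dosage (additive 0/1/2, no
standardisation, so α̂_j is per-allele) + K structure PCs. Markers
monomorphic in the current (possibly downsampled) population are
excluded from testing, from the FDR family and from power/FPR
bookkeeping, and are listed with a reason.

**GLM.** OLS via Frisch–Waugh residualisation on the covariate design —
numerically identical (coefficients, usual standard errors, t p-values,
df = N − K − 2) to the per-marker full OLS fit, verified against
statsmodels marker-by-marker in the tests.

**QR.** The check-loss problem is solved as the standard primal LP
(split positive/negative residuals) with HiGHS, objective tolerance
1e−8; ties among optimal bases are accepted — tests compare objectives,
not coefficients. Significance uses the regression rank-score (score)
test: the covariate-only τ-fit's LP duals are exactly the rank scores
b_i = τ − 1{ε̂_i < 0} (values in (τ−1, τ) on basic observations),
orthogonal to the covariate design by LP optimality; for marker j,
T_j = x̃_j′b / √(τ(1−τ)·x̃_j′x̃_j) with x̃_j the residualised marker, is
referred to N(0, 1), two-sided. Only the covariate model is fitted per
(dataset, τ), so a 2000-marker scan costs one LP plus matrix products.
Per-marker QR effect estimates need one LP each and are opt-in
(`effects="significant"` refits only FDR-passing markers).

**Multiple testing.** Benjamini–Hochberg adjusted p-values by default;
Storey's π₀-estimated variant (λ = 0.5) as an option. Significance is
q ≤ α = 0.01 throughout.

## Evaluation

Power = fraction of target-QTL windows containing ≥ 1 significant
marker; FPR = significant non-associated markers / all tested
non-associated markers. Under `major3_plus97` only the three major-gene
windows are targets; markers near the 97 minor loci count as
non-associated (an interpretation: the study's detection targets in
that architecture are the major genes, as its ⅓-granular power values
imply). Each scenario (architecture × h² × size) runs 10 replicates by
default, each a fresh end-to-end simulation; replicate r uses the r-th
child of `SeedSequence(master_seed)`, so results are bitwise independent
of execution order and trivially parallelisable. Aggregates are mean ±
SE (sample SD/√R).

## What the simulation does and does not show

Passing tests show the pipeline's behaviour on idealised populations:
purely additive traits, Gaussian noise, equal family sizes, a uniform
marker grid, founder divergence chosen to match the described LD
regime. Real data add allele-frequency spectra, missing genotypes,
genotyping error, non-additive variation and uneven relatedness, none
of which are modelled.

Two published patterns reproduce quantitatively: the GLM's power
collapse with shrinking N and low h², and the ~1 cM detection windows
with their slight widening as N falls (here the widening is weak —
proportional family downsampling keeps the number of independent
lineages, hence the null r² floor, nearly constant). One pattern does
**not** reproduce: quantile-regression scans with calibrated rank-score
inference call far fewer markers than the study reports (its QR power
of 1.00 with a false-positive rate of 0.35 implies a p-value inflation
that neither the rank-score test, nor t-tests built from rank-inversion
confidence intervals, nor uncorrected QR scans produce on populations
matching the stated design — we checked all three). The package
therefore shows QR as a *validly calibrated* competitor, which on these
family-structured samples is more conservative than OLS, not less.

## Numerical choices and degenerate inputs

LP ties: any optimal vertex accepted. Rank-score variance guard: a
marker whose residual sum of squares after covariate projection is
below 1e−10·n is reported as collinear. LOESS neighbourhoods always
contain ≥ degree + 1 distinct distances; a zero-bandwidth neighbourhood
falls back to the weighted mean. Window search starts from the smallest
observed distance; curves already below threshold raise. Eigenvalues of
G are clipped at 0 for variance shares. σ²_e = 0 is allowed (noise-free
phenotypes); h² ∈ {0, 1} is not. Downsampling requires the target to
split equally across families. All stage seeds are spawned from one
master seed per replicate.

## Problem sizes used in the checks

Acceptance-style checks run at the study's full population sizes
(N = 1000 cohorts, 2000 markers) with replicate counts of 3–10; the
scenario grid and unit tests use reduced geometries (2 chromosomes,
hundreds of individuals) chosen to keep the full suite in a few
minutes while preserving every code path.
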