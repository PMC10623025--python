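# Methods

## Model

All estimation is built on the linear mixed model for t traits observed on n
cows from a pedigree of q animals,

    y = Xβ + Zu + e,   u ~ N(0, G0 ⊗ A),   e ~ N(0, R0 ⊗ I_n),

where G0 (t×t) is the additive-genetic covariance, R0 (t×t) the residual
covariance, and A the numerator relationship matrix. Fixed effects are
five-year period classes of calving (or of birth, for AFC), four
agro-climatic season classes (summer Apr–Jun, rainy Jul–Sep, autumn Oct–Nov,
winter Dec–Mar), and a linear age-at-first-calving covariate for every trait
except AFC itself. Heritability is h² = σ²_g/(σ²_g+σ²_e) per trait; genetic
correlations come from G0 and phenotypic correlations from P0 = G0 + R0.

## Pedigree machinery

`renumber_pedigree` topologically orders animals (Kahn's algorithm, ties
broken by first appearance, so output is deterministic), adds parent-only
animals as founders, and rejects cycles and identifiers used as both sire and
dam. A is built by the tabular method; A⁻¹ directly by Henderson's rules with
δ_i = 1/(0.5 − 0.25(F_s + F_d)) when inbreeding is accounted (default; F from
the tabular pass) or the classical δ ∈ {2, 4/3, 1} otherwise. Unknown parents
are treated as unrelated base-population animals; no unknown-parent groups.
Tests verify A⁻¹ against the dense inverse at 1e−8 on random pedigrees.

## Frequentist track

Fixed-effect inference uses ordinary least squares on the full-rank design
(set-to-zero constraint on each factor's last level; covariate centred).
Reported least-squares means are population-marginal means (equal weight over
the other factors' levels, covariate at its mean) and are invariant to the
constraint choice — verified by a relabelling test. Each term gets a partial
F-test against the full-model residual; significance codes are *** p<0.01,
** p<0.05, * otherwise.

Sire and residual (co)variance components use Henderson Method III: σ²_e from
the full-model residual mean square; σ²_s from the fitting-constants
reduction R(sire | fixed) = y'(P_W − P_X)y with expectation
df·σ²_e + c·σ²_s, c = tr(Z'(P_W − P_X)Z). Everything is computed through QR
bases of X and [X Z] rather than explicit projection matrices. Negative sire
variances are truncated at zero with a flag; the raw value is retained.
Cross-trait sire/residual covariances use the same quadratic forms as
bilinear forms on common records. Heritability is the paternal half-sib
estimator h² = 4t with Swiger's large-sample SE

    Var(t) = 2(N−1)(1−t)²[1+(k−1)t]² / [k²(N−s)(s−1)],

k the effective progeny-group size (N − Σn_i²/N)/(s−1). Genetic correlations
divide sire covariances by the geometric mean of sire variances; cells with a
zero sire variance are reported NA with a reason rather than raising.
Robertson's approximation supplies the r_g standard error.

## Bayesian track

The Gibbs sampler updates, per cycle:

1. every fixed-effect coefficient from its scalar normal full conditional
   (Gauss–Seidel over the mixed-model equations, residuals updated in place);
2. every animal's t-vector of breeding values from its multivariate normal
   full conditional, animal by animal, using the sparse row of A⁻¹
   (single-site sampling; block updates are out of scope);
3. G0 ~ inverse-Wishart(S_g + U'A⁻¹U, ν_g + q);
4. R0 ~ inverse-Wishart(S_r + E'E, ν_r + n).

Draws after the burn-in are stored every `thinning` cycles; the stored count
is floor((total − burn_in)/thinning) — the default 30,000/1,000/10 stores
2,900. All randomness flows from one `numpy` Generator seed, so chains are
bit-reproducible. The location sweep is numba-compiled with an
arithmetically identical pure-NumPy fallback. An overflow guard aborts if any
sampled variance exceeds 10¹² times its starting value.

Priors default to a weakly informative inverse-Wishart with ν = t+2 and scale
(ν − t − 1)·diag(half the observed phenotypic variances), i.e. centred on the
"half-and-half" split of the observed variance; starting values are
G0 = R0 = half the phenotypic covariance. A flat-prior mode exists but warns,
since posterior propriety is not guaranteed on small data. Trait sets are
complete-case; there is no missing-trait augmentation. A common fixed design
is shared across the traits of a run with a per-trait column mask, so a
response never adjusts for its own covariate (the `AFC_cov` column is
recognised as an alias of the AFC trait).

Inverse-Wishart draws delegate to `scipy.stats.invwishart`
(mean scale/(ν−t−1)), checked by moment tests.

### Post-Gibbs summaries

Per scalar chain: mean and median are standard; the mode is the midpoint of
the modal bin of a Freedman–Diaconis histogram (binning choice documented
here because the posterior mode has no canonical sample estimator; for
near-symmetric chains it tracks the median closely). SD uses N−1. The 95%
HPD interval is the shortest window of ⌈0.95N⌉ consecutive order statistics,
ties resolved to the lowest lower bound — tested against a brute-force scan.
ESS uses the Geyer initial-monotone-sequence truncation of the
autocorrelation sum (FFT autocovariances, paired lag sums, stopped at the
first non-positive pair, forced monotone), capped at N; MCE = SD/√ESS by
construction. The Geweke diagnostic compares the first 10% and last 50%
window means, z = Δmean/√(V̂_A + V̂_B).

The Geweke window variances use the same initial-sequence estimator as the
ESS (V̂ = s²/ESS per window) rather than disjoint batch means: on 1,000 iid
chains of length 1,000, batch means with ≈√n batches gave a ~7% empirical
false-positive rate at |z| > 1.96 (too few degrees of freedom in the short
10% window), while the initial-sequence variant is measured at ~4%, close to
nominal. The calibration is enforced by a test.

Derived parameters are computed draw-by-draw (h², r_g, r_p, σ²_p = σ²_g +
σ²_e exactly per draw); draws with a non-PD G0 or P0 are excluded with a
count. Note mean(h² chain) ≠ mean(σ²_g)/mean(σ²_p) in general; both are
available, and summary tables report the former.

## Sire evaluation

Henderson's MME are assembled with Kronecker structure (trait-major) and
solved densely for q ≤ 2,000, else by Jacobi-preconditioned conjugate
gradients (rtol 1e−10). The sire-model route treats sires as unrelated and
uses the half-sib variance ratio λ = (4−h²)/h², reporting EBV = 2× the sire
solution; the animal-model route uses A⁻¹ with G0/R0 (e.g. posterior means)
and reports the animal solutions directly. Only sires with more than three
progeny are ranked; EBV ties break by sire identifier for determinism.
Rankings are compared by the Spearman correlation (average ranks on ties)
with t = r√((n−2)/(1−r²)) on n−2 degrees of freedom, n the number of
evaluated sires; |r| = 1 reports an unbounded t with a "significant" verdict
rather than raising.

## Synthetic herd generator

`simulate_pedigree` crosses founder sires with a founder dam pool; each
generation mates every current dam to a random founder sire and the daughters
become the next dam pool (capped at the founder dam count). The default —
8 sires, 120 dams, 2 offspring per mating, 4 generations — yields ~960
recorded cows in eight half-sib families, matching the scale of the research
herd the defaults emulate. `simulate_phenotypes` draws founder breeding
values from N(0, G0), transmits u = ½(u_s+u_d) + m with Mendelian sampling
m ~ N(0, ½G0) (inbreeding ignored in the simulation variance; A-based tests
use the exact pedigree A), assigns birth/calving dates over the herd's
1986–2019 recording window and codes period/season from them, and builds
phenotypes as mean + period + season + slope·(AFC − AFC̄) + u + e. True
breeding values are attached to every record.

Default trait means and SDs are the published herd descriptives (e.g. AFC
1,227.73 ± 179.45 d); default G0/R0 are assembled from the published
heritabilities and genetic/phenotypic correlation matrices. The printed
seven-trait correlation tables are not jointly positive definite, so the
defaults pass through a minimum-eigenvalue repair (floor 1e−6 of the largest
eigenvalue) — any trait subset is therefore usable. Fixed-effect magnitudes
default to 0.15 (period) and 0.10 (season) phenotypic SDs and the covariate
slopes to 0.05 SD per SD of AFC: visible but not dominant non-genetic
structure, as in a managed research herd.

What the generator does **not** emulate: non-Gaussian trait distributions
(real FSP is right-skewed and non-negative; Gaussian simulation can produce
negative values at CV ≈ 64%), selection and non-random mating, culling-driven
missingness, heterogeneous variances across periods, and records on male or
founder animals. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to these real-data
features.

## Numerical choices and problem sizes

* A⁻¹ vs dense-inverse agreement asserted at 1e−8 max-abs, pedigrees q ≤ 50.
* MME solves: dense for q ≤ 2,000; CG tolerance 1e−10.
* Fixed-variance Gibbs validation: 20,000 cycles on a ~50-record herd; the
  post-burn-in location mean is required within 1% of the MME solution's
  largest component (measured ~0.4%).
* Posterior recovery study: bivariate, truth h² = 0.5 and r_g = 0.6,
  ~500-animal pedigrees with ~380 records, chains 6,000/500/5, 20
  replicates; the truth must fall in the 95% HPD in ≥ 90% of the pooled
  parameter checks. These sizes keep a full run in the low minutes on one
  CPU while leaving enough information for h² to be identified.
* Calibration suites: 1,000 chains for the Geweke rate; AR(1) ρ = 0.9 with
  N = 20,000 for the ESS ratio against (1−ρ)/(1+ρ); 1,000 null replicates
  (n = 200) for the F-test type-I error; 200 replicates of 200 sires × 20
  progeny for half-sib recovery.

## Known limitations

* Single-site location sampling mixes slowly when fixed effects and the
  genetic mean are near-confounded; intercept-like components carry most of
  the Monte-Carlo error.
* Method III can produce negative sire variances (truncated, flagged) and
  out-of-range correlations (clipped, logged) on small sire samples.
* The histogram mode estimator is sensitive to binning for small stored
  samples; prefer the median or mean below ~100 draws.
* No maternal effects, unknown-parent groups, genomic relationships, or
  missing-trait augmentation.
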