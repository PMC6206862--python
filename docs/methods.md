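# Methods

This note records the statistical models, the conventions chosen where the
methodology is genuinely open, and what the synthetic-data generator does
and does not emulate.

## Line × Tester decomposition

For a balanced design of *l* lines × *t* testers with cross means x̄_ij:

    μ = mean(x̄),  g_i = x̄_i· − μ,  g_j = x̄_·j − μ,
    s_ij = x̄_ij − x̄_i· − x̄_·j + μ

so that μ + g_i + g_j + s_ij reconstructs every cross mean exactly and all
GCA/SCA vectors sum to zero — these identities are asserted to 1e-8 in the
tests. With replicated data, every location × year × replicate combination
is treated as one replication block of the crosses trial; the ANOVA
partitions SS(crosses) exactly into lines + testers + line×tester. Lines
and testers are F-tested against the L×T mean square, crosses and L×T
against error (the classical L×T convention). Variance components:

    σ²_sca = (MS_L×T − MS_error) / r
    σ²_gca = ½ [ (MS_lines − MS_L×T)/(r·t) + (MS_testers − MS_L×T)/(r·l) ]

Negative estimates are clamped to zero and logged. A single tester leaves
the testers stratum undefined and is rejected.

## Heterosis

Five statistics per cross × trait. MP, HB and HI use overall entry means
of the F1 and its parents; standard heterosis (K3/K4) forms the ratio
100·(F1 − check)/check within each location × year and then averages, so
genotype × environment variation in the check does not contaminate the
statistic. HI is defined as 100·F1/MPV (the common textbook form; the
definition is configurable in spirit — it lives in one function). "Better
parent" follows a per-trait direction table: higher is better for all
traits except micronaire. Zero denominators and missing parents yield NaN
with a warning, never an exception.

## Entry means

Association phenotypes default to shrunk entry means: the raw mean per
individual is pulled toward the grand mean with weight
σ²_g/(σ²_g + σ²_res/n_i), components estimated from a one-way
random-effects decomposition per trait. With zero residual variance the
weight is 1 (shrunk = raw); with zero genetic variance everything
collapses to the grand mean, which is the correct degenerate behaviour.
Raw means remain available via `mode="raw"`.

## RCBD ANOVA, correlations, PCA

The per-environment RCBD ANOVA is fitted through statsmodels
(`value ~ C(individual) + C(replicate)`, type-I partition — exact for the
balanced layouts the design produces); the test suite checks it against an
independent direct sums-of-squares oracle. Quartiles use linear
interpolation (type-7). PCA operates on the trait correlation matrix of
complete-case entry means; constant traits are excluded with a warning;
each component's sign is fixed so its largest-magnitude loading is
positive; eigenvalues sum to the number of traits by construction.

## Admixture model

Bands are modelled as haploid 0/1 loci (one allele draw per individual per
band): the single-row dominant coding carries no genotype/phase
information, so a diploid likelihood is not reconstructible. The Gibbs
sampler alternates (z | q, p), (p | z) with a correlated-frequency Beta
prior centred on the empirical ancestral frequency with drift F = 0.05,
and (q | z) with a symmetric Dirichlet(α = 1) prior (α fixed, not
inferred). LnP(D) is mean(ln L) − ½·var(ln L) over retained sweeps. Chain
lengths default to 100,000 + 100,000; the tests, examples and acceptance
script run chains of a few hundred sweeps, which the diagnostic fixtures
(strongly differentiated subpopulations) mix quickly enough for. ΔK pairs
replicate runs by index: ΔK(K) = mean_j |LnPD_j(K+1) − 2·LnPD_j(K) +
LnPD_j(K−1)| / SD_j(LnPD(K)); with no defined peak (e.g. exactly linear
LnPD) selection falls back to the smallest K and says so. Assignment
requires membership strictly above 0.5, else "admixed". Cluster labels are
exchangeable; all structure tests compare up to label permutation.

## Linkage disequilibrium

Band pairs are scored as haploid 2×2 tables on the locus pair's
complete-case submatrix (pairs with fewer than 4 complete observations are
skipped, not imputed). Locus-level r² and D′ are weighted averages over
polymorphic band pairs with weights proportional to the product of
marginal band frequencies, normalised. The permutation test shuffles one
locus's individual labels; ties between permuted and observed r² are
counted half (mid-p): band data make the permutation distribution heavily
discrete, and the conservative all-ties count would push the null p
distribution visibly away from uniform. Background LD is the
linearly-interpolated 99th percentile of unlinked r². The decay fit
regresses r² on ln(distance), replacing zero distances with 1e-7 first;
the decay distance solves intercept + slope·ln(d) = threshold (default
r² = 0.2) and is undefined (NaN, logged) for non-negative slopes.
Distances are bp internally, reported in kb/Mbp at the interfaces.

## Kinship and the mixed model

Kinship is simple-matching similarity over bands observed in both
individuals, rescaled so the least-similar pair anchors zero — a
defensible choice for dominant band data, where allele-sharing estimators
requiring genotypes are unavailable. Non-PSD results (rare) receive a
1e-6 ridge, logged. The association model is the standard Q+K mixed
model; REML uses one eigendecomposition of K and a bounded Brent search
over log₁₀ δ ∈ [−5, 5] with δ = σ²_e/σ²_g, also evaluating the
boundaries. Variance components are estimated once per phenotype vector
and held fixed across bands (P3D); each band enters as a fixed effect and
is F-tested by generalized least squares. Missing band entries are
mean-imputed per band for the test so the panel-level eigendecomposition
stays valid; marker r² is the fractional reduction in generalized
residual sum of squares. With K = I and no Q the whole machinery reduces
to OLS exactly — asserted to 1e-6 in the tests. Q covariates drop their
last column against intercept collinearity; collinear fixed effects are
dropped with a log message.

## The 32 combinations and post-scan rules

The scan enumerates the L×T association layout: maternal-line genotypes
against each tester's F1 phenotypes (5), each F1 family against itself
(5), parents against themselves (1); GCA as phenotype on the parents (1)
and on each F1 family via the maternal line (5); SCA per family (5); and
the five heterosis statistics on maternal-line genotypes (5) and F1
genotypes (5) — 32 combinations, with each heterosis combination
carrying MP/HB/HI/K3/K4 as separate scans. Marker-level significance is
the minimum band p (bands are the tested alleles). No multiple-testing
correction is applied beyond the fixed −log₁₀ p > 3 threshold — that is
the operating convention of this analysis style. The stable-QTL rule
requires support from ≥ 3 distinct testers; the supporting-variable
whitelist defaults to all eight dependent variables, with a narrower
five-variable preset ({phenotype, GCA, HB, MP, K4}) available, since both
conventions appear in practice. Effect typing: GCA support ⇒ additive,
SCA/heterosis support ⇒ dominance, both ⇒ both; phenotype-only support is
typed "both" with a low-confidence flag. Allele effects are computed per
genotype/phenotype combination (not pooled), so a_i for a heterosis
variable is on that percentage scale.

## Synthetic data

The generator emulates the target study system: 284 lines × 5 testers by
default, 203 multi-band SSRs uniformly over 26 chromosomes, three latent
subpopulations under a correlated-frequency model with Dirichlet
admixture, an RCBD with 3 replications, and two check cultivars grown in
every environment. The default environment layout is 2 locations × 2
years (the scale at which such trials are typically summarised); trait
means and residual SDs default to values typical of Chinese upland-cotton
trials. Tests, examples and the acceptance script use an explicit
desk-scale preset (`demo_config`: 60 lines, 30 markers, 2 environments)
so every stage runs in seconds to minutes.

Genetic values use a dominant-band a/d coding: a carrier parent
contributes 2a, an F1 contributes 2a/a+d/0 for two/one/zero carrier
parents — the minimal coding under which GCA responds to a and mid-parent
heterosis to d. An additive polygenic background (per-parent N(0, σ_poly)
with F1 = parental average; σ_poly defaults to one residual SD) keeps
every trait heritable without contributing heterosis. Environment effects
are drawn once per location × year and shared across genotypes; blocks
are nested in environments.

What the generator does **not** emulate: physical linkage (marker band
frequencies are independent, so LD decay with distance is absent from
simulated panels and the decay fit correctly reports "no significant
linked pairs" there — decay correctness is verified against closed-form
curves instead); segregating generations beyond F1; genotyping error
models beyond a uniform missing rate; selection or pedigree structure
among the lines. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted architectures, not
calibration against any particular real panel.

In recovery experiments the causal band is chosen at intermediate
frequency (0.3–0.7) on the simulated panel: power against a
nearly-monomorphic band is a different question from the one those
experiments ask.

## Numerical conventions

Determinism everywhere: all generators take explicit seeds; the pipeline
derives per-stage seeds from one master seed by hashing, and re-running a
config reproduces result tables byte for byte. Thresholds are strict
where the operating rules are strict (significance −log₁₀ p > 3,
assignment Q > 0.5, rare-band frequency < 0.05). Degenerate inputs
(constant phenotypes, monomorphic bands, zero denominators, all-missing
columns) are skipped or NA'd with a logged message rather than raised,
except where the result would be meaningless (constant phenotype in REML,
no unlinked pairs for background LD, < 2 replicates for RCBD).

## Problem sizes

The shipped test suite and acceptance script use: random L×T tables up to
20 × 5; MLM-vs-OLS on 50 instances of n = 100 × 50 bands; a structured
null of ≥ 5000 band tests; additive recovery on 200 lines × 5 testers
(a = 0.5 residual SD, 12–20 seeded runs); dominance detection on 100
lines (d = 0.5 residual SD); structure recovery on 120 individuals × 90
diagnostic bands, K ∈ 1..6 × 5 runs, 5–8 master seeds; 500 random
association tables against the brute-force stable-QTL oracle. These sizes
are the package's chosen verification scale; all are configurable upward.
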