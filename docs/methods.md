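# Methods

## Model and statistic

For one bi-allelic SNP with N callable individuals, genotype calls are
collapsed to microstates m ∈ {+1, 0, −1} (A/A = T/T → +1, G/G = C/C → −1,
anything else non-missing → 0; the homozygote-ambiguous pairs A/T and G/C
fall under "otherwise" and encode as 0). Missing calls are removed per SNP
(pairwise deletion); they are never imputed to 0 because a spurious 0
flattens the path locally and biases the partition.

Individuals are ranked by ascending phenotypic residual (stable sort;
ties keep input order — the method's premise is that residuals are
measured precisely enough to be essentially unique, so ties are a
degenerate case, not a modelled one). The genetic path is the cumulative
sum θ(i) of the ranked microstates with the anchor θ(0) = 0, so
θ(N) = N₊ − N₋ for every arrangement. Under no association the ranking
carries no genotype information, and the expectation of θ(i) over
scrambles is exactly linear, θ₀(i) = i·(N₊−N₋)/N (exchangeability). All
inference uses Δθ(i) = θ(i) − θ₀(i), anchored to 0 at both ends.

The slope (N₊−N₋)/N is carried as an exact rational; extremum search uses
the integer sequence N·Δθ(i) = N·θ(i) − (N₊−N₋)·i, so extremum locations
and ties are exact. Float Δθ is used only for export/plotting.

## Permutation null

Scrambling the string (seeded Fisher–Yates) gives the null ensemble of
paths. Its per-position variance has the closed form of a
without-replacement partial sum,

Var θ₀(i) = i(N−i)/(N−1) · σ²_m,  σ²_m = (N₊+N₋)/N − ((N₊−N₋)/N)²,

which is symmetric in i ↔ N−i and, after normalizing sd by √N and
position by N, independent of sample size at fixed microstate
frequencies. The analytic form serves as the fast oracle; simulation
(default K = 1000 replicates) remains the ground-truth cross-check in the
tests (agreement to within Monte-Carlo error, ~√(2/K) relative per
position).

## Path probability and its calibration

The anchored difference attains a maximum Φ₁ ≥ 0 and minimum Φ₂ ≤ 0 over
positions 1..N; the first such positions (smallest-index tie rule) split
the string into blocks (0,i₁], (i₁,i₂], (i₂,N] — the extremum's
microstate belongs to the block it terminates, because the path value at
i is determined by microstates 1..i. Empty blocks are legal (extremum at
N, or coincident extrema on a flat path, which yields i_max = i_min = 1).
The path probability is p̂ = N₁N₂N₃/N⁰_path, the fraction of arrangements
sharing the observed per-block contents. All factorials are evaluated in
log-gamma space (N ≈ 565 overflows fixed-width integers); the linear-scale
p̂ is clamped at 10⁻³⁰⁰ while −log₁₀ p̂ stays exact. For N ≤ 8 an
independent brute-force oracle (integer factorials, exact fractions, its
own extremum search) enumerates every arrangement; the pipeline matches
it to double precision, and the hand case [+1,+1,−1,−1] gives exactly 1/6.

p̂ is **not** a uniform p-value: under the null at N = 565 its −log₁₀
concentrates around 4–5.5. The package therefore treats it as a score
with three calibrated readouts:

1. **Thresholds.** Null −log₁₀ p̂ samples are pooled across six theoretic
   count presets (N₊,N₀,N₋) = (25,25,515) … (25,525,15), K = 1000 each;
   the pooled 95th/99th percentiles (≈6.8 and ≈7.7) are the significance
   lines. Pooled (rather than per-SNP-averaged) quantiles were chosen for
   determinism and simplicity; per-preset distributions are exposed for
   inspection. The preset medians differ by less than the pooled IQR and
   the thresholds are stable under halving/doubling N at fixed
   frequencies, which is what justifies sharing them across SNPs at this
   cohort scale.
2. **BH on p̂** (`p_gift`): the step-up adjustment applied across all
   tested SNPs, delegated to statsmodels. Reported because it is the
   method's published convention; not interpretable as FDR control since
   the inputs are not uniform under the null.
3. **Per-SNP permutation p-value** (`p_emp`): scramble the SNP's own
   string K = 999 times and report (1 + #{null ≥ obs})/(K+1). This is a
   valid, super-uniform p-value conditioned on the SNP's counts, and BH
   applied to it does control FDR. Conditioning per SNP matters: the null
   tail of a balanced SNP (e.g. ≈(140,280,145)) is measurably heavier
   than the skewed presets' (99% null quantile ≈8.7 vs ≈7.7), so pooling
   the calibration null across presets would make empirical p-values
   anti-conservative for balanced SNPs.

Per-SNP randomness derives from the master seed and a CRC32 hash of the
SNP id, so results are independent of SNP order and reproducible.

## Baseline and QC

The conventional readouts are group means per microstate, the Falconer
parameterization a = (μ₊ − μ₋)/2 and d = μ₀ − (μ₊ + μ₋)/2 (an alternative
d = a − μ₀ reading of the same verbal definition is available behind
`dominance_convention="a_minus_mu0"`; both are reported as "N/A" when a
homozygote group is empty), a pooled-variance two-group t-test (Welch
selectable), and an OLS regression of residual on dosage as the GWAS
stand-in. The OLS baseline is deliberately plain — no kinship/mixed
model — so comparisons against published mixed-model p-values are
qualitative only.

Fixed effects (e.g. farm, sex) are removed by least squares on a one-hot
design, optionally after natural-log transform; the rank-deficient solver
makes collinear factor codings harmless, and the adjustment is
idempotent. QC follows the standard single-marker filters: MAF < 0.05,
missingness > 10%, Hardy–Weinberg exact-test p < 10⁻⁶ (full enumeration
of heterozygote counts given allele counts — exact, since stratified
counts can be small). LD pruning is a greedy positional scan per
chromosome at r² > 0.1 on microstate dosages; Bonferroni thresholds
−log₁₀(level/N_independent) are computed from the pruned count.

## Synthetic cohorts

The generators define the validation conditions; their defaults are the
study settings, not tuning knobs.

- **Fisher cohort** (constant allelic effect): n = 1000 individuals,
  Hardy–Weinberg genotype at allele frequency 0.8 (class frequencies
  0.64/0.32/0.04), phenotype mean 68, sd 2, gene effect a = phenotype sd,
  no dominance. Noise convention: each microstate group is normal with sd
  equal to the phenotype sd around its shifted mean (per-group normality),
  so the marginal sd slightly exceeds the nominal value by the genetic
  variance — the alternative (fixing total variance) is a documented
  switch away via explicit `phen_sd`/`a_true` arguments.
- **Theoretic SNPs**: uniform arrangements of the six fixed count presets
  above (pure null with N = 565).
- **Sign-flip cohort**: a latent subpopulation s = ±1 (equal probability)
  contributes s·(a + 4·noise_sd) as an offset — separating the low and
  high residual ranges — and reverses the allelic effect: phenotype =
  s·half_gap + s·a·m + noise, defaults n = 500, allele frequency 0.5,
  a = 3, noise sd 1. Homozygote group means coincide in expectation
  (mean-based tests stay at their type-I level) while the ranked path is
  sigmoid. This is a minimal concrete mechanism for scale-dependent
  ("non-linear phenotypic field") effects, chosen for phenomenology, not
  taken from a published generative equation.
- **Genome panel**: independent SNPs (no LD, by design) across fake
  chromosomes, causal fraction split among architectures, one shared
  phenotype; sign-flip SNPs share a single latent subpopulation.

What the simulations do **not** emulate: linkage disequilibrium between
SNPs, relatedness/population structure, pedigree effects, genotyping
error, and multi-allelic sites. Passing the validation suite therefore
demonstrates correctness of the statistic and its calibration under the
stated architectures, not robustness to structure confounding — on real
cohorts the residuals handed to the ranking must already be adjusted for
such effects, as in any single-marker analysis.

## Validation problem sizes

Chosen as the package's own test conditions: null-ensemble checks at
K = 2000 replicates per preset; threshold calibration and fresh-null
self-consistency at K = 1000 per preset (6000 pooled draws); power
contrast over 200 sign-flip replicates at n = 500 against the 99%
threshold (observed power ≈ 100%, OLS rejection ≈ nominal 5%); effect
recovery over 500 Fisher replicates at n = 1000 (bias within 3 SE of the
replicate mean); FDR over 100 all-null 50-SNP panels at q = 0.05 with
K = 999 per-SNP permutations (≈3% of panels with any discovery).

## Known limitations

- The brute-force oracle is limited to N ≤ 8 by design (3^N growth).
- p̂'s closed-form null distribution is unknown; everything rests on
  permutation calibration, so `p_emp` resolution is bounded by 1/(K+1).
- Greedy LD pruning is order-dependent by construction (deterministic
  given input order), like the common single-pass tools.
- The published sheep analyses cannot be regenerated without their
  original supplementary data; the validation suite substitutes
  property-based checks on synthetic cohorts at the same scales.
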