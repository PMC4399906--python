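# Methods

## The statistic

For a region of k variants typed in n subjects (n1 cases, n0 controls),
let G_ij ∈ {0, 1, 2} count copies of the minor allele of variant j in
subject i, with the minor allele fixed once per variant from the
full-sample allele frequency (ties at 0.5 keep the input orientation, so
the coding never changes under label permutation). Two per-variant
quantities are recomputed from every phenotype labeling:

* the adjusted control minor-allele frequency
  q_j = (m_j + 1) / (2·n0 + 2), with m_j the minor-allele count among
  controls — the pseudo-count keeps q_j strictly inside (0, 1);
* the allele-table odds ratio with 0.5 added to every cell of the 2×2
  (minor/major × case/control) table, so OR_j is always finite and
  positive even for monomorphic variants.

Four weight schemes derive from these:

| scheme | w_j | captures |
|---|---|---|
| MAF | 1/√(n0 q_j(1−q_j)) | rarity (direction-blind) |
| OR  | log OR_j            | direction and strength (noisy for rare variants) |
| D   | I(OR_j>1) − I(OR_j<1) | direction only |
| DW  | D_j × MAF_j         | direction, with rarity as a strength surrogate |

Given a MAF cutoff θ, each subject's burden is
G_i(θ) = Σ_j w_j · I(q_j ≤ θ) · G_ij, summarised either as the
**rank-sum** (sum of case subjects' midranks of the pooled burdens) or
the **t-sum** (absolute Welch two-sample t of case vs control burdens,
unbiased group variances). Fixed-threshold methods use a single θ; by
default no filter at all (θ = ∞), since no principled fixed cutoff exists
and target comparisons use the unfiltered form. Variable-threshold (VT)
methods take S = sup over θ of S_θ, with the candidate set Θ equal to the
distinct observed q_j — the finest partition the data distinguish; a
user grid or single fixed value can be substituted. On ties the smallest
maximising θ is reported. The ten named methods combine these choices;
`VDWSS-t` (DW weight, t-sum, VT) is the flagship.

Empirical p-values come from B label permutations with the case count
fixed, sampled uniformly with replacement and seeded. Everything that
depends on labels — q, OR, weights, Θ, S — is recomputed per permutation;
freezing any of it would break the exchangeability on which the test's
validity rests (the calibration tests cover this). Both summaries reject
for large values, and p = (1 + #{S_perm ≥ S_obs}) / (B + 1) — the add-one
estimator, never zero, conservative. Permuted-vs-observed comparisons use
a tiny relative tolerance so floating-point noise cannot drop exact ties.

Degenerate inputs: a burden vector with zero variance in both groups
yields t-sum 0 when the means agree and +∞ otherwise (possible only on
pathological tiny inputs; a warning is emitted, and ∞ ≥ ∞ counts as a tie
in the permutation count). All-monomorphic regions return p = 1 by
convention in the region runner.

The permutation engine is vectorised: the allele counts for all labelings
in a chunk come from one matrix product, all weight schemes share those
counts, and the VT sweep reuses cumulative sums over variants sorted by
q, masking cumulative positions that fall inside a run of tied q values
(only the end of a run is a valid threshold). Memory is bounded by
processing permutations in chunks of 64.

## The simulator

`ScenarioSpec` encodes one study condition. Defaults are the base design
used throughout: 500 cases / 500 controls; 8 signal rare variants and no
noise variants; MAFs for rare variants from Uniform(0.001, 0.01) (signal
RVs from Uniform(0.001, 0.005) in `maf_mode="different"`), common
variants from Uniform(0.01, 0.1); independent variants (ρ = 0);
background prevalence 0.05.

Genotypes follow a latent-Gaussian threshold model: two independent
latent vectors per subject (the haplotypes) with AR(1) correlation
ρ^|u−v| between variants, generated by the exact scalar recursion
Z_u = ρZ_{u−1} + √(1−ρ²)ε_u rather than a Cholesky factor (exact for
this covariance and O(k) per haplotype); a haplotype carries the minor
allele at variant j iff its latent value is below Φ⁻¹(MAF_j). ρ = 0
reduces to Binomial(2, MAF_j) counts, which the tests verify, along with
the bivariate-normal orthant probability for adjacent variants at ρ = 0.7.

Disease status follows a logistic liability model:
logit P(D=1|G) = logit(0.05) + Σ_additive log(OR)·G + log(or_carrier)·I(any
carrier-block minor allele). Of the eight signal variants, the first four
act additively (per-allele OR `or_rv` = 2; a signal CV, when present,
takes one additive slot with OR `or_cv` = 1.5) and the last four form the
any-carrier block with joint odds multiplier `or_carrier` = 3 — one
mutation anywhere in the block is sufficient, more add nothing.
`protective()` inverts the additive odds ratios (1/2 and 1/1.5) and keeps
the carrier multiplier, which the liability model fixes at 3 irrespective
of the additive directions; `null()` sets every effect to 1, leaving
prevalence exactly 0.05. Signal/noise column positions are re-randomised
per dataset.

Case-control ascertainment is rejection sampling: population subjects are
drawn in batches until both strata are full (≈10⁴ draws for 500 cases at
5% prevalence), with an iteration cap and diagnostic for unreachable
strata. Same spec + seed gives a bit-identical dataset.

What the simulator does not emulate: genotyping error or missingness,
covariates or population stratification, haplotype-block or
recombination-driven LD (the AR(1) latent model is a stylised stand-in),
and selection-driven site-frequency spectra. Power and calibration
results under these conditions therefore characterise the statistics
under the stated model, not field performance on any particular cohort.

## The study harness

`run_study` estimates rejection proportions over `n_replicates` simulated
datasets with `n_permutations` per test at `alpha` (defaults 1000 / 500 /
0.05, the reference design). All methods of a grid are run on the same
datasets and permutation streams (common random numbers), so power
differences between methods are not inflated by simulation noise; this
can be avoided by running methods in separate configs. A master seed
spawns one child stream per (scenario, replicate), making any cell
reproducible in isolation. Every point estimate is reported with its
binomial standard error √(p̂(1−p̂)/R).

Problem sizes: the acceptance script and the acceptance tests use the
desk-scale preset of 300 replicates × 200 permutations per cell (about
one minute per scenario for several methods on one core), which carries a
Monte-Carlo band of roughly ±0.05 on power estimates near 1 and ±0.013 SE
on the type-I error. The full-scale design is a CLI flag away
(`n_replicates: 1000, n_permutations: 500` in the study YAML).

## Design choices where the design was open

* **Adjusted MAF**: the control-based pseudo-count form above; including
  case alleles would shift values slightly but leaves power essentially
  unchanged. The control-based form keeps the weight independent of case
  burden under the null labeling of each permutation.
* **OR from allele tables**, not carrier/genotype tables, matching the
  per-allele scale on which the burden weights operate.
* **Fixed-mode default θ = no filter**: any specific cutoff (0.01, 0.05)
  is arbitrary for methods whose point is to weight rather than truncate;
  the VT variants exist precisely to make the cutoff data-driven.
* **Missing genotypes** impute to 0 copies (conservative toward the
  null), with a warning above 20% per-variant missingness.
* **Rank ties** take midranks (standard Wilcoxon convention; burden
  scores tie heavily at 0 in rare-variant regions).
* **Upper-tail rejection only**: the rank-sum grows when cases carry more
  weighted burden and the t-sum is absolute-valued, so large values are
  the only evidence direction.

## Known limitations

* No covariate adjustment; stratified application is the caller's
  responsibility.
* No asymptotic p-values — permutation only, so genome-wide scans at
  very small α need large B (p is never below 1/(B+1)).
* Multiple-testing correction across regions is left to the caller.
* The label-swap symmetry (balanced designs) holds exactly only for
  unfiltered OR/D-weighted t-sum statistics; MAF-based weights are
  recomputed from the new control group and are approximately, not
  exactly, symmetric.
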