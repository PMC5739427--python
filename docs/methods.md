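# Methods

## Segment-count theory

The package's core quantity is the effective number of chromosome segments
`Me`, defined operationally by `1/Me = var(G_Tj)`: the variance of
whole-genome genomic relationships between a target individual and the
members of a reference sample.  Two routes compute it.

**Closed form.**  For a population at drift–recombination equilibrium with
constant effective size `Ne` and `Nchr` chromosomes of length `L` Morgans,
the per-chromosome relationship variance is

    v(Ne, L) = [ln(2NeL+1) + 2NeL(ln(2NeL+1) − 1)] / (4 Ne² L²),

the mean of Sved's expected squared genotype correlation
`E[r²] ≈ 1/(1 + 4Ne·c)` over all pairs of map distances `c` on the
chromosome (a form that accounts for mutation).  Cross-chromosome
covariance of relationships through the shared pedigree adds
`(Nchr−1)/(3Ne)`, giving

    Me = Nchr / ( v + (Nchr−1)/(3Ne) ).

The printed formula's operator precedence is ambiguous as typeset; the
implementation uses the reading above, which is the only one consistent
with the per-chromosome/whole-genome variance decomposition and with the
package's own empirical estimates.  With `Nchr = 1` it reduces exactly to
`1/v`.  Unequal chromosome lengths are supported as an extension by
averaging `v(L_i)` over chromosomes.  The power law `Me = 2.938·Ne^0.965`
(inverse `Ne = 0.327·Me^1.036`) is a fitted approximation specific to the
30 × 1-Morgan genome, accurate to <5% relative error for `Ne` in
[10, 10000]; it is what `ne_from_me` uses to attach an interpretable `Ne`
to an empirically estimated `Me`.

**Empirical.**  `build_grm` forms `G = XX′/M` on standardized genotypes
`x = (dosage − 2f)/√(2f(1−f))`, excluding monomorphic SNPs from `M` and
mean-imputing missing calls (zero contribution after centering).  Allele
frequencies come from the full supplied sample; pass `allele_frequency`
explicitly for reference-only standardization.  `empirical_me` inverts the
aggregated per-target variance of target–reference relationships.  The
default aggregation is the **median**, because the per-target variance
distribution is right-skewed when a handful of targets have close
relatives in the reference; the mean is available and is what the
theory↔simulation tests use (the theoretical value is a mean).  Sample
variances use `ddof = 1`; at reference sizes in the hundreds-to-thousands
the `n` vs `n−1` choice is immaterial but must be fixed for
reproducibility.

`per_chromosome_me` computes `M_i²/ΣΣ r²_{lm}` from the empirical
genotype-correlation matrix, diagonal included — forced by the limit that
a chromosome in perfect LD has `Me = 1`.  Consequently a finite panel of
`M_i` SNPs per chromosome inflates the per-chromosome variance by about
`1/M_i` relative to the continuum formula; marker panels should satisfy
`1/M_i ≪ v(Ne, L)` before comparing against the closed form (at
`Ne = 1000`, `v ≈ 0.0033`, so ≥ 1,000 SNPs/chromosome; the standard
validation panel uses 4,000).

## Prediction accuracy and power

Quantitative traits: `r²(g,ĝ) = b·h²/(b·h² + Me/N)` with
`b = M/(Me+M)`; `b` defaults to 1 (saturating panel) when no marker count
is given.  The phenotype-scale accuracy is `h·r(g,ĝ)`, so
`accuracy_phenotype² / reliability_gbv = h²` exactly.

Binary traits use the liability-threshold profile-score reliability

    r²(u,û) = h²z² / ( h²z² + [K(1−K)]²·Me / [P(1−P)·N] )

with `z = φ(Φ⁻¹(1−K))` always recomputed from the prevalence `K` — never
user-supplied, to keep `z` and `K` consistent.  `h²` is on the liability
scale.

Power of the predictor–outcome association in a target set of `N_T` uses
`NCP = N_T·r²/(1−r²)`, or, for case–control risk stratification contrasting
top and bottom predictor strata, the odds-ratio form
`NCP = ln(OR)²·[N_top·P_t(1−P_t)·P_b(1−P_b)] / [P_b(1−P_b) +
(N_top/N_bottom)·P_t(1−P_t)]`.  Both NCP expressions are χ²-scale, so the
normal-approximation power curve shifts by `δ = √NCP` by default: this
calibrates exactly (`power = α` at `NCP = 0`) and matches a 1-df
non-central χ² test.  A `literal_ncp` mode that shifts by `δ = NCP` is
exposed for compatibility with texts that plug NCP into the normal CDF
directly; tests are two-sided by default with a one-sided option.

## Combining reference cohorts

Each cohort contributes a predictor ĝ(k) with reliability r²(k).  For
random samples from one population the index has `g_k = r²(k)`,
`P_kk = r²(k)` and `P_ij = r²(i)·r²(j)` — independent samples are
correlated only through the true breeding value — and `g′P⁻¹g` is
**algebraically identical** to the weighted-`Me` route (Sherman–Morrison
on `P = gg′ + diag(r²(1−r²))` gives `S/(1+S)` with
`S = Σ r²(k)/(1−r²(k))`); the test suite verifies the identity to 1e-10
over randomized designs, and the CLI reports the difference between both
routes.  The returned quantity `g′P⁻¹g` is the reliability (squared
accuracy); both fields are reported explicitly to avoid the symbol
overload.

With genetic correlations, `g_k = rG(k,T)²·r²(k)`,
`P_kk = rG(k,T)²·r²(k)` and
`P_ij = r²(i)·r²(j)·rG(i,j)·rG(i,T)·rG(j,T)` — the entry structure that
reduces exactly to the plain index at unit correlations.  A source with
`rG(k,T) = 0` zeroes its entire row/column and would make `P` singular;
such sources are dropped before factorization, which realizes the correct
limit (they contribute nothing).  `P` is solved with a Cholesky
factorization; a non-positive-definite `P` raises an error naming the
sources rather than silently pseudo-inverting, since a designer must see a
degenerate design.  The off-diagonal independence assumption means cohorts
sharing individuals are mis-modeled; no overlap correction is attempted.
Mixed designs substitute the binary reliability for binary cohorts inside
the same index.

Cohorts specified by `Ne` are converted to `Me` through an explicit
`GenomeModel` (default 30 × 1 Morgan) so conversions are reproducible.

## Gene-dropping simulator

`simulate` implements discrete non-overlapping Wright–Fisher generations:
each offspring draws two parents uniformly with replacement (selfing
allowed; a monogamous-pair mode exists because the mating system is a free
choice at this level of theory), each gamete gets Poisson(L) crossovers
placed uniformly (Haldane, no interference), chromosomes assort
independently, and sites mutate at rate μ per generation.  Defaults follow
the standard validation setup: 30 chromosomes × 4,000 equally spaced SNPs,
L = 1 Morgan, μ = 1e-8.

Founders start at linkage equilibrium with allele frequencies drawn from
Uniform(0.05, 0.95); LD and pedigree relatedness then accrue over the
burn-in.  Running ~`Ne` generations brings the panel to
drift–recombination equilibrium; the final generation is expanded to
`final_sample_size` offspring drawn from the last `Ne`-sized generation.
No MAF filter is applied to simulated output (at μ = 1e-8 founder
polymorphism dominates; sites fixed by drift are dropped by the
monomorphic rule in `build_grm`).

Internally haplotypes are bit-packed (8 SNPs/byte, chromosomes padded to
byte boundaries) and gametes are built by patching alternating segments
between sorted crossover breakpoints, with partial boundary bytes blended
by bit masks — crossovers are sparse, so this avoids touching every SNP.
A numba-jitted kernel does the patching when numba is importable; the pure
NumPy/Python fallback is the same function and produces byte-identical
output.  All randomness flows from one `numpy` Generator seeded by
`SimulationSpec.seed`; identical seeds give byte-identical panels.

What the simulator emulates: neutral biallelic SNPs under drift,
recombination and mutation at constant `Ne` — exactly the regime the
closed-form theory assumes.  What it does not: selection, demographic
history (bottlenecks, admixture, growth), interference in recombination,
realistic site-frequency spectra from mutation–drift balance, genotyping
error, or multi-breed structure.  Passing validation therefore shows the
theory and estimators are internally consistent, not that real populations
satisfy the constant-`Ne` equilibrium assumptions.

`simulate_families` draws distinct parents from a simulated base
population and generates full-sib (expected relationship 0.5) or half-sib
(0.25, one shared sire with per-sib dams) families for studying structured
references.

## Validation problem sizes

The test suite validates simulator against theory at two scales.
Full-scale runs mirror the standard setup: `Ne = 50` for 50 generations
and `Ne = 1000` with the burn-in shortened to 300 generations (the
cross-chromosome pedigree term `(Nchr−1)/(3Ne)`, which contributes ~75% of
`1/Me` at `Ne = 1000`, equilibrates within tens of generations; the
residual deficit from unequilibrated tight-linkage LD is a few percent,
well inside the 25% Monte-Carlo band), each with 30 × 4,000 SNPs and 1,000
sampled individuals.  Module-level tests use thinned panels (120–1,000
SNPs/chromosome, 400–500 individuals, 3 seeds) chosen so that the
finite-marker `1/M_i` inflation stays small relative to the tolerance, and
scaled-down drift/heterozygosity and family-structure checks.  Observed
agreement in this environment: off-diagonal GRM variance 0.00766 vs theory
0.00766 at `Ne = 50`, and 0.000402 vs 0.000432 at `Ne = 1000`.

## Numerical choices and edge cases

- `power(0, α) = α` to 1e-12 by construction; in double precision the
  power curve saturates to exactly 1.0 near `NCP ≈ 100` at `α = 0.05`,
  so strict monotonicity is only asserted below saturation.
- Zero heritability returns reliability 0 with a warning rather than an
  error (a degenerate but well-defined design).
- `me_for_family_structure` treats the target's relationship to the
  reference as a two-point mixture (`kinship` with probability
  `p = 1/n_families`, else 0): `var = p(1−p)·kinship²`, `Me = 1/var`.
  Mendelian-sampling scatter around the expected kinship is excluded by
  default; `extra_within_variance` adds a user-supplied within-class
  variance.  `p ∈ {0, 1}` is rejected as "infinite Me".
- Relatedness-tier splitting assigns a reference individual by its
  *maximum* relationship to any target (an aggregation rule that must be
  fixed somehow; maximum matches the intuition that one close relative
  among the targets is what makes an individual informative), samples each
  tier fraction with a seeded generator, and is deterministic under that
  seed.
- GRM validation warns (not errors) when the mean diagonal leaves
  [0.9, 1.1], since legitimately inbred or small-`M` panels can exceed it.
- QC defaults: MAF > 0.01, SNP call rate > 0.95, individual call rate
  > 0.95; individuals are filtered before SNPs.  A Hardy–Weinberg χ²
  filter is off by default (equilibrium is guaranteed in simulated data).
- Display rounding (integer `Me`, 2-decimal accuracies) is applied only at
  the CLI surface; JSON/TSV reports carry full double precision, and the
  two report forms contain identical numbers.

## Known limitations

- The mutation-free variant of the segment-count formula is not
  implemented (its exact closed form is not fixed by the sources used
  here); the formula above accounts for mutation.
- Multi-breed/admixed references, historical population dynamics and
  overlapping-sample corrections are out of scope; `Ne` is assumed
  constant over the relevant past.
- Pedigree-based expected relationships (`A`) and `var(G − A)`-based
  segment counts are deliberately not implemented; the package works with
  `var(G)` throughout.
- The power calculation is a normal approximation, not an exact
  non-central χ²/F computation.
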