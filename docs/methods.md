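# Methods

This note documents the models implemented in `heteropath`, the
defaults of the synthetic-data generator, the numerical conventions,
and what the tests do and do not establish about real data.

## The breeding design being emulated

The material of interest is a pair of backcross (BC) introgression
libraries: exotic donor accessions crossed to an elite recurrent
parent, with the tallest, flowering-synchronized plant selected each
generation and backcrossed again, to BC3–BC6 ("phenotypic-selected
introgression families", PIFs).  Unselected BC1-derived doubled
haploid (DH) lines from the same parents serve as the neutral
comparison.  Donor alleles in a PIF are almost entirely heterozygous
(one recurrent allele at every locus is guaranteed by the final
backcross), so the donor genome proportion is

    DGP = heterozygosity% / 2 + donor-homozygous%

with the second term zero for PIFs and the whole of DGP for DH lines.
Without selection, E[DGP] after t backcrosses is 100·(1/2)^(t+1)
(50% in the F1, halved each backcross): 6.25, 3.13, 1.56, 0.78% for
BC3..BC6, and 25% for a doubled BC1 gamete.  Truncation selection on
height drags donor segments along, so observed DGP far exceeds these
expectations — the selection signature the simulator reproduces.

## Genome and meiosis model

Genomes are represented at marker resolution only (no sequence).  The
default map is 10 chromosomes × 270 Mb with uniformly placed markers
and a flat 1 cM/Mb rate; the genetic model is Haldane
(no interference), implemented as a Markov chain of parental-origin
states along each chromosome with recombination fraction
r = (1 − e^{−2d})/2 between adjacent markers at distance d Morgans.
At marker resolution this chain is exactly equivalent to simulating a
Poisson crossover process and reading it off at the marker positions,
and it vectorizes over thousands of meioses.  Because each BC
individual carries one all-recurrent haplotype, only the non-recurrent
haplotype needs to be tracked as a donor-origin indicator vector.

Selection is truncation on latent plant height among k candidate sibs
per family per generation (default k = 20; the real selection
intensity in the field is unknowable from the published material).
Latent height follows the structural model below with heterozygosity
standardized *within the candidate batch* — selection only uses
within-family ranking, so this choice fixes the selection intensity
per generation rather than letting it decay as heterozygosity shrinks.

## Structural model and its calibration

Four observed variables are linked by a recursive system
(standardized scale, unit variances):

    GA  = a·Het + e1          a = 0.53
    BR  = b·GA  + e2          b = 0.52
    PHT = c·Het + d·GA + f·BR + e3
                              c = 0.566, d = 0.181, f = 0.210

The coefficients are not free choices: a and b are the observed
GA–heterozygosity and BR–GA correlations in the taller-background
introgression library, and (c, d, f) solve the standardized path
(normal) equations against that library's PHT correlations
(0.72 with heterozygosity, 0.59 with GA, 0.46 with BR).  Residual
variances complete each equation to unit variance.  The implied
correlation matrix therefore reproduces the observed table, except
the BR–heterozygosity cell, which the five-edge topology forces to
a·b = 0.276 (observed 0.34) — that gap is exactly the df = 1
constraint the path analysis tests.

`simulate_phenotypes` maps latent values to field scale: PHT mean
180 cm with genetic SD 25 cm, and variance components
(σ²env, σ²ge, σ²e) = (100, 400, 650) cm², giving entry-mean
heritability ≈ 0.81 over the default 5 locations × 2 replicates —
the level reported for height in this type of trial.  Hormone traits
are scaled versions of the same components.

## Hormone assay model

Mesocotyl lengths average 40 mm under water (MW).  Inhibitor
treatments multiply MW by a logistic link in the latent hormone score,
g(z) = lo + (hi−lo)·sigmoid(0.5·z + m), bounded in (0.03, 0.95): a
genotype with more hormone synthesis/signaling tolerates the inhibitor
better and keeps a longer mesocotyl.  Centers are set so the mean
Pcz ratio (BR response MP/MW) is 0.30 and the mean Ucz ratio
(GA response MU/MW) is 0.18 — uniconazole shortens mesocotyls more
than propiconazole, as observed.  Replicate means carry noise
σ/√(n seedlings) with σ = 6 mm and 12 seedlings per replicate.
The logistic link is monotone but nonlinear, so observed-scale
correlations are mildly attenuated relative to the latent ones; tests
on the latent scale check the structural calibration, tests on the
observed scale check the full assay chain.

## Marker quality control and imputation

QC filters run in a fixed order so the report tallies are
unambiguous: (1) markers missing in all recurrent-parent control
individuals; (2) markers heterozygous in ≥3 of 6 controls (residual
heterozygosity in a fixed inbred should not recur at one position);
(3) markers with >5% missing calls across entries; (4) minor allele
frequency ≤ 5%, counting a heterozygous call as one copy of each
allele.  Missing calls are then filled by a k-nearest-neighbour vote
(k = 5) over the 30 markers flanking the target within its
chromosome, distance = count of mismatching non-missing calls,
distance ties broken by entry order and vote ties resolved to the
marker's modal call.  The named published algorithm (LD KNNi) leaves
its parameters unspecified; these defaults are configurable.

## Variance components and heritability

On balanced genotype × environment × replicate layouts the two-way
random model is estimated by the method of moments from expected mean
squares: σ²g = (MS_G − MS_GE)/(rn), σ²ge = (MS_GE − MS_E)/r,
σ²e = MS_E, negatives truncated to zero, and
h² = σ²g/(σ²g + σ²ge/n + σ²e/(rn)) on entry means.  Moment
estimation was chosen over REML because it is closed-form, exactly
testable, and identical to REML on balanced data for this model;
unbalanced layouts raise an explicit error rather than silently
reweighting (REML is a recognized extension left unimplemented).
Mean squares are computed directly from group means — a design matrix
with hundreds of genotype dummies is never built.

## Association scan and multiple testing

Each marker is tested by least squares of the trait on an intercept,
the ancestry fractions Q minus their last column (rows sum to one),
and the additive genotype code 0/1/2.  In BC material
donor-homozygotes are rare, so the contrast is effectively
heterozygous vs recurrent-homozygous.  The family-wise threshold is
α/m_eff with m_eff computed per chromosome as the smallest number of
leading eigenvalues of the marker correlation matrix reaching 99.5%
of the total, summed over chromosomes.  This follows the simpleM
idea; the original program's composite-LD correlation is simplified
to Pearson correlation on additive codes, a documented divergence.
Hit declaration is inclusive (p ≤ threshold).

## Co-localization enrichment

A SNP captures a gene if the gene interval lies within 1 Mb on the
same chromosome (distance to the nearest interval boundary, zero
inside).  The 1 Mb figure is a capture radius, not a window width:
published capture distances up to 0.87 Mb exclude the ±0.5 Mb
reading.  The null resamples the associated-set size with replacement
from the full marker frame 10,000 times; the p-value is the strict
exceedance fraction #(null > observed)/n_sim as defined, with the
conservative ≥ variant always reported because the strict rule can
return exactly 0.  Since with-replacement draws are iid Bernoulli in
the frame's capture fraction q, the null is exactly Binomial(n, q);
the package reports the closed-form survival probability alongside
the Monte-Carlo p as a built-in cross-check, and the test suite
verifies their agreement and the test's type-I calibration under
unenriched gene maps.

## Path analysis

Models are recursive (acyclic) linear systems over the four observed
variables with uncorrelated residuals,
Σ(θ) = (I−B)⁻¹ P (I−B)⁻ᵀ, fitted by minimizing the Wishart ML
discrepancy F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p on the correlation
matrix of the standardized variables (the published relationships are
standardized; the covariance-based χ² differs only at second order at
these scales).  For this model class F_ML decouples equation by
equation, so the per-equation least-squares solution computed from S
is the exact ML optimum and is used directly; the test suite verifies
it against an independent numerical minimization.  χ² = (N−1)·F_ML,
AIC = χ² + 2q with q = #edges + #variances (+ exogenous covariances).

Model search enumerates every acyclic edge subset under role
constraints — heterozygosity receives no edges (genotype precedes
physiology), height emits none — giving 96 candidate graphs on four
variables, replacing an unspecified stepwise add/delete search with
an exhaustive, order-independent one.  A model passes only if the
whole battery holds: χ² p > 0.05, RMSEA < 0.05, CFI > 0.95,
GFI > 0.8, AGFI > 0.9, NFI > 0.9, RFI > 0.9, IFI > 0.9.  Saturated
models (df = 0) have undefined RMSEA/RFI/χ²-p and are excluded.  Two
conventions deserve note:

- **Incremental indices and a fitting baseline.**  CFI/NFI/RFI/IFI
  measure improvement over the independence baseline.  When the
  baseline itself is not rejected (near-diagonal S), these indices
  are degenerate — the empty model, which *is* the baseline, has
  NFI ≡ 0 — so in that regime they do not bind in the battery and
  the absolute-fit criteria decide.  With correlated data (the case
  of interest) the baseline is overwhelmingly rejected and the full
  battery applies.
- **Stringency of RMSEA at df = 1.**  For a correctly specified
  df = 1 model the χ² statistic is χ²₁-distributed regardless of
  effect sizes, so RMSEA < 0.05 at N = 300 is passed with
  probability only P(χ²₁ < 1 + 0.0025·299) ≈ 0.81 even by the true
  model.  Consequently the search sometimes returns no winner on
  data generated from the true five-edge topology; when it does
  return a winner, it names the generating topology in ≈ 97% of
  replicates (the rare misses drop the weakest edge, GA→PHT at
  0.18).  The acceptance test asserts exactly these two facts.

## Problem sizes and defaults

The default end-to-end run uses 300 families, 1000 markers on 10
chromosomes, 5 environments × 2 replicates, 3 assay replicates of 12
seedlings, 120 candidate genes at enrichment 0.3, and 10,000
resamples; it completes in a few seconds.  Test-suite simulations use
200–500 entries and 200–500 markers, sizes at which the Monte-Carlo
tolerances quoted in the tests (3 SE bands, ±0.01 at n = 10⁵ for the
path-tracing check) are informative.

## Known limitations

- Donor parents are simulated as fully homozygous alternative-allele
  lines; real donors are segregating accessions, so real allele
  frequencies and within-family variation are messier than simulated.
- Flowering-time co-selection is not simulated; in the field it
  constrains which plants are selectable but adds no tested
  computation.
- No phasing, pedigree-aware imputation, Hardy–Weinberg filtering,
  kinship/mixed-model association, or LD-aware permutation schemes;
  population structure enters only through the Q covariates, and Q
  estimation itself (e.g. by STRUCTURE) is out of scope — Q is an
  input.
- Path models are restricted to observed variables with uncorrelated
  residuals (no latent variables, mean structures, bootstrap errors,
  or modification indices).
- The heritability machinery requires balanced layouts by design;
  REML for unbalanced data is a noted extension.
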