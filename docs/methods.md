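# Methods

This note documents the models, algorithms and numerical conventions in
`gblend`, the design choices made where more than one reasonable option
existed, and what the synthetic-data generator does and does not emulate.

## The animal model and REML

The model is `y = Xτ + Zu + e` with one record per individual,
`u ~ N(0, V_A·M)` and `e ~ N(0, V_E·I)`. `X` carries an intercept plus
reference-coded dummies for sex and hatch week (levels ordered by first
appearance; exactly collinear columns dropped by QR). `M` is any
relationship matrix: pedigree **A**, linkage-analysis **G_LA**,
LD-based **G_LD**, or a composite `λ·M1 + (1−λ)·M2`.

Estimation profiles the ratio γ = V_A/V_E. After one symmetric
eigendecomposition of the training submatrix of M (eigenvalues below
1e-8 clamped to 1e-8, with the count recorded — G_LD is rank-deficient
whenever markers are fewer than individuals), every γ evaluation is a
set of diagonal operations: with `H = γM + I = U(γd+1)U'`, the residual
variance has the closed form `V_E = y'Py/(n−p)` and the restricted
likelihood of γ alone is maximized by a bounded scalar search on log γ
over [1e−6, 1e6] (relative tolerance 1e−8, derivative-free). This is
deliberately simple and robust rather than fast-converging like AI-REML;
at the problem sizes used here the eigendecomposition dominates anyway.

The reported log-likelihood is the *full* restricted log-likelihood of
the error contrasts,

```
logL = −½[(n−p)·log 2π + log|V| + log|X'V⁻¹X| − log|X'X| + y'Py],
```

i.e. the exact density of `B'y` for any orthonormal basis B of the null
space of X'. Every M-dependent term is included and the convention is
identical across fits, so profiles over λ are directly comparable and
the 3.84 support-interval rule applies to honest likelihood-ratio drops.
(Absolute logL values from other software typically use a different
constant and are not comparable.) Standard errors come from the observed
information of the two-parameter restricted likelihood at the optimum
(central differences, step 1e−4 relative); the h² standard error uses
the delta method. Degenerate cases are flagged rather than hidden: a
flat likelihood in γ (e.g. M ∝ I with one record per individual, where
only V_A + V_E is identifiable) sets `flat_likelihood` and clears
`converged`; a solution at the γ search boundary sets `boundary`.

BLUP breeding values for all individuals (including the masked test set)
are `û = V̂_A · M[:,TRN] · V⁻¹(y − Xτ̂)`, algebraically identical to the
mixed-model-equations solution; the test suite verifies this identity
against a directly solved Henderson system.

## The λ profile

The grid runs from 0 to 1 inclusive (default step 0.1, giving 11 fits
per sequence). The peak is the grid argmax of logL with ties broken
toward smaller λ; the 95% support interval is the [min, max] of grid
points whose doubled drop from the peak is below 3.84 (χ²₁, 0.95). The
interval is reported from the discrete grid without interpolation, since
the grid is the object of interest. At λ = 1 the LDA and LDLA sequences
blend to the same matrix, so their fits agree bit-for-bit — asserted in
the tests as a consistency check.

## Relationship matrices

**A** uses the tabular method: `a_jj = 1 + ½a(s_j, d_j)` and
`a_ij = ½(a_i,s_j + a_i,d_j)`, unknown parents contributing zero.

**G_LD** follows VanRaden's Method 2, standardizing each marker by
`2p(1−p)`. Allele frequencies are computed from *all* genotyped
individuals (training plus test), not base-population frequencies: base
frequencies are unobservable in real data, and this matches common
practice. Missing genotypes are mean-imputed (contribute zero);
monomorphic markers are dropped with a warning (they are retained, as
uninformative, in G_LA, which involves no 2pq division).

**G_LA** is built in two stages.

1. *Transmission inference.* For each meiosis a two-state hidden Markov
   chain over loci tracks which parental haplotype was transmitted.
   Transitions between adjacent loci use the Haldane map function
   `r = ½(1 − e^(−2d))` (d in Morgans; r = ½ across chromosome
   boundaries). Emissions compare the offspring genotype with the
   parental allele of each state, integrating the other parent's
   contribution through its genotype (transmission probability g/2,
   falling back on the population allele frequency when unknown), with
   a genotyping-error rate ε = 0.001 guarding against zero-probability
   paths. Parental phase is resolved only where the parent's own
   parents force it Mendelianly; unresolved heterozygous loci are
   uninformative for that meiosis. A meiosis with no informative locus
   returns 0.5 everywhere and is counted in a diagnostic. This is a
   deliberate simplification of full multi-locus iterative peeling:
   single-locus phasing plus a per-meiosis HMM, rather than joint
   inference across the whole pedigree.
2. *Allele-kinship recursion.* Per locus, founder alleles are distinct
   (self-kinship 1, 0 otherwise — the same base assumption as **A**); a
   child's paternal allele has kinship `t·K(father h1, ·) +
   (1−t)·K(father h2, ·)` with t the transmission posterior (dam side
   analogous), and the individual-level relationship is half the sum of
   the four cross-allele kinships, so a non-inbred diagonal is 1 and
   the diagonal in general is 1 plus the allele-pair identity
   probability. G_LA is the unweighted mean over loci.

Two exact limits anchor the construction and are asserted in the tests:
with every posterior at 0.5 the recursion collapses algebraically to the
tabular method, so G_LA equals **A** entrywise; with posteriors equal to
the true transmission indicators it reproduces the realized gene-drop
IBD matrix. The HMM path with truth-supplied phase on a dense map
(0.125 cM spacing) recovers realized IBD to a mean absolute error below
0.005. The recursion is O((2n)² per locus) and is jit-compiled; the
per-locus allele matrix is held in float32. For very large populations
the mean over a thinned subset of loci (the `loci` argument) is an
unbiased estimator of the full average.

Composites are entrywise convex combinations with provenance recorded;
a convex combination of PSD matrices is PSD, and blending is linear in
λ, which the profile code relies on.

## Marker QC and chip construction

QC removes markers (never individuals) failing any of: one-df chi-square
HWE test P ≤ 0.001 (expectations from the sample allele frequency;
monomorphic markers return P = 1 — a closed-form test chosen over the
exact test for hand-verifiability), call rate ≤ 0.95, or MAF < 0.01.
Failure counts are reported per criterion with overlap, plus the single
removal count.

The **ESM** chip places, per chromosome, n target positions at
`(j − ½)·L/n` over the occupied genetic-map range; for each target,
candidates within half the inter-target spacing are ranked by MAF, then
proximity, then marker id, and the winner is taken (nearest unselected
marker if the window is empty). Chromosomes with ≤ n markers contribute
all of them. The **GWAM** chip takes the n smallest single-marker GWA P
values per chromosome, irrespective of significance, with deterministic
tie-breaking (smaller P, larger |t|, lowest id), making the panel
invariant to input order. The GWA itself is a fixed linear model of
phenotype on allele count with sex and hatch-week covariates, restricted
to training individuals (enforced), computed vectorized via
Frisch–Waugh residualization and verified against per-marker OLS.
Whether the original chip-design GWA adjusted for these covariates is
not documented; including them matches the trait's fixed-effect model
and is flagged as an assumption.

## Evaluation

Accuracy residualizes EBV and phenotype separately on sex and hatch week
*within the test set only* (singleton hatch-week levels are retained as
their own levels and contribute zero residual), takes the Pearson
correlation, and divides by √h². The h² used defaults to the pedigree
REML estimate from the training set and is configurable; the value is
reported uncapped — an estimate above 1 signals miscalibration and
should be visible. Bias is the EBV coefficient in a single linear model
`phenotype ~ EBV + sex + hatch week` on the test set, with its standard
error. Both statistics touch only test rows; mutating training
phenotypes leaves them bit-identical (tested). The theoretical blending
weight is `λ = m/(m + k)`; k is taken as an input (50, or an externally
derived effective segment number M_e), since deriving M_e requires
population quantities outside this package's scope.

## The synthetic-data generator

The generator emulates the *structure* of a closed commercial broiler
line: discrete generations; a founder base; a limited number of sires
and dams per generation drawn from the previous one, with dams allocated
to sires in a balanced way (defaults: 288 founders, 64 sires and 205
dams per generation, 5 offspring per dam → ~5,400 individuals, ~16
offspring per sire); ~75% females, mirroring a female-parent line;
hatch-week contemporary groups nested in generation (~30 individuals per
group); markers at uniform-random genetic positions on 10 chromosomes of
100 cM with founder allele frequencies uniform on [0.05, 0.5] in linkage
equilibrium; and meioses with Poisson crossovers (Haldane, no
interference — the same map function the HMM uses, keeping simulation
and inference self-consistent). The trait is polygenic: QTL are a random
subset of loci, *excluded* from the marker panel by default so that
G_LD must work through LD rather than causal genotypes; effects are
normal, rescaled so the realized founder breeding-value variance equals
V_A exactly (sharper parameter-recovery tests than scaling in
expectation); phenotype = sex effect + hatch-week effect (i.i.d. normal
per level) + BV + normal residual. Default variances V_A = 54.94,
V_E = 104.54 (h² = 0.3445) match the pedigree-model estimates of the
motivating dataset. The default marker count (5,000) is a deliberate
scale-down of a 27k chip to keep a full desk run in minutes; chip-level
counts are configurable.

The training/testing split labels individuals from the youngest
generation upward, admitting an individual to the test set only if none
of its offspring are in training, until the requested fraction is
reached (default 3146/5416 training). This reproduces the validation
design where test individuals are offspring/sibs of training
individuals; it errors if the fraction is unattainable.

What the generator does *not* emulate: selection (mating is random
within generation, so the EBV bias that selection induces in real
breeding data appears only through panel-construction overfitting, not
through selection itself — an optional truncation-selection mode would
be the natural extension); genotyping at low density plus imputation
(simulated genotypes are complete, whereas imputed real genotypes are
already shrunk toward pedigree expectations); overlapping generations;
genome-scale marker counts per chromosome; and non-equilibrium founder
haplotype structure (founders are in linkage equilibrium, so long-range
LD from ancestral bottlenecks is absent). Passing tests therefore
establish the estimators' correctness and the pipeline's behaviour under
the stated design, not the magnitude of accuracy or bias on any real
population.

## Problem sizes used in tests and the acceptance script

Tests verify exact identities on small instances (REML likelihood vs a
brute-force error-contrast density, EBV vs Henderson's equations, HMM
posteriors vs exhaustive path enumeration at 8 loci, G_LA = A under
uninformative markers) and stochastic properties at moderate scale:
200 replicate gene drops on a 20-individual pedigree for E[IBD] = A,
20-replicate parameter recovery at ~580 individuals, 20-replicate
panel-bias contrasts at ~600 individuals, and heritability recovery on
20 replicates of a ~3,100-individual six-generation population (the
same computation `scripts/acceptance.py` performs). These sizes were
chosen so the whole suite runs in a few minutes on one CPU while keeping
Monte-Carlo standard errors well inside the asserted tolerances.
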