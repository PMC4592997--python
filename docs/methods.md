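# Methods

This note documents the models and numerical conventions behind `gsindex`:
what the simulator generates, how each estimator is defined, which
constants are fixed by convention rather than by theory, and what the
package's tests do and do not establish about real data.

## 1. Simulated genome and populations

**Map.** Ten chromosomes, 250 biallelic markers each, with recombination
fraction 0.0906 between adjacent markers. 315 biallelic QTL are dropped
into randomly chosen inter-marker slots (at most one per slot); a QTL is
fully linked to its left flanking marker (r = 0) and one interval
(r = 0.0906) from its right one. A random subset of 15 QTL ("LE QTL",
5%) instead segregates in linkage equilibrium with the whole map
(recorded as r = 0.5 to both flanking markers). All counts and fractions
are configurable (`GenomeConfig`).

**Meiosis.** A first-order Markov walk per chromosome: a gamete starts on
a uniformly random strand and switches strands between adjacent loci with
probability equal to their recombination fraction. There is no crossover
interference — the model implied by fraction-based breeding simulators.
Two implementation details matter:

- LE QTL are drawn independently *outside* the chain. Embedding an
  r = 0.5 locus inside the chain would also destroy the 0.0906 linkage
  between its two flanking markers, which the design does not intend.
- Chromosome independence is realized by restarting the strand uniformly
  at each chromosome.

**Populations.** The base cycle (C0) is an F2 of two fully homozygous
complementary inbreds (all-1 × all-0), so every locus segregates 1:2:1 and
marker–QTL disequilibrium is maximal. Later cycles are random intercrosses
of the selected parents: each progeny draws two distinct parents uniformly
(resampled per progeny) and one meiotic gamete from each. True breeding
values are `a = (D − 1)E`, with D the QTL dosage matrix and E the effect
matrix; they are exactly reproducible from haplotypes and effects.

## 2. Trait architecture calibration

Four traits are controlled by 300/100/60/40 of the 315 QTL, with target
genetic correlations (T1T2, T1T3, T1T4, T2T3, T2T4, T3T4) =
(−0.5, 0.4, 0.3, −0.3, −0.2, 0.1) and per-plot heritabilities
(0.4, 0.6, 0.6, 0.8). Effect magnitudes are drawn uniformly on (0, 0.5]
(per allele copy); signs are free. Which QTL are shared between traits,
the signs, and the magnitudes are found by a simulated-annealing-style
local search (sign flips, magnitude redraws, membership swaps; geometric
cooling; 10⁴-move cap) minimising the maximum absolute deviation between
the implied F2 genetic correlations and the targets, with tolerance 0.05.

The implied correlations are computed against the *exact* F2 QTL-dosage
covariance of the map, `cov(d_i, d_j) = ½·Π(1 − 2r_k)` along the chain
(zero across chromosomes and for LE QTL). An earlier Monte-Carlo reference
population was abandoned: the optimiser exploits the reference's sampling
noise, leaving realized correlations systematically 0.05–0.1 short of
target. The search also polishes to half the tolerance internally, because
an architecture accepted exactly at the boundary leaves no margin for the
sampling noise (≈ 0.04 SD) of a realized 500-individual population. The
search raises an error, reporting its best deviation, if the tolerance
itself is unreachable within the move budget.

## 3. Phenotypes and variance components

Each genotype is evaluated in 4 plots; a plot value is the genotypic value
plus an independent N(0, σ²ₑ) residual with σ²ₑ = σ²_g (1 − h²)/h². The
residual variances are calibrated once against the realized genotypic
variances of C0 (so the per-plot h² holds exactly there) and then held
fixed: heritability drifts downward in later cycles as selection erodes
genetic variance, which is the standard convention for a fixed phenotyping
protocol. Phenotyping the F2 genotypic value directly stands in for
evaluating each family's selfed progeny, since the index operates on entry
means either way.

**REML.** For the balanced one-way multivariate model
`y_ijq = μ_q + g_iq + e_ijq`, the expected-mean-squares estimator
(Ĉ = (MS_G − MS_E)/n, R̂ = MS_E on mean-cross-product matrices) *is* the
REML solution whenever Ĉ is positive semi-definite, and is used verbatim
then. Only when Ĉ is indefinite (tiny or noise-dominated designs) does an
EM-REML refinement run (≤ 500 iterations, restricted-likelihood
convergence 10⁻⁸), followed by eigenvalue bending (eigenvalues floored at
10⁻⁶·λ_max) so that downstream solves never receive indefinite matrices.
Unbalanced tables are rejected: the simulated design is perfectly balanced
and the supported real-data path needs only cycle-0 tables.

**Bases.** A single plot has variance C + R; a 4-replicate entry mean has
variance C + R/4. Both are exposed (`CovarianceSet.phenotypic(basis)`).
The experiment driver's conventions, chosen to match how such studies
report their quantities, are:

- estimated PSI response: plot basis, R̂ = k√(b̂'P̂b̂) with P̂ = Ĉ + R̂ and
  b̂ = P̂⁻¹Ĉw — the literal textbook estimator;
- true PSI response: entry-mean basis with the simulator's known C and
  fixed R — the response an index applied to 4-replicate means can
  actually achieve. The plot-basis estimator therefore *underestimates*
  truth by roughly √(h²_plot/h²_entry) ≈ 0.75–0.9, increasingly so as
  genetic variance erodes — a calibration pattern the package reproduces,
  not a bug;
- PSI accuracy ρ̂_H = √(b̂ₑ'P̂ₑb̂ₑ / w'Cw): entry basis, because selection
  ranks entry means.

## 4. Marker models

Markers are coded {−1, 0, 1} (or {0,1,2} on input, recoded). Effects are
trained once, in C0, per trait by RR-BLUP on entry means:
`û_q = (X_c'X_c + λ_q I)⁻¹ X_c'(ȳ_q − μ̂_q 1)` with
`λ_q = (σ̂²_e,q / n_reps) / (σ̂²_g,q / Σ2pq)`, the variance components
coming from the C0 REML fit and σ²_g = Σ2pq·σ²_u being the canonical
relation between genetic and per-marker variance. The system is solved in
its dual (g × g) form when m > g. GEBVs in any cycle use the training
column means for centering (the base-population coordinate frame):
`γ̂_q = X_{c,l} û_q`. No retraining ever happens — decay of the GEBV
accuracy over cycles is part of the phenomenon under study.

**Relationship matrix and Γ̂.** `G_l = X_c X_c'/c` is computed per cycle
with that cycle's own column means. The scaling constant c is a
convention, not a derived quantity; the package default is the per-marker
scale c = m, with VanRaden's c = Σ2p̂(1−p̂) available
(`compute_grm(..., scale=)`). In an F2 at p = ½ the two differ by exactly
a factor 2, and only the product c·G⁻¹ reaches the Γ̂ estimator, so the
choice rescales Γ̂ while leaving per-trait GEBV correlations essentially
untouched; the per-marker convention is the one whose Γ̂-based accuracies
line up with this study design's expected values. A column-centered G is
singular by construction (rows sum to zero), so when the smallest
eigenvalue is below 10⁻⁸ of the largest a ridge of 10⁻⁶·tr(G)/g is added
before inverting (logged); the centered GEBV columns are orthogonal to the
offending constant eigenvector, so the result is stable in the ridge.

## 5. Index mathematics

Selection intensity is the infinite-population truncation value
k = φ(z)/p (k = 1.755 for p = 0.10). Responses are (k/L)√(v'Mv) and gains
(k/L)·M_num v/√(v'M_quad v) with (M, v) = (P̂, b̂) or (Γ̂, w). Truncation
selection takes the ⌈gp⌉ highest index values, ties broken by stable
original order. Estimated accuracies can exceed 1 in finite samples; they
are clipped to [0, 1] with a logged warning (the unclipped value remains
available). The true GSI response plugs the current cycle's true
breeding-value covariance into the response formula,
R = (k/L)√(w'C_l w); the per-cycle estimated/true ratios thus measure how
much of the available genetic variance the genomic machinery still "sees".
The Technow comparison is implemented as L_GSI < (ρ_H,GSI/h_PSI)·L_PSI,
with the estimated PSI accuracy supplied for h_PSI (the index-level analog
of the square root of trait heritability); all inputs are echoed in the
returned record, so the alternative reading L_GSI < ρ·h·L_PSI is equally
computable from it.

## 6. Experiment design

Both branches share C0 (phenotyped, 500 genotypes × 4 replicates) and the
C1 population produced by phenotypic selection at C0 — C0 is also the
genomic training population. From C1 the branches diverge: the phenotypic
branch re-phenotypes and re-estimates C, R, P every cycle; the genomic
branch only genotypes, predicts GEBVs with the C0 effects, estimates Γ̂,
and selects on w'γ̂. Default: 7 post-C0 cycles, top 10% intercrossed to
500 progeny, L_PSI = 4 y, L_GSI = 1.5 y, w = (1, −1, 1, 1). Per-cycle
records include responses per cycle (L = 1) and per year, expected gains,
accuracies, σ_H, per-trait GEBV correlations and the selected ids; the
comparison table adds λ and Technow decisions. A master seed drives
separate child generators for genome, architecture, base population and
each branch, so runs are reproducible bit for bit.

**Real-data mode** mirrors the deposited-file workflow: per-cycle coded
marker tables and a cycle-0 phenotype table; the phenotypic index is
computed only at cycle 0 and the genomic index at every cycle with marker
data. Entry-level phenotype tables (no replicate column) cannot separate C
from R; the driver then uses the sample covariance of entry means for P̂
and the genomic Γ̂ of the training cycle for Ĉ, ridge-training effects
with the variance ratio those two matrices imply. This is a pragmatic
substitute for the unavailable trial-level REML and is exercised on
synthetic tables in the tests.

## 7. Problem sizes and what the tests show

The replicate study (`gsindex.study`, `scripts/acceptance.py`) runs ten
7-cycle paired experiments plus ten one-cycle runs at the full design
scale — enough for Monte-Carlo standard errors of ~0.01–0.02 on the
reported means at sub-minute runtime. Unit and property tests run at
reduced scale (3-chromosome genomes, 100–300 genotypes) with exact
algebraic oracles where the quantity is deterministic.

The simulator emulates an idealized breeding program: biallelic loci, a
uniform marker grid, purely additive gene action, Gaussian iid plot
errors, balanced replication, no genotyping error and no
genotype-by-environment interaction. Passing tests therefore demonstrate
the internal consistency and calibration of the estimators under these
assumptions, not their behavior under field realities (dominance,
epistasis, G×E, unbalanced trials, structured populations).

Known limitations:

- Absolute response magnitudes depend on the product of QTL effect scale
  and QTL number; with effects on (0, 0.5] and this map, the simulated
  net-merit standard deviation is σ_H ≈ 6–7 at C0, and all absolute
  responses inherit that scale. Relative quantities (ratios, accuracies,
  correlations, λ) do not.
- The EM-REML path is a repair mechanism for indefinite small-sample
  estimates, not a general unbalanced-data REML engine.
- No map-distance/cM interface, mutation, dominance or epistasis; no
  multi-environment trials; no restricted or desired-gains indices; no
  phenotype+GEBV combined index.
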