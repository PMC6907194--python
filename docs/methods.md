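# Methods

## Scope

`eigenblup` studies how much of the genomic information used by genomic
BLUP (GBLUP) is carried by the largest eigenvalues of the genomic
relationship matrix (GRM), in a structured livestock population with a
small recent effective population size. It reimplements the whole
pipeline as a simulation study: forward-in-time population simulation,
VanRaden GRM construction, GBLUP under three representations of the
genomic covariance (standard, eigen-truncated, APY sparse inverse), and
two validation protocols (realized accuracy and PEV-based accuracy with
effective record counts).

## Simulation model

**Two phases.** A historical phase of random mating establishes linkage
disequilibrium (LD) and mutation–drift balance: census size ramps
linearly from a starting size down to a bottleneck at the midpoint
generation and back up to a final size (the stated endpoints are hit
exactly; the schedule between them is linear, the simplest curve
through the three stated sizes). A recent phase of 10 discrete
generations is then bred from 10 sires and `n_dams` dams drawn at
random from the previous generation, giving Ne = 4·Nm·Nf/(Nm+Nf) ≈ 40.
Each dam is mated to a single randomly drawn sire per generation, so
litters are full sibs — the mating pattern of standard breeding-
simulation software with litter size 2; probing the alternative
(per-offspring sire draws, i.e. maternal half-sib litters) showed it
leaves the GRM eigen-profile unchanged but loses ~0.04 of realized
accuracy, so the litter structure matters and is part of the design.
Sexes are assigned in an exactly balanced 1:1 ratio.

**Genome and meiosis.** 10 chromosomes of 100 cM (L = 10 Morgan) carry
evenly spaced SNPs and uniformly placed QTL. Meiosis draws the
per-chromosome crossover count from Poisson(length in Morgan) with
uniform crossover positions and no interference; chromosomes assort
independently; each transmitted allele mutates (flips) with probability
2.5e-5 per locus per generation (recurrent mutation). Founders start
with allele frequency 0.5 at every locus, in linkage equilibrium.

**Trait.** QTL allele-substitution effects are gamma(shape 0.4, scale 1)
magnitudes with random sign — the documented default of the emulated
simulation software; the absolute scale is irrelevant because variances
are calibrated afterwards. TBV_i = Σ_j effect_j · allele count. The
genetic variance σ²_u is the realized variance of TBV among genotyped
animals (not the theoretical QTL variance), and σ²_e is set so that
σ²_u/(σ²_u+σ²_e) equals the scenario heritability exactly; phenotypes
are `mean + TBV + N(0, σ²_e)` for generations 8–9 only. Generation 10
is the unphenotyped validation set. One simulated replicate can be
re-analysed at several heritabilities (`SimOutput.with_heritability`):
genotypes and TBV are kept, only the residual draw changes — a paired
design across heritabilities.

**Marker panel.** QTL are distinct loci and never enter the GRM panel.
SNPs monomorphic among the genotyped animals are removed (VanRaden
centering is undefined at p ∈ {0,1}); no further MAF filter. If more
than half the panel is lost the run aborts — that signals degenerate
drift parameters, not a real scenario.

## GRM, truncation, blending, APY

* `G = ZZ'/2Σp_j(1−p_j)` with observed allele frequencies of the current
  genotyped set (the only frequencies available from the data).
* Full symmetric eigendecomposition (LAPACK `syevd` via SciPy), sorted
  descending; eigenvalues in [−1e-8·λmax, 0) are clipped to zero, larger
  negatives abort. An eigenvalues-only mode serves profile studies at
  roughly a quarter of the cost.
* `G_eig = U D_r U'` keeps the r largest eigenvalues; the
  variance-explained profile reports, per threshold t, the smallest r
  with tr(D_r)/tr(D) ≥ t.
* Blending adds 0.01·I to G and to G_eig before any inversion. The APY
  inverse is also built from the blended G: without blending the
  noncore conditional variances m_nn,i = g_ii − g_ic G_cc⁻¹ g_ci can
  reach zero (an animal fully explained by the core), which the code
  treats as an error naming the animal.
* The APY inverse is stored in blocks (dense core inverse, core×noncore
  block, diagonal m_nn) and assembled on demand; core animals are
  permuted to the leading block internally and results are returned in
  the original animal order.

## GBLUP and PEV

The model is `y = 1μ + Wu + e`, var(u) = Gσ²_u over *all* GRM animals
(phenotyped or not), var(e) = Iσ²_e. The mixed-model equations are
solved by dense Cholesky factorization — exact and testable at the
study's sizes (≤ 12k animals). The three GRM options only differ in the
inverse inserted in the animal block: dense inverse of blended G,
`U diag(1/(d_i+ε) or 1/ε) U'` for blended G_eig (no factorization
needed), or the assembled APY inverse. Variance components are always
the simulation's true values; nothing is re-estimated.

PEV_i is σ²_e times the animal-block diagonal of the inverted
coefficient matrix. Two routes are implemented:

* **direct** — dense inversion of the LHS assembled over training
  animals only (validation animals excluded entirely, the second
  validation protocol);
* **reduced-rank** — rotate the equations into the GRM eigenbasis
  (u = U_r γ, var(γ) = (D_r+εI)σ²_u) and invert the (r+1)-dimensional
  rotated LHS; PEV is the quadratic form of each animal's eigenvector
  row with the γ-block. At full rank this is algebraically identical to
  the direct route — the package's acceptance check asserts the
  correlation between the two is 1.000 — and at r < n it is flagged
  (a warning) as a reduced-rank approximation, never silent.

Degenerate contracts worth knowing: constant records give μ̂ = mean and
all GEBV = 0; with an estimated mean and a single record the record is
absorbed by μ̂ and PEV returns the prior variance — the textbook 1×1
closed form `σ²_u g₁₁ α/(α+g₁₁)` holds for the no-intercept model, and
the tests pin both variants.

## Validation measures

* Realized accuracy: Pearson correlation of GEBV with TBV over
  generation-10 animals (undefined, reported as NaN, if either side has
  zero variance).
* PEV accuracy per training animal: `acc_i = sqrt(1 − PEV_i/(σ²_u g_ii))`
  with g_ii from the blended G used in the fit; effective genomic
  records invert `acc ≈ sqrt(1 − α/(α+d_p+d_g))` with d_p = 1 record;
  the training-set mean d̄_g gives the population approximation
  `sqrt(1 − α/(α+d̄_g))` for unphenotyped animals.
* The count of eigenvalues exceeding α = σ²_e/σ²_u marks which
  eigen-components carry more signal than noise per record; it is a
  diagnostic for where the accuracy plateau of eigen-truncation sits.
  Its exact scale convention is an open point (it could equally be
  defined on normalized eigenvalues); the count-above-α rule reproduces
  the described plateau behavior and is what the package reports.
* M_e formulas: 4NeL, 2NeL, and 2NeL/ln(4NeL) with the natural
  logarithm (the convention of the quantitative-genetics literature).
  At Ne = 100, L = 30 the third evaluates to 638.8; it is sometimes
  quoted rounded to the hundreds as ~600 — the code returns the exact
  value and the documentation notes the rounding rather than forcing it.

## Study orchestration

One replicate is simulated once and analysed under every option — a
paired design: standard G, G_eig at the rank reaching each
explained-variance threshold {10, 30, 50, 70, 90, 95, 98}%, and APY
with the *same* rank as the number of randomly chosen core animals (the
study's central device). Replicate seeds derive deterministically from
a master seed via `SeedSequence`, so identical designs reproduce
bit-identical tables. Per-replicate failures are recorded and tolerated
once; two or more abort the study.

## Desk-scale profile

The full printed design (1250 historical generations up to 25,015
individuals, 50k SNPs) is supported by the code but not what the
analyses run. The desk profile keeps every quantity that the study's
conclusions depend on at the printed scale — 10 sires (Ne ≈ 40), L = 10
Morgan, litter size 2, the genotyped/phenotyped counts (3000/6000/12000
genotyped; generations 8–9 phenotyped; generation 10 validation) — and
shrinks only two computational dials: the historical phase (125
generations, 500 → 100 → 2500) and the panel (5000 SNPs, 1500 QTL).
Both dials were probed directly: doubling the historical length and
sizes, or tripling/sextupling the panel, moves realized accuracy by
< 0.02 and the eigen-profile counts by < 10%, because the panel still
far exceeds the number of independent chromosome segments and
short-range LD equilibrates within far fewer generations than either
history. Scaling the *record counts* instead would mechanically lower
accuracy (fewer phenotypes is less information), which is why the
recent phase is not a dial.

With these conditions the package reproduces the headline pattern:
~4 eigenvalues explain 10% of the genomic variation, ≈ 1–2% of all
eigenvalues explain 50%, realized accuracy of standard-GRM GBLUP rises
with heritability and with population size, truncation at 98% explained
variance matches the standard GRM, and low-heritability accuracy
plateaus by ~70% explained variance.

## Known limitations

* The simulator's mid-band eigenvalue counts run ~40% above the
  reference simulation software's (r at 50% ≈ 65–75 vs ≈ 45–49 for
  3000–12,000 animals). The discrepancy is robust to marker density,
  historical length/size and mating structure, and so appears to stem
  from untracked internals of that software's historical/recent-phase
  bookkeeping. Quantities tied to the absolute mid-band counts inherit
  it. In particular, because the eigenvalues at the 70%-variance rank
  still exceed α = σ²_e/σ²_u at h² = 0.1, the low-heritability accuracy
  plateau of eigen-truncation falls nearer 90% explained variance here
  rather than ~70% — exactly what the eigenvalue-vs-α rule predicts for
  this spectrum, but later than in the reference study. Pairwise option
  comparisons (98%-truncation vs standard, APY vs eigen at matched
  rank) and the 10%-variance count are unaffected.
* No selection, migration, overlapping generations, crossover
  interference, or sequence-level processes; no pedigree/H-matrix or
  variance-component estimation — all outside the study's scope.
* PEV-based population accuracy treats the training-set mean d̄_g as
  common to all validation animals; it is an approximation, expected to
  sit near (and typically slightly off) the realized accuracy.
* Synthetic data only: passing tests show the methods are internally
  correct and reproduce the stated simulation conditions, not that any
  field dataset behaves this way (real data add genotyping error,
  selection, and pedigree structure the generator does not emulate).

## Problem sizes used by tests and the acceptance script

Unit tests run micro-scenarios (hundreds of animals, ≤ 1000 loci) with
closed-form or brute-force oracles. The acceptance tier and
`scripts/acceptance.py` run the desk profile: five replicates at 6000
genotyped animals (plus 3000, and a single 12,000 replicate for the
profile-by-size table), training subsets of 2000/4000 for the PEV-route
check. These sizes were chosen so a complete run stays in the tens of
minutes on one core.
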