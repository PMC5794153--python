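# Methods

This note records the statistical models behind `dominant-sgs`, the defaults
and why they were chosen, the numerical decisions, and what the bundled
generators do and do not emulate.

## Dominant markers and the observation model

A dominant biallelic locus has an amplifiable (band) allele with frequency
*p* and a null allele with frequency *q* = 1 − *p*; heterozygotes and band
homozygotes are indistinguishable, so the data per individual and locus are a
band indicator *x* ∈ {0, 1} (plus a missing code). Under inbreeding
*F*<sub>IS</sub> the null-homozygote probability is *q·h* with
*h* = *F*<sub>IS</sub> + (1 − *F*<sub>IS</sub>)*q*, so E[*x*] = *B* = 1 − *q h*.

## Bayesian allele-frequency estimation

Let *z* be the population null-homozygote proportion (*z* = *q*² under HWE).
With *m* band-absent individuals out of *n* typed, *m* ~ Binomial(*n*, *z*).
A Beta(*a*, *b*) prior on *z* is fitted empirically across loci by the method
of moments: with per-locus fractions *ẑ* = *m/n*,

- μ = mean(*ẑ*), and v = var(*ẑ*) − mean(*ẑ*(1−*ẑ*)/*n*) corrects the
  observed spread for binomial sampling noise;
- *a* = μ(μ(1−μ)/v − 1), *b* = (1−μ)(μ(1−μ)/v − 1).

If the corrected variance is non-positive (e.g. all loci at the same
fraction) the prior falls back to uniform with a warning, and v is capped
below μ(1−μ) to keep the Beta proper. The posterior of *z* is
Beta(*a*+*m*, *b*+*n*−*m*) and the point estimate is the posterior mean of
*q*:

  *q̂* = E[√z] = B(*a*+*m*+½, *b*+*n*−*m*) / B(*a*+*m*, *b*+*n*−*m*),

evaluated in log-Gamma space (stable for *n* in the thousands); the posterior
variance is E[*z*] − *q̂*². *q̂* is strictly inside (0, 1) and strictly
increasing in *m*. With an assumed *F*<sub>IS</sub> ≠ 0 the same Beta
posterior applies to *z* = *q*² + *F*<sub>IS</sub>*q*(1−*q*) and *q̂* is the
posterior mean of the monotone root, computed by quantile-midpoint quadrature
(512 nodes; agrees with the closed form to ~1e−4 as *F*<sub>IS</sub> → 0).
Default is HWE (*F*<sub>IS</sub> = 0): the assumed inbreeding of the study
protocol enters the kinship step, not the frequency step. Loci with *m* < 3
are flagged (Lynch–Milligan small-sample guard) but kept — the posterior
already regularises them.

## Diversity and Nei distances

Per population, per-locus gene diversity is *h* = 2*p̂q̂*·*n*/(*n*−1);
*H*<sub>E</sub> is the mean over loci, its standard error the across-locus
sd/√L, and PPL the percentage of loci with min(*p̂*, *q̂*) above a 5%
threshold (configurable; the criterion behind published PPL tables is rarely
stated, and the 5% allele-frequency rule is the common dominant-marker
default). The partition uses uncorrected 2*p̂q̂*: *H*<sub>w</sub> is its mean
across populations, *H*<sub>t</sub> the diversity of the across-population
mean frequencies, *H*<sub>b</sub> = *H*<sub>t</sub> − *H*<sub>w</sub>. Because 2*pq* is
concave, *H*<sub>b</sub> ≥ 0 by construction; applying the *n*/(*n*−1) factor
inside the partition could make it negative for identical populations, which
is why the corrected values appear only in the per-population table. Nei
distances default to the 1972 standard distance
D = −ln(J<sub>xy</sub>/√(J<sub>x</sub>J<sub>y</sub>)) with identities summed over loci from
(*p̂*, *q̂*); the 1978 unbiased variant (within-population identities
corrected by (2*nJ*−1)/(2*n*−1)) is available behind a flag.

## AMOVA, F<sub>ST</sub> and the Mantel test

AMOVA works on squared Euclidean distances between band-phenotype vectors
(missing loci dropped pairwise; the per-pair mean squared difference is
rescaled to the full locus count so pairs of different completeness remain
comparable). Sums of squares come from the distance-matrix identities
SS<sub>total</sub> = Σ<sub>i&lt;j</sub>d²/N and SS<sub>within</sub> = Σ<sub>g</sub>Σ<sub>i&lt;j∈g</sub>d²/n<sub>g</sub>;
variance components follow the expected mean squares with unequal group
sizes (n₀ coefficient), Φ<sub>ST</sub> = σ²<sub>b</sub>/(σ²<sub>b</sub>+σ²<sub>w</sub>), and the
p-value is the add-one fraction of label permutations (individuals permuted
freely among populations) with Φ ≥ observed. On instances of ≤9 individuals
`method="exact"` enumerates all N! orderings instead.

Wright's *F*<sub>ST</sub> is the across-population variance of the Bayesian
band-allele frequencies standardised by *p̄*(1−*p̄*), as a ratio of sums over
loci (loci implicitly weighted by *p̄*(1−*p̄*)). Its significance comes from
a G-test: G = 2ΣΣ O·ln(O/E) over per-locus population × phenotype
contingency counts, summed across loci, with individuals permuted among
populations. The G statistic is computed on phenotype counts, not inferred
allele counts — allele-level G is ill-defined for dominant data without
extra assumptions.

One caveat measured during development: Φ<sub>ST</sub> on dominant
*phenotype* distances estimates a phenotype-level fixation index that
exceeds the allele-level *F*<sub>ST</sub> by a factor of roughly
4*q̄*/(1+*q̄*) per locus (≈1.2 at intermediate frequencies). At strong
divergence (θ ≈ 0.4) the two statistics differ by ~0.06–0.08; they agree
within 0.05 for θ ≲ 0.15. Both are reported; they answer slightly different
questions.

The Mantel test correlates lower-triangle entries of two distance matrices
(Pearson r) and permutes rows/columns of one matrix jointly, one-sided by
default, add-one rule. With fewer than 4 populations the permutation null is
nearly degenerate and a warning is issued.

## Pairwise kinship for dominant phenotypes

For individuals *i*, *j* and loci with band frequency *p*, the estimator is
the multilocus ratio of sums

  F̂<sub>ij</sub> = Σ<sub>l</sub> (x<sub>il</sub> − B<sub>l</sub>)(x<sub>jl</sub> − B<sub>l</sub>) / Σ<sub>l</sub> 4 p<sub>l</sub> q<sub>l</sub> h<sub>l</sub>²,

with loci missing in either individual dropped from both sums and loci with a
constant observed phenotype excluded (no pairwise information). The
denominator is the first-order covariance scale: writing the condensed
identity coefficients (k₁, k₂) of a non-inbred pair,
Cov(x<sub>i</sub>, x<sub>j</sub>) = k₁p q³ + k₂q²p(1+q) at *F*<sub>IS</sub> = 0, and since
θ = k₁/4 + k₂/2 the estimator is exactly unbiased for pairs that cannot share
two genes identical by descent (parent–offspring, half sibs, unrelated) and
inflated for full sibs by k₂[Σp q²(1+q)/(4Σp q³) − ½] ≈ +0.05 at
*p* ~ U(0.2, 0.8). The pedigree calibration test fixes this property: the
regression of mean F̂ on true θ over {unrelated, half-sib, parent–offspring,
full-sib} has slope 1.0 ± 0.15, with the full-sib class individually inflated
by ~20%. Ratio-of-sums (not a mean of per-locus ratios) stabilises
low-information loci. The assumed *F*<sub>IS</sub> (default 0.19, an
allozyme-based estimate for the emulated species) enters through
*h* = *F*<sub>IS</sub> + (1−*F*<sub>IS</sub>)*q*.

## Correlogram, b_F, Sp and dispersal

Distance classes are quantile-based with near-equal pair counts; the number
of classes is the largest value in [5, 30] keeping ≥ 40 pairs per class
(half-open intervals, top class closed). Samples too small for five such
classes fall back to a single class, flagged non-conforming, with a warning.

*b*<sub>F</sub> is the OLS slope of pairwise kinship on ln(distance) over all
pairs with *d* > 0 (co-located pairs stay in the first-class mean; an
optional `max_dist` exists for sensitivity analyses but is off by default).
The permutation scheme shuffles the assignment of locations to individuals
within the population — this fixes the distance multiset, so class sizes and
the ln-distance moments are permutation-invariant and only the pairing of
kinship with distance varies. 95% envelopes (97.5/2.5 percentiles over
10,000 permutations by default; a 99% option reproduces stricter flags) are
computed for each class mean and for the slope; values outside are flagged
significant. Then

  *Sp* = −*b*<sub>F</sub>/(1−*F*₁),  *N*<sub>b</sub> = (*F*₁−1)/*b*<sub>F</sub>,
  σ<sub>g</sub> = √(*N*<sub>b</sub>/(4π*D*<sub>E</sub>)),

with densities entered in trees/ha and converted by 1 ha = 10⁴ m².
σ<sub>g</sub> is reported under the census density and reduced effective
densities (1/2, 1/4, 1/10 by default), so σ<sub>g</sub>(D/f) = σ<sub>g</sub>(D)·√f
exactly. Neighbourhood size and dispersal are only reported when
*b*<sub>F</sub> is negative and significant; otherwise the estimates are
suppressed (Sp is still printed, flagged "no positive SGS" when
*b*<sub>F</sub> ≥ 0).

## Synthetic data

**Clustered mode** emulates a multi-population dominant-marker survey
(defaults: six populations of 50/20/50/22/17/11 individuals, 401 loci —
the emulated study design). Population band-allele frequencies are
Balding–Nichols draws, Beta with mean equal to the ancestral frequency and
variance θ·p(1−p), so θ is the target *F*<sub>ST</sub> (default 0.39, the
divergence magnitude of the emulated survey). Genotypes are drawn with
inbreeding *F* = *s*/(2−*s*) induced by partial selfing (default
*s* = 0.3193, giving *F*<sub>IS</sub> ≈ 0.19); phenotypes are the dominance
mask (band iff ≥ 1 band allele). Populations sit in small uniform patches
separated by 10 km, so among-patch geography is essentially categorical.

**Isolation-by-distance mode** is a forward-time lattice model on a
rectangular torus: one plant per lattice site at exact density *D*
(spacing 1/√D), non-overlapping generations. Each site's new occupant draws
its mother through a Gaussian(σ<sub>s</sub>) seed kernel centred on the site
and its father through a Gaussian(σ<sub>p</sub>) pollen kernel centred on the
mother (self with probability *s*, otherwise the mother is excluded as
father); gametes are Mendelian. The lattice holds density exactly — a
free-placement continuum model develops strong spatial clumping under local
dispersal (no local density regulation), which makes the local density, and
with it *N*<sub>b</sub> = 4π*D*σ<sub>g</sub>², ill-defined. Axial gene-dispersal
variance is σ<sub>g</sub>² = σ<sub>s</sub>² + σ<sub>p</sub>²/2 (pollen moves one gamete), and
the expected SGS intensity is *Sp* ≈ 1/*N*<sub>b</sub>. Configurations with
*N*<sub>b</sub> < 1 are rejected as drift-degenerate.

Defaults: σ<sub>s</sub> = 2 m, σ<sub>p</sub> = 7 m — pollen-dominated gene flow, as
for a bee-pollinated tree with locally dropped, animal-moved seed —
and G = 300 generations. G was chosen from a measured sensitivity: with
windows spanning ~20σ<sub>g</sub>, the correlogram is still short of
drift–dispersal equilibrium at G = 100 (N̂<sub>b</sub> biased ≈ +40%),
reaches a stable state by G ≈ 300, and is unchanged at G = 400. Sampling
mimics an exhaustive field census of a central transect-shaped window
(default long axis 120 m ≈ 20σ<sub>g</sub>, width set by the target census
size and density; `idist_config_for_nb` builds such configurations for a
target *N*<sub>b</sub>). The transect shape matters: reference allele
frequencies are estimated from the sample itself, and a compact window
(~7σ<sub>g</sub> across) absorbs much of the kinship decay into the sample
mean, flattening *b*<sub>F</sub> by tens of percent; a transect spanning the
log-linear range keeps that referencing bias small (measured recovery:
median N̂<sub>b</sub> 22.5 for truth 20 and 44.2 for truth 50, ten seeds).

What the generators do **not** emulate: mutation (initial frequencies only),
overlapping generations, landscape resistance or anisotropy, genotyping
error and band homoplasy, and any real divergence history (the
Balding–Nichols cluster model matches a divergence magnitude, not a
phylogeny). Passing recovery tests therefore show the estimators are
calibrated under the stated models, not that field data meet those models.

## Numerical choices and degenerate inputs

- Permutation p-values use the add-one rule (1+hits)/(1+n_perm); ties are
  counted with a 1e−12 slack toward significance.
- Permutation defaults follow the emulated protocol: SGS 10,000, *F*<sub>ST</sub>
  5,000, AMOVA 999, Mantel 9,999; all configurable. The pipeline derives an
  independent seed per stage (CRC-keyed `SeedSequence`), so changing one
  stage's permutations never perturbs another's results.
- Kinship matrices are exactly symmetrised; pairs sharing no informative
  locus get NaN and are excluded from class means and regression per
  permutation.
- All-identical phenotypes: Φ reported as 0 with an explanatory note;
  monomorphic matrices make *F*<sub>ST</sub> an error; single-individual
  populations are excluded from AMOVA with a warning.
- Coordinate projection is a spherical transverse Mercator about the sample
  centroid (mean Earth radius); within 150 km of the central meridian the
  scale error is < 0.03%. Pre-projected `x_m`/`y_m` columns bypass it.
- The quantile classing caps v at proper-Beta bounds and resolves boundary
  ties with half-open intervals; heavily tied distances reduce the class
  count rather than produce empty classes.

## Test problem sizes

The graded suite runs the null calibration at 200 replicates of 40
individuals × 80 loci with 499 permutations, and the recovery study at
*N*<sub>b</sub> ∈ {20, 50} with ~200 sampled individuals, 300 loci, 10 seeds
and 1,000 permutations — sizes chosen so the full suite completes in a few
minutes on one core while keeping every check's power (binomial and K-S
bounds are stated in the tests).

## Known limitations

- The kinship estimator's full-sib inflation (~+20%) is inherent to
  first-order moment estimators on dominant data; correlograms dominated by
  full-sib family structure will overstate *F*₁ somewhat.
- Φ<sub>ST</sub> (phenotype level) and *F*<sub>ST</sub> (allele level) diverge at
  strong differentiation; compare like with like across studies.
- *N*<sub>b</sub> and σ<sub>g</sub> inherit every assumption of
  drift–dispersal equilibrium isolation by distance; in disturbed or
  non-equilibrium stands they are best read as effective, not demographic,
  quantities.
- Sub-σ<sub>g</sub> pairs and finite sampling windows bias the all-pairs
  ln-distance regression toward shallower slopes; the transect guidance above
  quantifies the effect under the simulator.
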