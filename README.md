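# dominant-sgs

Population genetics and **fine-scale spatial genetic structure (SGS)** for
**dominant markers** (AFLP, ISSR, RAPD — anonymous bands scored
present/absent), aimed at conservation geneticists and forest ecologists who
need diversity, differentiation and gene-dispersal estimates from band
phenotype tables plus GPS coordinates.

At a dominant biallelic locus only the null homozygote lacks the band, so
allele frequencies must be inferred, not counted. The package implements the
standard analysis chain for such data:

1. **Bayesian allele frequencies** (Zhivotovsky): an empirical Beta(a, b)
   prior on the null-homozygote proportion *z* = *q*² is fitted across loci
   by moments, the posterior of *z* given *m* band-absent out of *n* typed is
   Beta(a+m, b+n−m), and *q̂* = E[√z] in closed form via log-Beta functions.
2. **Diversity and distances**: Nei gene diversity *H*<sub>E</sub>, percentage of
   polymorphic loci (5% frequency rule), the *H*<sub>w</sub>/*H*<sub>b</sub>/*H*<sub>t</sub>
   partition and Nei (1972/1978) genetic distances.
3. **Population structure**: one-level AMOVA on squared Euclidean
   band-phenotype distances (Excoffier variance components, Φ<sub>ST</sub>,
   permutation test), non-hierarchical Wright *F*<sub>ST</sub> from the Bayesian
   frequencies with a permutation **G-test**, and the Mantel test of
   isolation by distance.
4. **Fine-scale SGS** — the core: pairwise kinship *F*<sub>ij</sub> for dominant
   phenotypes under an assumed inbreeding coefficient *F*<sub>IS</sub>
   (moment estimator with per-locus weight 4*p q h*², *h* = *F*<sub>IS</sub> + (1−*F*<sub>IS</sub>)*q*),
   distance-class correlograms with 95% permutation envelopes, the regression
   slope *b*<sub>F</sub> of kinship on ln(distance), and

   *Sp* = −*b*<sub>F</sub>/(1−*F*<sub>1</sub>),  *N*<sub>b</sub> = (*F*<sub>1</sub>−1)/*b*<sub>F</sub> = 4π*D*<sub>E</sub>σ<sub>g</sub>²,  σ<sub>g</sub> = √(*N*<sub>b</sub>/(4π*D*<sub>E</sub>)),

   where *F*<sub>1</sub> is the mean kinship in the first distance class,
   *D*<sub>E</sub> the effective density (census and 1/2, 1/4, 1/10 scenarios)
   and σ<sub>g</sub> the axial gene-dispersal distance in metres.
5. **Synthetic data with known truth**: a Balding–Nichols clustered-population
   generator (target *F*<sub>ST</sub>, selfing-induced *F*<sub>IS</sub> = *s*/(2−*s*)) and a
   forward-time lattice isolation-by-distance simulator (seed kernel σ<sub>s</sub>,
   pollen kernel σ<sub>p</sub>, σ<sub>g</sub>² = σ<sub>s</sub>² + σ<sub>p</sub>²/2), so every estimator is
   testable without external data.

## Worked example

Simulate an isolation-by-distance stand with known neighbourhood size
*N*<sub>b</sub> = 20, then run the full SGS chain (frequencies → kinship →
correlogram → *Sp* → *N*<sub>b</sub> → σ<sub>g</sub>):

```python
import dominant_sgs as ds

cfg = ds.idist_config_for_nb(20, seed=3)
markers, samples, truth = ds.simulate_spatial(cfg)
model = ds.DominantSGS(markers, samples.coords_m(), f_is=0.0, class_range=(5, 10))
res = model.fit(n_perm=1000, seed=42)
print(res.summary())
print(res.dispersal(census_density_per_ha=1e4 * cfg.density_per_m2).summary())
```

prints (abridged correlogram):

```
Fine-scale spatial genetic structure
====================================
   lo    hi  n_pairs  mean_dist  mean_kinship    env_lo     env_hi  significant
4.232 13.38     2642      8.755       0.05279 -0.005006 -0.0007894         True
13.38 18.92     2430      15.96       0.03394 -0.005215 -0.0007822         True
...
85.06 122.1     2690      97.76       -0.0373 -0.004863    -0.0012         True
------------------------------------
F_1 = 0.0528   b_F = -0.0405 [95% envelope -0.0010, 0.0009; significant]
Sp = 0.0428   (1000 permutations, 26796 pairs in regression)
N_b = 23.4 individuals (census density 558 trees/ha)
 fraction  density_per_ha  density_per_m2  sigma_g_m
        1           558.4         0.05584      5.772
      0.5           279.2         0.02792      8.163
     0.25           139.6         0.01396      11.54
      0.1           55.84        0.005584      18.25
```

Kinship decays log-linearly with distance and the slope is far outside the
permutation envelope, so the stand shows significant SGS; the estimated
neighbourhood size (23.4) recovers the simulated truth (20) and halving the
assumed effective density multiplies σ<sub>g</sub> by √2 exactly.

The same chain runs from the shell on TSV tables:

```bash
dominant-sgs simulate --config sim.yaml --out data/
dominant-sgs run --config run.yaml --out results/
dominant-sgs sgs --markers m.tsv --samples s.tsv --seed 1 \
    --density QU=2.72 --out sgs_out/
```

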