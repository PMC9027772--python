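# halosoil

Analysis toolkit for microbial community composition and metabolic activity
in coastal saline soils.

Salinization is a major constraint on agricultural soils in coastal regions.
A standard survey of such soils combines four strands of evidence, and
`halosoil` implements all four as a tested, reusable pipeline:

1. **Salinity classification** — electrical conductivity (EC, μS/cm) of a
   1:5 soil–water suspension is converted to soluble-salt content with the
   coastal-soil calibration

   *salinity* [g/kg] = EC / (1000 × 0.39) − 0.0182

   and plots are grouped as Non- (< 1 g/kg), Mild- ([1, 4) g/kg) or
   Severe-salinity (≥ 4 g/kg).

2. **Microcalorimetric growth kinetics** — isothermal calorimetry records a
   power–time curve P(t) (μW per g soil) for each soil ampoule. Unamended
   soils yield the basal heat release P_bas (mean heat flow); glucose-amended
   soils follow a microbial growth curve whose substrate-unlimited initial
   phase obeys

   P(t) = A + B·exp(k·t)

   with A the heat flow uncoupled from growth, B the initial heat flow of
   the growing fraction, and k (h⁻¹) the specific growth rate of the soil
   community. The fitter uses separable least squares (a deterministic log
   grid over k with golden-section refinement; A and B solved in closed
   form per candidate), plus peak descriptors P_max and T_max from a
   smoothed curve.

3. **Community statistics** — rarefaction, richness, Faith's phylogenetic
   diversity, Bray–Curtis dissimilarity, PERMANOVA (global and pairwise
   with Holm adjustment), the Mantel test, one-way ANOVA with Tukey-HSD
   compact letter display, and simple linear R² — all implemented from
   first principles with permutation p-values using the +1 correction.

4. **Co-occurrence networks** — per-group Pearson correlation networks of
   log₁₀ relative abundances, thresholded by a random-matrix-theory
   spacing criterion (raise the cutoff until the eigenvalue
   nearest-neighbour spacings become Poisson-like), with a topological
   index suite (density, average degree, Freeman degree centralization,
   transitivity, average geodesic distance, greedy-modularity modules) and
   degree-preserving / Erdős–Rényi null-model comparisons.

A synthetic-data module generates calorimetry curves, Gaussian-niche OTU
tables along a salinity gradient, and EC-linked soil chemistry, so every
stage can be exercised end-to-end without any external data.

## Worked example

```python
import numpy as np
from halosoil import (CommunitySimSpec, CurveSimSpec, anova_tukey, bray_curtis,
                      classify_salinity, ec_to_salinity, fit_growth_model,
                      gen_community, gen_curve, peak_features, permanova,
                      rarefy, richness)

# 1. salinity: EC 491 μS/cm → 1.24 g/kg → Mild-salinity
s = ec_to_salinity(491)
print(round(s, 2), classify_salinity(s).value)        # 1.24 Mild

# 2. growth kinetics on a simulated glucose-amended curve
curve = gen_curve(CurveSimSpec(a=2.0, b=0.2, k=0.45, noise_sd=0.3, seed=7),
                  mode="realistic", sample_id="plot7")
feat = peak_features(curve)
fit = fit_growth_model(curve, frac=0.2)   # early-phase window
print(f"P_max={feat.p_max:.2f} uW/g  T_max={feat.t_max*60:.0f} min")
print(f"A={fit.a:.3f}  B={fit.b:.3f}  k={fit.k:.3f} 1/h  R2={fit.r2:.4f}")

# 3. community statistics on a synthetic salinity gradient
table, meta, tree = gen_community(CommunitySimSpec(seed=1))
rt = rarefy(table, 4500, seed=1)
groups = meta.set_index("sample_id").loc[rt.sample_ids, "sal_class"]
F, p, letters = anova_tukey(richness(rt).to_numpy(), groups.to_numpy())
print(f"richness ANOVA: F={F:.2f} p={p:.3f} letters={letters}")
res = permanova(bray_curtis(rt), groups, n_perm=999, seed=1)
print(f"PERMANOVA: pseudo-F={res.statistic:.2f} R2={res.effect:.3f} p={res.p_value:.4f}")
```

Output:

```
1.24 Mild
P_max=60.22 uW/g  T_max=1758 min
A=1.740  B=0.298  k=0.390 1/h  R2=0.9916
richness ANOVA: F=1.33 p=0.281 letters={'Non': 'a', 'Mild': 'a', 'Severe': 'a'}
PERMANOVA: pseudo-F=10.36 R2=0.434 p=0.0010
```

The last two lines show the signature the pipeline is built to detect: the
salinity gradient leaves rarefied richness statistically unchanged (all
groups share the letter "a") while community *composition* shifts strongly
(PERMANOVA R² = 0.43 at the permutation floor p = 1/1000). The fitted
k = 0.39 h⁻¹ sits below the generator's 0.45 h⁻¹ because the logistic test
curve self-limits even inside the early window; see `docs/methods.md`.

## Command line

```bash
halosoil simulate community --seed 1 --out data/
halosoil salinity --in data/chemistry.tsv --out data/classified.tsv
halosoil calorimetry --manifest curves/manifest.tsv --out feats/
halosoil diversity --otu data/otu_table.tsv --tree data/tree.nwk \
    --meta data/community_meta.tsv --depth 4500 --perms 999 --seed 42 --out div/
halosoil network --otu data/otu_table.tsv --meta data/community_meta.tsv \
    --prevalence 0.5 --threshold auto --nulls 100 --seed 7 --out net/
halosoil run --out run1/ --seed 0       # full synthetic end-to-end pipeline
```

Every pipeline run writes a `run_manifest.json` with all inputs, seeds and
parameters for exact reproduction.

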