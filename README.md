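# micronet

Microbial carbon pools, community properties and co-occurrence network
complexity as predictors of cropland soil organic carbon (SOC).

Regional soil surveys increasingly measure not just soil chemistry but the
soil microbiome: amplicon (16S/ITS) community profiles, chloroform
fumigation-extraction biomass carbon, and amino-sugar biomarkers of dead
microbial residues ("necromass"). `micronet` implements the full analysis
chain that turns such measurements into predictive models of SOC for a
two-crop (maize/rice) survey design, together with a synthetic survey
generator with known ground truth so that every stage can be validated
against a recoverable target.

## What it computes

**Carbon pools** (`micronet.carbon_pools`). Microbial biomass C from the
fumigation flush, MBC = (TOC_fum − TOC_unfum)/0.45; bacterial necromass C
from muramic acid, BNC = 45·MurA; fungal necromass C from glucosamine after
the bacterial correction,

    FNC = (GluN/179.17 − 2·MurA/251.23) × 179.17 × 9,

total necromass MNC = BNC + FNC, and the MNC/SOC percentage.

**Community statistics** (`micronet.community`). Rarefaction by
hypergeometric subsampling, observed species and Shannon index H = −Σ pᵢ ln
pᵢ, Bray–Curtis dissimilarity, classical PCoA, and one-factor PERMANOVA
with a seeded (or exhaustive) permutation null.

**Co-occurrence networks** (`micronet.network`). Per crop: taxa below 0.01%
relative abundance removed, pairwise Spearman ρ with Benjamini–Hochberg
FDR, edges where |ρ| ≥ 0.7 and q < 0.001. Seven topological parameters of
each sample's induced subgraph (n, average connectivity, Freeman
centralization of betweenness and degree, transitivity, density, average
path length) are condensed by PCA into per-sample network complexity
indices (network PC1/PC2). Greedy modularity module detection and a
descriptive log–log degree-distribution slope round out the module.

**SOC multi-model inference** (`micronet.soc_models`). Twelve Z-scored
predictors in four categories (climate, soil, microbial C pools, community
properties); all 2¹² predictor subsets fitted by OLS/ML and ranked by AICc;
Akaike-weighted averaging over the ΔAICc < 2 confidence set with
unconditional SEs; relative importance 100·|β̂ⱼ|/Σ|β̂ₖ|; and the four-suite
comparison (#1 all predictors, #2 without community properties, #3 without
C pools, #4 climate + soil only).

**Path analysis** (`micronet.path_model`). SOC is residualized on climate +
soil controls; a recursive structural-equation model (diversity, network
complexity, MBC, MNC → SOC residual) is fitted by minimizing the ML
discrepancy F_ML = ln|Σ(θ)| − ln|S| + tr(SΣ⁻¹) − p, with χ² = (n−1)F̂, RMSEA,
CFI, GFI, and Wright's-rules total effects. Editable maize/rice topology
configs ship as JSON.

**Synthetic surveys** (`micronet.synthetic_data`). 349 maize + 119 rice
sites by default; covariates from the surveyed climate ranges; amino sugars
back-solved from target pools; block-correlated log-normal → multinomial
count tables with a crop composition shift; SOC generated from known
standardized coefficients.

## Worked example

```python
import micronet as mn

# carbon pools from the crop mean amino-sugar components (mg/g)
mnc = mn.total_necromass_c(1.22, 3.49)          # 4.71
share = mn.necromass_fraction_of_soc(3.49, mnc)  # 74.1  (% of MNC that is fungal)

# a synthetic survey with known ground truth
truth = mn.default_ground_truth(seed=1)          # mnc 0.4, np_ratio 0.3, mbc 0.2, net_pc1 0.2
ds = mn.generate_survey(349, 119, truth, seed=1)

tab = ds.predictors.copy()
tab["soc"] = ds.sites.set_index("site_id")["soc"]
z, params = mn.z_standardize(tab)
ms = mn.all_subsets(z["soc"].to_numpy(), z[list(mn.PREDICTOR_NAMES)])
print(ms.best.predictors, round(ms.best.r_squared, 3))
```

prints

```
('np_ratio', 'mbc', 'mnc', 'fungal_shannon', 'net_pc1') 0.416
```

— the best-AICc subset finds exactly the four predictors that truly drive
SOC in the generator (plus one spurious diversity term in this replicate),
and the model explains ~0.42 of the SOC variance, consistent with the
generating signal-to-noise.

The same pipeline is exposed as a CLI:

```
micronet simulate --n-maize 349 --n-rice 119 --seed 1 --out survey/
micronet pools     --sites survey/sites.tsv --out pools.tsv
micronet community --counts survey/counts_bacteria.tsv --sites survey/sites.tsv --out comm/
micronet network   --fixtures survey/ --crop maize --out net/
micronet models    --table merged.tsv --out models/
micronet sem       --table merged.tsv --spec src/micronet/path_specs/maize.json --out sem/
```

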