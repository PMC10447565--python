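# Methods

This note documents the models, conventions and design choices behind
`micronet`, in the order the pipeline runs.

## Carbon pools

Microbial biomass C is the chloroform-fumigation flush divided by the
extraction-efficiency factor kEC = 0.45 — "conversion factor 0.45" is read
as a divisor (the standard kEC interpretation), not a multiplier, since the
flush recovers only ~45% of biomass C. A negative flush (unfumigated extract
richer than fumigated, a measurement artifact) is floored at zero and
flagged, never passed through silently.

Necromass C comes from amino-sugar biomarkers. Muramic acid occurs only in
bacterial peptidoglycan, so BNC = 45·MurA (mg/g). Glucosamine is of mixed
origin; the fungal share is the molar GluN excess over 2× the MurA molarity
(each mole of bacterial MurA is accompanied by roughly two moles of
bacterial GluN), converted back to mass with the glucosamine molecular
weight 179.17 g/mol (MurA: 251.23 g/mol) and multiplied by the fungal
factor 9. When MurA is large relative to GluN the bracket goes negative;
the value is clamped to 0 and flagged. Galactosamine is measured and
carried through I/O but consumed by no formula. MNC = BNC + FNC holds
bit-exactly by construction.

Units: amino sugars and necromass in mg C/g soil, MBC and SOC in g C/kg;
the two scales are numerically identical, so MNC/SOC needs no conversion.
Crop-level MNC/SOC summaries are means of per-site ratios, not ratios of
means (the two differ under heterogeneity; the per-site mean is the
documented choice).

## Community statistics

Rarefaction subsamples each sample's reads without replacement (multivariate
hypergeometric) to a common depth; samples below the depth are dropped and
reported. Diversity defaults to rarefied tables. Shannon entropy uses
natural log (nats) with a configurable base. Bray–Curtis is
1 − 2Σmin(xᵢ,yᵢ)/(Σx+Σy). PCoA is classical scaling (double-centered
−D²/2); negative eigenvalues are reported but produce no coordinates, and
variance proportions are taken over the positive eigenvalues (so they sum
to 1); an optional Cailliez correction makes non-Euclidean inputs
embeddable.

PERMANOVA uses the one-factor pseudo-F on squared dissimilarities,
F = (SS_among/(a−1))/(SS_within/(N−a)), with a label-permutation null and
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm); 999 permutations by default. For
small designs an exhaustive mode enumerates all distinct labelings and
reports the exact permutation p. If all dissimilarities are zero the test
degenerates to F = 0, p = 1. PERMANOVA and PCoA are implemented in-package
because seeded generators, the exact-p mode and the reporting conventions
above are part of the contract; scikit-bio's implementations serve as
independent cross-checks in the test suite.

## Co-occurrence networks

Networks are built per crop from the merged bacteria + fungi table. Taxa
below 0.01% of the grand total are removed; a taxon at exactly the
threshold is retained (≥). Correlations default to relative abundances
after filtering (counts are also supported); Spearman ρ uses average ranks,
with two-sided p from the t approximation and Benjamini–Hochberg adjustment
over the C(m,2) upper-triangle tests. Edges require |ρ| ≥ 0.7 and q < 0.001;
strong negative correlations qualify by default (`positive_only` restricts
to positive), and isolated taxa are dropped.

Per-sample topology uses the subgraph induced by the taxa present in that
sample (count > 0 by default; threshold configurable). The seven
parameters: node count n; average connectivity 2|E|/n; density
2|E|/(n(n−1)); clustering coefficient = global transitivity (3·triangles /
connected triples); Freeman centralization of degree, Σ(max−dᵢ)/((n−1)(n−2)),
and of normalized betweenness, Σ(max−cᵢ)/(n−1) — both 1 for a star graph;
average path length = mean shortest-path length over reachable pairs only,
flagged when the subgraph has more than one component. Subgraphs with n < 2
are reported undefined. The complexity index is a PCA of the Z-scored
seven-column matrix; constant columns are dropped with a warning, and each
component's sign is fixed by making its largest-|loading| element positive,
so scores are deterministic. Module detection uses greedy modularity
maximization (validated against exhaustive partition enumeration at toy
scale), with modules numbered by decreasing size. The degree-distribution
summary is a descriptive OLS slope of log(count) on log(degree).

## SOC multi-model inference

Predictors and response are Z-scored (ddof = 1). Every subset of the
predictor roster is fitted by OLS; the Gaussian ML log-likelihood uses
σ̂² = RSS/n, and k counts intercept + slopes + error variance. AICc
(= −2ℓ + 2k + 2k(k+1)/(n−k−1)) is the default criterion — the small-sample
correction matching the MuMIn convention — with plain AIC by flag. A
perfect fit is guarded by a variance floor so the likelihood stays finite.

Averaging is over the ΔAICc < 2 confidence set with renormalized Akaike
weights. The default is full (zero-substitution) averaging: a predictor
absent from a model contributes β = 0 with SE 0; conditional averaging is
available by flag. Unconditional standard errors follow Burnham–Anderson,
SE = Σwᵢ·sqrt(seᵢ² + (βᵢ − β̄)²); 95% CIs and p-values use the normal
approximation on that SE (the unconditional choice is the conservative
reading where the source is silent). Relative importance uses absolute
values, 100·|β̂ⱼ|/Σ|β̂ₖ| — the literal signed ratio can exceed 100% with
mixed signs — plus sums over the four categories. The four suites are
#1 all 12 predictors, #2 without community properties (8), #3 without
C pools (10), #4 climate + soil (6), each run through the full
all-subsets → averaging pipeline and ranked by best AICc.

## Path analysis

SOC is residualized on climate + soil controls by OLS; the residual
variance share is reported. The path model is recursive with all variables
observed: Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ, with free parameters the edge
coefficients, declared exogenous covariances, and log-parameterized
variances. F_ML is minimized by BFGS from the equation-wise OLS start
(exact for saturated recursive models) plus jittered restarts (5, seeded);
non-convergence is flagged, never silent. χ² = (n−1)·F̂ (the n−1 convention
of the common desktop SEM software); df = p(p+1)/2 − free;
RMSEA = sqrt(max(χ²−df,0)/(df(n−1))); CFI against the independence
baseline; GFI = 1 − tr[(Σ̂⁻¹(S−Σ̂))²]/tr[(Σ̂⁻¹S)²]. Standardized
coefficients use model-implied SDs; total effects are computed in closed
form as (I−B_std)⁻¹ − I, equal to Wright's sum over directed paths.
Standard errors come from the inverse numerical Hessian of (n−1)/2·F_ML.

The shipped maize topology (df = 1: diversity and network complexity →
MBC; network → MNC; MBC → MNC; all four → SOC except diversity → MNC) and
rice topology (df = 5: network → diversity and SOC; diversity → MNC;
MNC → SOC; MBC → SOC) are best-effort reconstructions of the published
figure — the exact set of non-significant gray arrows cannot be read
unambiguously — and are plain JSON intended to be edited.

## Synthetic surveys

The generator emulates the survey's conditions: 349 maize and 119 rice
sites; growing-season precipitation uniform in 450–1200 mm and temperature
in 4.6–10.3 °C; soil chemistry from crop-shifted truncated normals with
means near the reported crop summaries (e.g. MBC 0.13 vs 0.21 g/kg, BNC
1.22 vs 1.01, FNC 3.49 vs 2.91 mg/g for maize vs rice). Amino sugars and
extract TOCs are back-solved from the target pools, so the carbon-pool
stage has an exact inversion oracle; GalN is drawn independently since no
formula consumes it.

Counts follow a compound model: per-taxon log-normal latent abundances
(base log-mean N(0, 1.5²), latent SD 1.2) with block-factor correlation
(ten blocks of eight taxa at within-block ρ = 0.85 by default, allocated
across the merged 120-bacteria + 60-fungi list so some blocks span
domains), a per-taxon crop log-fold shift (N(0, 0.6) on a random half of
taxa, centered), then one multinomial draw per site at library size 20,000.
The blocks give the correlation screen strong edges; the shift gives
PERMANOVA a real crop signal. Compositional closure identifies the shift
only up to a common constant, so recovery checks compare centered log
relative-abundance ratios.

SOC is a linear combination of the Z-scores of the twelve predictors
(defaults: mnc 0.4, np_ratio 0.3, mbc 0.2, net_pc1 0.2, rest 0; residual
SD 0.7 on the standardized scale) mapped to g/kg by one global affine
transform (14 + 5·z, clipped far in the tail to stay positive). A single
global transform — not crop-specific intercepts — keeps the generating
model exactly the linear model the downstream stages fit, so averaged
coefficients are recoverable without omitted-variable bias. Four of the
twelve predictors (bacterial/fungal Shannon, network PC1/PC2) are latent
per-site attributes drawn directly rather than recomputed from the
generated count tables: this gives recovery tests an exact design matrix.
The latent values are persisted in `ground_truth.json` so fixtures
round-trip losslessly.

What the generator does **not** emulate: spatial autocorrelation,
sequencing-depth variation, taxon-specific overdispersion beyond the
log-normal, any feedback from community state to the SOC predictors
(diversity as drawn is independent of the realized count tables), or crop
differences in SOC beyond what the twelve predictors carry. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generating model, not predictive validity on real surveys.

## Problem sizes and numerics

Replicate studies use the survey's own sampling design (n = 468): 200
replicates for coefficient recovery and CI coverage, 100 for the suite
comparison, 1000 simulations for permutation-test calibration, and n = 2000
for path-coefficient recovery; graph metrics are validated against
brute-force enumeration on 200 random graphs with n ≤ 12 at 1e-10. The
ML-variance floor (1e-30), the PCoA positive-eigenvalue cutoff (relative
1e-12), the permutation tie tolerance (1e-12) and the SEM penalty value for
non-PD candidates (1e10) are the only magic numbers; each exists to make a
degenerate case well-defined rather than to tune results.
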