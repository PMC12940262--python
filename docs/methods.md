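# Methods

## Model

All regressions are phylogenetic generalised least squares (PGLS) analyses of
covariance. For breed *i* with body weight *wᵢ* and ancient indicator *aᵢ*
(modern is the reference level, so the indicator coefficient is the
ancient − modern contrast):

    g(yᵢ) = β₀ + β₁ f(wᵢ) + β₂ aᵢ [+ β₃ f(wᵢ)aᵢ] + εᵢ,   ε ~ N(0, σ²V)

The transform registry is fixed to three models: lifespan (years) on weight
(kg), both untransformed; the square root of mean litter size on natural-log
weight; and the natural log of cancer mortality rate (CMR, the proportion of
diagnosed deaths attributed to cancer) on natural-log weight, the CMR model
including the weight × breed-age interaction by default. Natural logarithms
are used throughout (configurable in principle via the transform registry;
the published slopes are only reproducible once a base is fixed, and e is
the default).

`V` is the Brownian-motion covariance of the time-scaled breed tree:
`V[i,j]` is the time from the root to the most recent common ancestor of
tips *i* and *j*, and the diagonal is the tree height. Pagel's transforms
distort it in the fixed order **κ → build V → δ → λ**:

- κ raises every branch length to the power κ (κ = 0: unit branches,
  punctuational change at divergences; κ = 1: identity). κ is applied to all
  branches, including the polytomy terminal branches.
- δ raises the entries of V to the power δ, then rescales the matrix so the
  largest diagonal entry keeps its pre-transform value. The rescaling keeps
  σ² estimates comparable across δ; without it, δ = 3 on a tree ~10⁴ years
  deep changes the scale of V by ~10⁸.
- λ multiplies the off-diagonal entries (λ = 0: star phylogeny / independent
  residuals; λ = 1: full Brownian expectation).

(1, 1, 1) is the identity end to end. All transformed matrices remain
symmetric positive semi-definite (for tree matrices the δ map corresponds to
transforming node heights, which preserves the nested structure); this is
property-tested against the eigenvalue tolerance `λmin ≥ −1e-8·trace`.

## Estimation

GLS is computed through the Cholesky factor V = LLᵀ: regressing L⁻¹y on
L⁻¹X gives β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂² = rᵀV⁻¹r/(n−k), standard errors from
σ̂²(XᵀV⁻¹X)⁻¹, two-sided p-values from t(n−k), and R²/overall F against the
V-weighted intercept-only model. Phylogenetic residuals are reported on the
decorrelated scale (L⁻¹r). Matrices that fail Cholesky but whose smallest
eigenvalue is within −1e-8·trace get a jitter of 1e-12·trace; anything worse
is an error. Coefficients, t, p, R² and F are invariant to positive scalar
rescaling of V (tested), so working in years rather than unit tree height is
immaterial.

When λ/κ/δ are estimated rather than fixed, each requested parameter is
profiled sequentially in the order κ, then δ, then λ (matching the common
default of sequential single-parameter optimisation in comparative-methods
software; the alternative of a joint grid gave identical results on our
synthetic checks and costs ~60× more likelihood evaluations). Each profile
is a grid scan at step 0.05 over λ ∈ [0,1], κ ∈ [0,3], δ ∈ (0,3], followed
by bounded scalar refinement around the best grid point (tolerance 1e-4).
The criterion is the multivariate-normal log-likelihood with the ML variance
σ̂²ML = RSS/n. A residual sum of squares below 1e-10·max(1, yᵀy) (noiseless
data) or a likelihood range below 1e-6 across the grid triggers a warning
and returns the parameter's boundary value.

The interaction test is the partial F between nested fits under the same V:
F = ((RSS_red − RSS_full)/df₁)/(RSS_full/df₂) on the decorrelated scale.
The Jarque–Bera statistic uses moment skewness and kurtosis with no
small-sample correction, JB = n/6·(S² + (K−3)²/4), referred to χ²(2); it is
location/scale invariant (tested) and requires n ≥ 8.

## Tree construction

The lineage table is a parent table, one row per named node
(`child,parent,divergence_time_years`), where the divergence time is the age
of the node named by `child` — 0 for breed tips, which are all
contemporaneous, making the tree ultrametric by construction. This
convention was chosen over encoding attachment times on edges because it
makes polytomies explicit (a node with more than two children) and
validation local (ages strictly decrease from root to tips; ties create
zero-length branches, which are nudged to 1e-6 yr with a warning). Cycles,
multiple roots, duplicate nodes and dangling internal nodes are errors.
Modern breeds are attached as a star under a designated clade node (default
name `modern`) whose height is forced to the modern terminal branch length
(default 200 yr); an `asian` node, if present, is likewise forced to the
Asian polytomy branch length (default 500 yr).

The bundled `synthetic_ancient_lineages.csv` is a **synthetic**
reconstruction of the ancient-breed lineage diagram: the seven ancient
breeds (basenji; Greenland sledge dog; dingo and New Guinea singing dog;
Tibetan mastiff, jindo and chow chow as the 500-yr Asian polytomy) on
plausible but not literature-exact dates (root 16 ka, Arctic split 9.5 ka,
Oceanian 8.5/5 ka, modern ancestor 3 ka). It exists so the pipeline runs end
to end without external data; analyses of real data should supply their own
lineage table or Newick tree. `synthetic_ancient_breeds.csv` is likewise a
non-biological placeholder used only in interface tests.

## Life-table analysis

Fitness is expected lifetime reproductive success LRS = Σ lₓmₓ over the
breeding window (ages 2–6 inclusive by default; mₓ = 0 outside it). Ages are
integer years, no interpolation. Fecundity from litter size uses the
litters-per-year distribution (82.2% one, 17.1% two, 0.66% three — the
proportions sum to 99.96% and are deliberately not renormalised, matching
the source's own products), i.e. mₓ = litter × 1.1838. When a life table
supplies an `lxmx` column it takes precedence over recomputing lₓ·mₓ,
because printed mₓ values are rounded to one decimal while the product
column carries four. LRS counts total offspring (no ÷2); a `per_daughter`
flag halves it for per-daughter accounting. The selection coefficient of an
improved survivorship schedule is s = ΔLRS/LRS_baseline, compared with the
drift threshold 1/(2Nₑ) at Nₑ = 100 (breed effective population sizes are of
this order); `favoured` is the strict comparison s > 1/(2Nₑ).

## Synthetic data generator

The generator emulates the study conditions: 104 modern + 7 ancient breeds;
weights log-uniform on 5–70 kg (spanning the 10–50 kg prediction range with
margin); a deterministic tree with the ancient breeds on a pectinate
backbone (node ages geometrically spaced from 16 ka down to 1 ka) and the
modern star at 200 yr; trait means linear in (transformed) weight within
breed-age groups with the published effect sizes as default β (lifespan
slope −0.0865, ancient offset +1.287; √litter slope 0.3435, offset −0.1778;
log-CMR modern slope 0.3187, interaction −0.9826 with the ancient line
crossing at 20 kg). Residuals are multivariate normal with covariance
σ²·V(λ,κ,δ)/max diag — the unit-diagonal scaling makes σ the residual
standard deviation on the transformed scale. Default σ: 1.0 yr (lifespan),
0.15 (√litter), 0.3 (log CMR), chosen to give standard errors of the same
order as the published fits at n ≈ 111. CMR is emitted as counts (diagnosed
deaths uniform on 100–600, cancer deaths binomial at the model proportion),
so the log transform, the zero-CMR exclusion and the CMR ≥ 1 resampling path
are exercised; simulated log-CMR values ≥ 0 are redrawn with a warning.

What the generator does **not** emulate: the real weight distribution of
registered breeds, birth-cohort censoring of lifespans, sparse/missing CMR
for ancient breeds (present only if the user blanks counts), the true
lineage dates, and any admixture structure. Passing tests therefore show
the estimator is correct under the assumed model at realistic sizes and
noise, not that the model assumptions hold for real kennel-club data.

## Problem sizes and numerical choices

Recovery and calibration checks use the sizes the package defaults to:
100 replicates for coefficient recovery and CI coverage on the 111-tip tree
(λ = 1 Brownian residuals, fitted under the generating V); 50 replicates per
regime for λ-identifiability (λ̂ ≥ 0.8 under λ = 1, λ̂ ≤ 0.2 under λ = 0);
1000 null simulations (40 tips) for the interaction-F type-I error and 500
simulations of n = 1000 for the Jarque–Bera rejection rate, both checked
against the [0.03, 0.07] band around the nominal 0.05. These sizes give
Monte-Carlo standard errors well inside the asserted bands while keeping the
whole suite fast.

Other conventions: strict `<` at the 20% ancestry boundary (exactly 0.20 is
excluded) and inclusive `≥` at 90%, following the printed inequality
symbols; ancestry values > 1 are auto-interpreted as percentages with a
warning; breeds with fewer than 10 genotyped individuals are accepted with a
logged warning. Breeds present in the trait table but absent from the tree
are dropped with a warning (the analysis runs on the intersection). The
published per-trait (λ, κ, δ) are shipped as pipeline defaults for the
fixed-parameter reproduction path; whether those values were originally
estimated jointly or sequentially is not documented, which is why both fixed
and `"ml"` settings are accepted per parameter per trait.

## Known limitations

- The bundled lineage dates are synthetic; covariances among ancient breeds
  in the bundled tree are illustrative only.
- The δ height-preserving rescale and the κ-then-δ-then-λ composition are
  conventions; other software may compose transforms differently, giving
  different σ² (though identical fits at (1,1,1) and identical λ-only fits).
- Profile ML at grid step 0.05 bounds the λ/κ/δ resolution at ~1e-4 after
  refinement; likelihoods that are multimodal between grid points could in
  principle be missed.
- The life-table module ingests survivorship; it does not derive lₓ from raw
  mortality records, and no Euler–Lotka growth-rate analysis is attempted.
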