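# Methods

## Data model

The central object is a samples × ASVs matrix of non-negative integer read
counts (`AsvTable`), joined to sample metadata (site, habitat ∈
{bacterioplankton, biofilm, soil}, occasion index, date, dendritic distance
from the upstream source in km, stream order) and to an environment table
keyed by (site, occasion). Sample identifiers are opaque strings; the
community–environment join always goes through the (site, occasion) key,
never through parsing of sample names. Dates are ISO-8601; the **occasion
index defines "consecutive"**, while the **date defines temporal distance
in days** — sampling intervals in repeated surveys are only approximately
regular, so both notions are needed. Missing environmental values are
explicit (NaN) and propagate through every statistic; they are never
imputed.

## Preprocessing

**Singleton filter.** An ASV is a singleton when its total count across the
whole data set is 1 (the common amplicon convention; a per-sample definition
would remove far more). A caller-supplied identifier list can be excluded
alongside, standing in for taxonomy-driven removal (mitochondria,
chloroplasts, unassigned) that happens upstream of this package.

**Rarefaction.** Depth defaults to the lower 5th percentile of per-sample
totals, computed by linear interpolation between order statistics and
floored to an integer. Each sample with at least that many reads is
subsampled **without replacement** (multivariate hypergeometric), one seeded
draw per sample; shallower samples pass through unchanged by default rather
than being discarded. A single rarefied data set — not an average over
draws — feeds all downstream analysis, so results are reproducible given
the seed. Each sample receives an independent substream of the seed, making
the draw independent of sample order.

**Rarefaction curves** use the analytic hypergeometric expectation
E[S_d] = Σ_i [1 − C(N−N_i, d)/C(N, d)], evaluated with log-gamma functions
so large totals do not overflow; tests verify agreement with Monte-Carlo
subsampling within 3σ.

**Environment.** Variables are z-scored (mean 0, sd 1, n−1 denominator)
per variable over **all** (site, occasion) rows, before any pairing or
subsetting; the alternative (standardizing within each regression's rows)
is a sensitivity the package does not currently expose. SUVA is absorbance
at 254 nm divided by DOC (dimensionless ratio by default; ×100 gives the
conventional L·mg⁻¹·m⁻¹ form — the choice is irrelevant downstream because
variables are standardized). Logger series (30-min temperature and water
level) are summarized as the arithmetic mean over the half-open 7-day
window preceding each sampling date.

## Temporal statistics

Bray–Curtis dissimilarity d_ij = Σ|p_i − p_j| / Σ(p_i + p_j) is computed on
relative abundances of the rarefied table (rarefy → normalize → distance);
computing on raw counts is exposed but non-default. Temporal β-diversity is
the mean of d over consecutive-occasion pairs (gaps reduce the pair count
and are logged). Temporal distance decay is the OLS slope of all pairwise
within-site dissimilarities on |Δt| in days (occasion lags are available;
days are the default because intervals are uneven). Environmental temporal
variability is the mean consecutive-occasion Euclidean distance on the
standardized variable set.

Soil–aquatic linkage at a site: similarity s_t = 1 − BrayCurtis(soil_t,
aquatic_t) for each occasion sampled in both habitats; reported are the
mean, the sd over all matched occasions, and — because "variation across
consecutive sampling times" admits two readings — also the sd restricted to
occasions participating in consecutive pairs. The all-times sd is the
default; both appear in the output. All sds use the n−1 denominator.

## Inference

**OLS** uses the exact least-squares solution with a two-sided t test on
the slope (n−2 df). **Partial regression** regresses y on the covariate z
and x on z separately, then regresses the y-residuals on the x-residuals —
the textbook residual construction matching a linear-model workflow.
Significance is flagged at p < 0.05 with no multiple-testing correction,
mirroring the solid/dashed convention of regression figures; a
Benjamini–Hochberg helper is provided but off by default.

**PERMANOVA** partitions squared dissimilarities: SS_total =
(1/N)Σ_{i<j}d²_ij, SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²_ij, pseudo-F =
(SS_among/(a−1))/(SS_within/(N−a)). The p-value permutes group labels
freely over samples (one-way design, no strata — a documented limitation;
the habitat contrasts here are one-factor) with p = (#{F* ≥ F}+1)/(P+1),
default P = 999 so the attainable minimum is 0.001. An exact mode
enumerates all distinct label arrangements on small instances. Tests verify
the pseudo-F against an explicit Gower-centering oracle and the permutation
p against full enumeration.

**NMDS** minimizes Kruskal stress-1 = √(Σ(d̂−d)²/Σd²) where d are
configuration distances and d̂ the isotonic (pool-adjacent-violators) fit
to the rank order of the input dissimilarities; ties are handled by the
primary (weak) approach, ordering tied dissimilarities by current
configuration distance. Optimization is SMACOF-style Guttman majorization;
after each update the configuration is rescaled to unit rms distance
(stress-1 is scale-invariant, and without renormalization the iteration
contracts toward the origin). A step that would increase stress terminates
the run, so the recorded stress sequence is non-increasing by construction.
Defaults: k = 2, 20 restarts (the first from classical metric scaling, the
rest random under the seed), 300 iterations, tolerance 1e-7 on the stress
change; the best final configuration is returned and is bit-reproducible
given the seed. Group centroid distances are Euclidean distances between
coordinate means in the ordination space (solution-dependent: they inherit
the ordination's rotation/scale indeterminacy and should be read
comparatively, not absolutely).

## Shared-ASV analysis

"Occurrence" means count > 0 **after** rarefaction by default (presence
detection is depth-sensitive; a pre-rarefaction option exists). For each
aquatic sample, the shared count is the number of its ASVs present anywhere
in the partner habitat's samples of the same site (any occasion). The
shared fraction divides the site mean by the focal habitat's total distinct
ASV pool across the whole data set. Site means are regressed on dendritic
distance per habitat pair. Taxon-group summaries report both the raw mean
relative abundance per group (share of whole-sample reads, restricted to
the ASV set) and the within-set renormalized share.

## Synthetic generator

The generator emulates the output of an amplicon workflow over a dendritic
design — it produces count tables, not reads. Defaults mirror the study
scale: 13 sites (5 first-order headwaters, 5 second-order, 3 third-order;
maximum dendritic distance 9.8 km on a fixed tree whose leaves are
headwaters), 7 occasions at roughly two-week spacing, 3 habitats, 800-ASV
pool split into soil-associated (45%), aquatic-generalist (35%) and
biofilm-specialist (20%) guilds, and log-normal read depths (median ≈ 7800,
sd 0.5 on the log scale, floor 2239) so that rarefaction at the lower 5th
percentile with passthrough is exercised realistically.

Mechanisms, in the order the statistics detect them:

* **Soil**: site-specific soil-guild-dominated log-abundances with
  mean-reverting AR(1) innovations (ρ = 0.6) whose sd is 0.7·τ_s, where τ_s
  is a per-site lognormal factor (sd 0.6) that also scales the soil
  environment's temporal noise — producing the soil-β ↔ soil-environment
  coupling with no network trend. (A pure random walk instead of AR(1)
  lets high-τ sites collapse onto a few taxa within seven occasions, which
  is neither realistic nor stationary.)
* **Bacterioplankton**: at occasion t, a mixture w_soil·soil + (1−w_soil)·
  [λ·(mean of immediate upstream plankton) + (1−λ)·core], with
  w_soil = min(0.85, 0.8·R_t·e^{−dist/2 km}) and R_t a single network-wide
  half-normal rainfall pulse per occasion (scale 1.0). Fluctuating pulses
  make headwater composition swing between soil-dominated and core states
  (high turnover); the exponential decay plus dilution through successive
  junctions (λ = 0.5, equal weights over upstream neighbours) removes the
  signal downstream and carries ever-fewer soil taxa along the flow path.
  A per-taxon lognormal jitter (sd 0.35) is the water column's baseline
  noise.
* **Biofilm**: a selection kernel e^{4·trait} (trait +1 for biofilm
  specialists, 0 for aquatic generalists, −1 for soil taxa) applied to the
  local water column, with AR(1) log-noise whose innovation sd grows with
  distance (0.35 + 0.08/km). The kernel filters the soil pulses out —
  biofilm composition is largely independent of the overlying taxa pool —
  so its turnover gradient is set by the noise gradient, opposite in sign
  to bacterioplankton's.
* **Environment**: chemistry innovation variance declines roughly linearly
  with relative network distance, physical (temperature/level) variance
  increases, soil variables follow τ_s.

Counts are multinomial draws from the latent compositions. What the
generator does **not** emulate: PCR/primer bias, chimeras, overdispersion
beyond multinomial sampling, taxonomy errors, hydrological routing
(discharge-weighted mixing), or site-specific rainfall. Passing the
recovery tests therefore shows the statistics detect these mechanisms at
realistic effect sizes and depths — not that real data meet the generator's
assumptions.

Noise scales were fixed so that site-level mean turnover falls in the
0.3–0.5 range typical of repeated microbial surveys while the dendritic
gradients remain detectable at n = 13 sites; they are ordinary config
fields, and the recovery tests run at exactly these defaults.

## Numerical and design choices

* Bray–Curtis pairs of all-zero rows are an error naming the samples, not a
  silent 0/0.
* Environmental distance pairs with any missing variable are NaN and are
  excluded pairwise with a logged count.
* The percentile depth floors the interpolated value so it is a valid
  integer subsampling depth.
* The pipeline consumes a processed ASV table; read processing
  (denoising, taxonomy) is out of scope and handled by established
  upstream tools.
* Replicate pooling is not modelled: the data model assumes one sample per
  (site, habitat, occasion).
* The report JSON is canonicalized (sorted keys, native float repr), so
  identical inputs, seed and configuration yield byte-identical reports.

## Problem sizes used in validation

Oracle-equivalence tests use ≥100 random small instances per kernel;
permutation exactness uses full enumeration at N ≤ 7; type-I calibration
uses 1000 OLS and 400 PERMANOVA null replicates; parameter recovery uses 20
replicate data sets at the default configuration plus 20 with the rainfall
pulse ablated, with the pool reduced only where a test needs many replicate
PERMANOVAs. These sizes give binomial/Monte-Carlo error bars comfortably
inside the asserted margins.
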