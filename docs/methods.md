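# Methods

This note records the models, defaults and numerical choices behind
`srphos`, and what the synthetic benchmarks do and do not demonstrate.

## Data model and preprocessing

Phosphosite tables follow the MaxQuant "Phospho (STY)Sites" TSV dialect:
one row per site isoform (multiply-phosphorylated isoforms are kept as
distinct rows, since no collapsing rule is universally agreed), `+`
flags for reverse-database and contaminant rows, and zero-filled
intensities for absent quantifications. Zero intensities are read back
as *missing*: in label-free data a zero is a failed quantification, not
a measured zero, and treating it as a value would corrupt the MNAR
imputation downstream. Files are UTF-8, tab-separated, `.` decimal;
floats are written via `repr` so a parse/write cycle is byte-identical.

Filtering removes reverse and contaminant rows and sites below the
Class I localisation confidence. The threshold is **inclusive**
(≥ 0.75): a site at exactly 0.75 is kept. `min_loc_prob` is
configurable for users who prefer the strict reading.

**Quantile normalization** equalises the intensity distribution across
samples within a *normalization group*. Global (whole-lysate) and
proximal (streptavidin + phospho double-enriched) samples form separate
groups and are never co-normalized, because the double enrichment
left-shifts the proximal intensity distribution; forcing both onto one
reference would manufacture intensity differences. Within a group the
rank-r value of every column becomes the mean of the rank-r values
across columns; ties receive the average of their tied ranks' means
(deterministic, limma-style); missing cells are excluded from ranking —
each column is mapped through its own observed quantiles onto a common
reference grid — and remain missing. On complete data the transform is
idempotent.

**Imputation.** Two left-censoring models are provided:

- `impute_downshift` (trafficking arm default): each missing cell in
  column c is drawn from N(μ_c − shift·σ_c, (width·σ_c)²) with
  shift = 1.8 and width = 0.3, the conventional defaults for
  downshifted-normal imputation of label-free data. Moments are the
  column's observed mean/sd (ddof = 1); at least 3 observed values per
  column are required.
- `impute_qrilc` (SRP arm default): per column, the latent normal's
  (μ, σ) are estimated by regressing the sorted observed values on
  standard-normal quantiles at plotting positions
  p = f + (1 − f)·(i − 0.375)/(n + 0.25), where f is the missing
  fraction — i.e. the observed data are treated as the upper (1 − f)
  tail of a censored normal. Draws come from that normal truncated
  above at the censoring point μ + σ·Φ⁻¹(f).

Observed cells are never modified; the imputed mask records exactly the
formerly missing cells; fixed seeds make both methods deterministic.

**z-scores.** Each site row is standardized across samples with the
*sample* standard deviation (ddof = 1); the convention matters only at
tiny sample counts but is recorded here because published tools differ.
Zero-variance rows are dropped with a warning. Replicate-level z-scores
feed the ANOVA gate; per-condition medians of the z-scores feed
clustering and transfer.

## Response clustering and label transfer

The **ANOVA gate** runs a one-way fixed-effects ANOVA per site across
conditions on replicate z-scores. Both a Benjamini–Hochberg-adjusted
and a raw-p threshold are supported (`adjust='bh' | 'none'`); the
pipeline config defaults to the raw-p reading at α = 1e-4. A caution
worth recording: with three replicates per condition the per-site F test
has only 8 error degrees of freedom, so even a 4-fold (2 log2-unit)
response over 0.3 log2 units of noise passes p < 1e-4 only ~60% of the
time — the gate at this α is *selective*, not exhaustive, and
sensitivity claims must be read against that power ceiling. The gated
subset it does retain is almost pure signal, which is what the
downstream clustering needs.

**Fuzzy c-means** is the Bezdek formulation with Euclidean distance:
memberships u_ik = 1/Σ_j (d_ik/d_jk)^{2/(m−1)}, centroids the
u^m-weighted means, objective Σ u_ik^m d_ik². Defaults: fuzzifier
m = 2.0, tol 1e-6 on centroid movement, 200 iterations max, best of 10
restarts initialised from distinct data rows (tiny jitter splits
coincident rows). Distances are normalised by the row minimum before
exponentiation so small fuzzifiers cannot overflow; a point coinciding
with a centroid gets a one-hot membership. Ties in the hard assignment
break to the lowest cluster index. The objective is non-increasing
across iterations and is verified against a brute-force recomputation
in the tests.

**Response taxonomy.** With Δ = centroid(FGF10_GFP) − centroid(UT), a
cluster is FGF10-regulated iff |Δ| ≥ `reg_margin` (default 0.5 median-z
units). A perturbation *preserves* the response iff its same-direction
change from UT retains ≥ `preserve_frac`·|Δ| (default 50%). membrane =
both dominant negatives preserve; internalisation = DnDNM2 dysregulates
while DnRAB11 preserves; recycling = both dysregulate; anything else is
`other`. Both margins are analysis choices — the original assignment of
response names to clusters was done by inspection — and are exposed in
the config.

**Parzen transfer.** Class-conditional Gaussian product-kernel
densities with per-class, per-dimension Scott bandwidths
σ_d·n^{−1/(d+4)} (Silverman and fixed available; bandwidths floored at
1e-3 to survive degenerate dimensions), priors = class frequencies,
posterior ∝ prior·density computed in log space. With point-mass
classes and equal bandwidths the classifier reduces to nearest
neighbour, which the tests verify.

## Proximal (SRP) contrast

`reference_normalize` summarises replicates by their **median** and
subtracts the GFP-APEX2 reference median at the matched treatment and
timepoint, giving log2 ratios per (bait, treatment). The operation is
shift-equivariant to numerical precision (~1e-12; exact bitwise equality
is not achievable for float addition).

`extract_recycling_cluster` clusters the ratio rows agglomeratively and
cuts the dendrogram into `k_cut` clusters (a required analysis choice —
the delimitation of the published cluster was not algorithmic). A cut
cluster joins the recycling proximal signalling set iff its centroid
exceeds `min_up` (default 0) in **both** FGF10 bait columns *and*
exceeds the matching UT centroid in both baits; the output is always a
union of whole cut clusters. The default linkage is **Ward**: on the
synthetic benchmark, complete linkage — though the classical default of
R's `hclust` — produces cut clusters that absorb single-bait sites into
the double-enriched cluster and its precision is unstable across seeds,
while Ward's variance-minimising merges keep the cut clusters pure.
`linkage='complete'` remains available.

`global_fgf10_up` selects FGF10-responsive sites in the global samples
with an empirical-Bayes **moderated** two-sample t-test: the pooled
per-site variance is shrunk toward the across-site mean variance with
`prior_df` = 4 prior degrees of freedom (limma-style), the statistic is
referred to t with `prior_df` + n₁ + n₂ − 2 df, BH across sites, and
sites additionally need a mean difference ≥ `min_log2fc`. Plain Welch
at n = 3 loses ~25% of genuine 4-fold responders; moderation restores
them without inflating the null (verified by simulation in the tests).

## Enrichment and networks

ORA uses the one-sided Fisher exact test in its hypergeometric-tail
form: p = P(overlap ≥ a) for a foreground of size n drawn from the
background with |set ∩ background| successes, BH across sets, rows
sorted by (q, p). The background should be the quantified proteins of
the experiment, not the genome — detection bias otherwise masquerades
as enrichment; `compartment_summary` defaults to the union of
compartment annotations plus the query. The subnetwork filter keeps
edges with experimental confidence **strictly** greater than the cutoff
(default 0.4); edge lists are canonicalised (undirected, self-loops
dropped, duplicate edges keep max confidence); nodes without surviving
edges stay in the graph as isolated nodes.

## Imaging statistics

The **à-trous wavelet** uses the separable B3-spline kernel
[1,4,6,4,1]/16 with holes dilated by 2^j and mirror boundary; detail
plane w_{j+1} = c_j − c_{j+1}. The planes plus the final smooth
reconstruct the input exactly (machine precision), which the tests
assert at 1e-9. The bandpass drops the finest plane (single-pixel
speckle) and the residual smooth (background). The function signature
defaults to 4 levels; the analysis chain passes `n_levels=5` because
the passband must cover the punctum scale — with σ ≈ 2 px puncta a
4-level transform leaves part of the punctum energy in the discarded
smooth plane and biases intensity-weighted coefficients. Negative
bandpass coefficients are clipped to zero before positivity-based
statistics, otherwise the sign of a product pixel is meaningless.

**Costes thresholds**: channel B is regressed on A by total least
squares (principal axis of the centred cloud); the pair
(T, slope·T + intercept) is scanned down from max(A) in 1/255 steps
until the Pearson correlation of the pixels below both thresholds is
≤ 0. An empty or zero-variance below-threshold subset counts as
uncorrelated and stops the scan — so anti-correlated channels stop at
the first step (thresholds at max, nothing colocalized) and noiseless
identical channels run down to the minimum positive intensity.
Thresholds are clamped to [0, 1]. On independent-noise channels the
outcome fluctuates with the sample correlation of the realisation;
claims about background classification are therefore made on medians
over several realisations.

**Manders** numerators require the reference channel above its own
threshold (M1 sums A over pixels with A > t_A *and* B > t_B); 0/0 is
defined as 0. OF counts ROI pixels with strictly positive channel
product. Vesicle counting binarises strictly above the 8-bit threshold
(default 50) and counts 8-connected components of ≥ `min_size` pixels
per DAPI nucleus.

## Synthetic data: what it emulates, and what it does not

The phosphoproteome generator plants four archetypes with the condition
structure of the two designs: membrane sites respond to FGF10 under
every perturbation; internalisation sites lose the response under
DnDNM2; recycling sites lose it under both dominant negatives; null
sites never respond. In proximal designs the recycling archetype is
enriched near both baits, internalisation near FGFR2b only and membrane
near RAB11 only, so "up in both baits" identifies exactly the recycling
archetype. Defaults describe the emulated study: base log2 intensity
N(23, 1.5²), effect 2 log2 units, replicate noise 0.3, three
replicates, 10% overall missingness, proximal left-shift 1 log2 unit,
5% decoy rows, 10% of sites below the Class I threshold. Missingness
is logistic in the latent log2 intensity (steepness 0.5 log2 units)
with the midpoint solved by bisection so the expected rate matches the
request — a sharp detection-limit model of MNAR censoring.

The image generator draws isotropic Gaussian puncta truncated at 3σ
with centres at least 2·⌈3σ⌉ + 1 px apart (supports never touch), a
chosen fraction of channel-B centres shared with channel A, additive
Gaussian read noise, clipping and quantisation. True M1/M2/OF are
computed from the noiseless images at zero threshold and equal
brute-force pixel sums by construction.

Passing the synthetic benchmarks shows the algorithms recover planted
structure under this generative model. Real data violate it in ways
the benchmarks do not probe: correlated site effects within proteins,
batch effects, heteroscedastic noise, non-Gaussian intensity
distributions, mixed-archetype kinetics, optical aberrations and
non-Gaussian PSFs. Quantile normalization also mildly distorts
site-level contrasts when a large fraction of sites shift in one
condition — visible even in the synthetic runs — which is a property of
the method, not of the implementation.

## Problem sizes and determinism

The shipped benchmarks use 2000 sites × 12–18 samples per arm, 128²–192²
images and ≤ 500-member ORA universes; each arm runs in seconds on one
CPU, and the whole acceptance script in well under a minute. Every
stochastic step takes an explicit seed; pipeline runs write a manifest
with a SHA-256 hash per output file, and reruns with the same config and
seed are byte-identical.

## Known limitations

- `k_cut` and `min_up` must be chosen by the analyst; no automatic
  model selection for the number of clusters (fuzzy or hierarchical) is
  provided.
- The Parzen classifier has no reject option: sites unlike any training
  cluster still receive a label (with a low posterior).
- QRILC moment estimation assumes an underlying normal column
  distribution; heavy tails bias σ upward.
- Costes thresholding is known to be unstable when channels are nearly
  uncorrelated; downstream coefficients should be read together with
  the thresholds.
- 2-D colocalization only; no deconvolution or nucleus segmentation
  (nuclei counts are user inputs).
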