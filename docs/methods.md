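# Methods

This note documents the models, parameter choices and numerical conventions
behind `finerange`, and what the synthetic-landscape tests do and do not show
about real data.

## The synthetic landscape

The generator emulates the statistical structure the analysis assumes, not
any particular place.

**Terrain.** A long-wavelength Gaussian random field is rank-normalized and
passed through a logistic ramp between the valley floor (default 1000 m) and
the plateau level (default 3000 m). The ramp's flat tails produce valley
floors and summit plateaus; its steep middle produces flanks whose slope
peaks at mid elevation — the hypsometry of dolomitic massifs, which is what
drives the velocity findings. Summit heights vary across massifs (plateau
level reduced by up to 25% of the relief via a second smooth field) so the
coldest climates are spread over several distinct levels; without this,
nearest-analog search degenerates because the entire summit climate
disappears under warming. Three octaves of smoothed noise (~1% of relief)
roughen the surface.

**Climate.** 19 layers on the coarse grid (default 20 × 20 fine cells ≈ 1 km
on a 50 m analysis grid): 7 temperature-like layers decreasing with
elevation at a configurable lapse rate (default 6.5 K/km) plus smooth noise
(sd 0.3 K); 8 precipitation-like layers with an orographic elevation term
and a shared smooth *wetness* field independent of elevation (30% of the
layer mean); 4 mixture layers blending both. The wetness field matters: it
gives the pooled PCA a genuine second (moisture) axis with spatial
structure, as real bioclim data have. Future scenarios add a per-RCP warming
offset (default 2.2 K for rcp45, 4.3 K for rcp85 — mid-century/late-century
Alpine-scale magnitudes) scaled by each layer's temperature share, plus a
per-GCM, per-layer scalar jitter (sd 0.25 K) for five pseudo-GCMs.

**Geology and species.** The carbonate mask thresholds a smooth random field
at the requested areal fraction (default 0.7). Virtual species have Gaussian
niches in (PC1, PC2) space; occurrences are sampled with probability
proportional to suitability and jittered within cells. The demo community
places niche centers on the cold side of the baseline PC1 distribution
(15th/40th/25th percentiles) with breadths of ~0.8–0.9 baseline-PC1 sd —
narrow endemics with coherent ranges covering roughly a quarter of the
landscape. One species has only 31 occurrences so cell-thinning can push it
under the "> 30 occurrences" modelling floor.

**What passing tests show.** Parameter recovery on this landscape shows the
pipeline's machinery is correct and well-calibrated when its assumptions
hold (climate fully determines suitability, occurrences are an unbiased
suitability-weighted sample, geology is known exactly). It does not show
robustness to sampling bias, biotic interactions, dispersal limitation or
niche truncation — all absent from the generator.

## Terrain metrics

Slope and aspect use Horn's 8-neighbour stencil; the one-cell border is
nodata. **Aspect is the upslope (gradient) azimuth, clockwise from north**:
a plane rising eastward has aspect π/2. Flat cells get aspect 0 and are
flagged. Northness/eastness are cos/sin of that angle; the sign convention
(opposite to the GIS downslope convention) is irrelevant to the GWR fit.
TRI is the mean absolute elevation difference to the existing neighbours
(3–8 at borders; this keeps border cells valid rather than nodata). TCI is
the 3D/2D surface-area ratio per coarse block, computed as the NaN-aware
block mean of 1/cos(slope); flat terrain gives exactly 1 and a uniform 45°
plane exactly √2. In the pipeline, where only one DEM resolution exists, TCI
is computed over 5 × 5-cell (250 m) blocks and nearest-neighbour-resampled
back to the 50 m grid; with a finer DEM available, `tci()` accepts any
fine-in-coarse factor (e.g. 10 m in 50 m). The irradiation proxy is the
clear-sky noon-incidence geometry at the configured latitude (default 46°),
clipped at 2% of flat-terrain irradiance so self-shaded cells stay positive.

## Climate axes and downscaling

The PCA is fitted once on all scenarios pooled (cells × scenarios rows),
after centring and scaling each variable on the pooled sample — bioclim
units are heterogeneous, and without scaling precipitation variance would
dominate. Constant layers are dropped with a warning. Sign conventions: PC1
is oriented to correlate positively with the mean temperature-like layer;
PC2's largest-magnitude loading is made positive. Projection uses the shared
loadings, so axis values are comparable across scenarios and the
decomposition is scenario-order invariant.

GWR downscaling fits, at every coarse cell, a weighted least-squares
regression of the axis on the five block-averaged topographic predictors
with a Gaussian distance kernel. The default bandwidth is **1.5 coarse cell
widths**: local enough that the block-averaged downscaled field reproduces
the coarse field to within a few percent (measured 5–7% relative RMSE on
the demo landscape, vs 14–20% at 3 cell widths, which over-smooths at desk
scale), while still pooling each cell's immediate neighbourhood. The kernel
is widened locally (×1.5 steps) until the Kish effective sample size reaches
predictors + 2; locally constant predictors are dropped; a rank-deficient
local design falls back to the kernel-weighted mean with a warning. Fine
cells whose predictors are undefined (the slope border) use their coarse
block means, so output coverage equals coarse coverage. A planted linear
elevation signal is recovered essentially exactly (the local WLS interpolates
a zero-residual fit).

## Ensemble SDMs

Base learners (scikit-learn, fixed hyperparameters): GLM = unpenalized
logistic regression on linear + quadratic axis terms; GAM = logistic
regression on cubic-spline bases (5 knots per axis); GBM = gradient-boosted
trees (100 rounds, depth 3, learning rate 0.1); RF = 200 trees, min leaf 2;
CTA = one depth-8 tree, min leaf 5. The bespoke content of the package is
the sampling/evaluation/threshold/consensus machinery around them.
Pseudo-absences are uniform over non-presence cells: 10 000 × 3 sets for the
regression families, n-presences × 10 sets for the tree families (the
standard recommendations for each family class); on small demo grids the
regression-family count is capped at half the free cells. Presences and
pseudo-absences are equally weighted. Each pseudo-absence set is evaluated
by 10 stratified 70/30 splits; AUC (midrank Mann–Whitney form) and TSS are
computed only on the held-out 30%, with cutoffs derived from the training
scores. One suitability map per (family, scenario) is the mean over the
per-set refits on the full data; the cutoff per (family, rule) is the median
over CV repeats, then over sets. All sub-seeds derive from the master seed
via CRC32 of named labels, so reruns are bit-identical.

## Binarization, consensus, range accounting

Cutoff candidates are the distinct observed scores plus {0, 1}; among
equally optimal candidates the smallest is returned; binarization is
suitability ≥ cutoff (boundary = presence). Consensus pools all projections
of one climate (15 baseline; 75 per RCP) and declares presence at ≥ 50% of
non-nodata votes (exact ties count as presence). The geology mask is applied
after the vote (it commutes with it). Per-combination RC/RL/RG statistics
use single-model binarizations after masking; the headline category map uses
the consensus maps. PR = 0 for a combination means that model projects no
baseline range; such combinations are excluded from the summary. Gains are
counted over the whole masked study area (unlimited-dispersal reading).

## Climate-change velocity

The two fine-grid axes are binned on an equal-width 12 × 10 grid (120
classes) spanning the pooled baseline ∪ future ranges, per GCM. Each cell's
distance to the nearest future cell of its baseline class is a KD-tree query
(verified exactly against an all-pairs oracle); classes absent from the
future are flagged no-analog, not numeric. Velocity = max(distance, half a
cell width)/Δyears — the floor keeps log10 finite for self-analog cells —
and CCV = 100·log10(velocity). Δyears defaults to 74 (midpoint 1996 of a
1979–2013 baseline to midpoint 2070 of a 2061–2080 horizon; 75 is accepted
via config). GCM averaging happens on the CCV (log) scale; a cell is
no-analog in the average only if every GCM lacks an analog.

## Category statistics

Kruskal–Wallis uses the tie-corrected H with the chi-square approximation at
all sample sizes (matching the default of the standard R functions);
pairwise Mann–Whitney tests are two-sided with Bonferroni multiplication
capped at 1. The robustness procedure subsamples each category without
replacement (10%, 1%, or min(n, 1000) cells) 1000 times and counts
significant Kruskal–Wallis replicates at α = 0.05; categories too small for
a scheme keep all their cells, with a warning.

## Problem sizes and defaults

The demo pipeline runs a 160 × 160-cell fine grid (8 × 8 km at 50 m) with an
8 × 8 coarse climate grid, 5 GCMs × 2 RCPs, three virtual species and 1000
robustness replicates — a landscape large enough to exhibit the
plateau/mid-slope velocity contrast and elevation-structured range loss,
and small enough to run in a few minutes on one CPU. Every default above is
a `LandscapeConfig`/`PipelineConfig` field.

## Known limitations

- Pseudo-absence counts per family follow the general recommendations, not
  any study-specific table; they are configurable.
- No model-quality filter is applied before ensembling (all 165 projections
  vote regardless of AUC/TSS).
- The velocity bin-grid shape (12 × 10), the no-analog treatment and the
  zero-distance floor are documented conventions; only the total of 120
  bins is canonical.
- Statistical tests are not adjusted for spatial autocorrelation beyond the
  subsampling robustness procedure.
- The published per-species range-change table used for the internal
  consistency check contains one row whose printed RC differs from RG − RL
  by 0.03 (beyond its printed precision); the corresponding check reports
  the discrepancy rather than hiding it.
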