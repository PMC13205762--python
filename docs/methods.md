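# Methods

## Nested accumulation construction

All scaling models operate on an accumulation surface built per plot
(site × treatment). Sampling points are partitioned into L nested area
levels (level j's point set strictly contains level j−1's); months form the
temporal axis. Under the default **nested** method, the cell (j, T) holds
the diversity of the union of taxa observed over the points of levels 1..j
and months 1..T — time is treated exactly like nested area, so richness and
PD are monotone non-decreasing along both axes by construction. A taxon
counts as present at any read count > 0; no minimum-count threshold is
applied.

Two alternative temporal constructions are provided: **complete-nested**
(for each window length T, the mean cumulative diversity over all K−T+1
consecutive windows; at T = K it coincides with the nested terminal value)
and **temporal islands** (each independent survey contributes one (duration,
richness) point).

Faith's phylogenetic diversity is the branch-length total of the union of
root-to-tip paths of the observed taxon set — the root-inclusive convention,
matching common picante behaviour; `include_root=False` switches to the
MRCA-spanned subtree. Internally PD over many cells uses a precomputed
edge × taxon incidence matrix, and the implementation is cross-checked
against scikit-bio's `faith_pd` in the test suite.

Missing (point, month) samples are a hard error by default (the designs this
package targets are complete); a permissive mode skips them with a warning.

## Depth standardization (passive-sampling control)

Because larger spatial/temporal pools contain more reads, richness–scale
relationships could be pure sampling artifacts. `standardize_depth` rarefies
each scale's pooled counts to a common depth without replacement
(multivariate hypergeometric, default 100 replicates, seeded) and reports
the closed-form expected rarefied richness
`E[S] = Σ_i (1 − C(D−x_i, d)/C(D, d))` alongside the Monte-Carlo mean.

## Scaling models

SAR/PAR/STR/PTR are ordinary least squares in natural-log space; the
STAR/PTAR interaction model regresses ln(response) on
[1, ln A, ln T, ln A·ln T]. Fits are closed-form (`numpy.linalg.lstsq`) so
they can be repeated thousands of times inside permutation loops; agreement
with statsmodels OLS is asserted in tests. Fits are performed in base units
(m², months). Converting a fitted model to other units uses the exact
change of log-variables (ln A_old = ln a + ln A_new):

    z' = z + u ln t,  w' = w + u ln a,  u' = u,
    b' = b + z ln a + w ln t + u ln a ln t,

under which the equivalence ratio exp((z−w)/u) transforms exactly as
ratio·t/a. Both routes — refitting in converted units and post-hoc
conversion — are therefore equivalent, and the tests assert it.

Degenerate designs raise errors rather than returning NaNs: a single
distinct area or time is a rank-deficiency error; a constant response in the
single-variable fit returns slope 0 and R² 0 with a `degenerate_` flag. The
equivalence ratio is undefined at u = 0 (error) and flagged unstable when
|u| < 1e−6.

## Block-permutation inference

Accumulation cells are serially dependent along both axes, so model
significance uses restricted block permutation: the ordered scale labels of
each axis are grouped into intact blocks of 3 consecutive scales (a trailing
remainder block of 1–2 scales stays intact), block orders are shuffled
independently on the two axes, and the model is refit with the relabelled
design. The permutation acts on the scale labels of the built surface —
i.e. on the assignment of (A, T) values to accumulated diversity values —
not on raw samples. p-values use (1 + #extreme)/(1 + R), always in (0, 1]:
upper-tail for R², two-sided on magnitude for exponents. Degenerate null
fits are discarded and counted. Measured on 300 structureless (i.i.d.
log-response) surfaces with 199 permutations each, the empirical type-I
error at nominal 0.05 is 0.05.

**STAR vs PTAR exponent contrasts.** Both models share one log-log design,
so the exponent difference equals the corresponding coefficient of a single
OLS fit to the cell-wise difference surface ln S − ln PD. Its null is built
by restricted residual permutation (Freedman–Lane): residuals of the reduced
model (the difference fit without the tested term) are permuted in intact
scale blocks along both axes, the full model refit, and the coefficient
recorded; two-sided p on the magnitude. A direct block-wise swap of the two
response labels was evaluated and rejected during design: intercept and
spatial-exponent differences between the responses leak into block-restricted
swaps and inflate the null spread to the point of zero power, whereas the
residual-permutation construction measures power ≈ 1 at a w-gap of 0.035
under noise 0.02 while keeping empirical type-I ≈ 0.035 and returning
p = 1 exactly for identical responses.

## Moving windows and effect sizes

Window families traverse all window sizes 5–14 months at step 1 (a K-month
series gives K−s+1 windows of size s; 85 per plot per response at K = 17).
Within a window the nested accumulation restarts at the window's first
month, so each window yields an independent STAR (and PTAR) fit tagged with
window size, start (`ystart`), plot, and site.

Treatment and soil-texture contrasts on window-family exponents use a linear
mixed model with nested random intercepts (window size as grouping factor,
site and plot as nested variance components). The specified residual
structure also includes an AR(1) correlation indexed by `ystart`; the
statsmodels backend does not support AR(1) residuals, so the model falls
back to the nested-intercepts structure and flags the omission in the
result note. Non-convergent fits fall back to OLS, flagged. Complementary
effect sizes: the ln-response ratio ln(mean_t/mean_c) with delta-method
variance s_t²/(n_t·m_t²) + s_c²/(n_c·m_c²), and pooled-SD Cohen's d.
Correlation screens (e.g. scaling rates vs trait or heterogeneity tables)
use Spearman's rho with Benjamini–Hochberg adjustment across the whole
tested family; constant vectors yield flagged undefined records excluded
from the family.

## Traits and heterogeneity

rrn copy numbers are matched against an rrnDB-style reference from the
query's lowest resolved rank upward: all reference rows carrying the name at
that rank are averaged (child-mean); failing that, ranks are ascended to a
parent-taxon mean; taxa unmatched at every rank are flagged and excluded
from community aggregation (numerator and denominator — renormalization).
The community-level trait is the relative-abundance-weighted mean
Σ S_i n_i / Σ S_i, bounded by the trait extremes and invariant to count
rescaling.

Heterogeneity is a coefficient of variation with sample (n−1) standard
deviations throughout: spatially sd/mean across points at one timepoint;
temporally the sd of residuals from an OLS regression on the integer time
index divided by the raw series mean (detrended CV — an exactly linear
series scores 0). Temporal stability of a richness series is the inverse
CV, mean/sd; a constant series is flagged infinite.

## Sloan neutral community model

Per timepoint, each taxon's occurrence frequency across the plot's local
communities is compared with the neutral expectation
1 − BetaCDF(d; Nmp, Nm(1−p)), with p the taxon's mean relative abundance,
N the mean per-sample read depth (overridable), and detection limit
d = 1/N (the standard convention). m is estimated by bounded scalar least
squares on (1e−6, 1]; R² = 1 − SSE/SST may be negative. The generative
sampler draws each local relative abundance from the stationary Beta and
realises ⌊N·x⌋ individuals — the Beta already embodies finite-community
sampling noise, so no extra read-level noise is layered on top. Recovery at
m = 0.1, N = 1000, 50 communities: median relative error ≈ 0.19 over 20
replicates. Known limitation: m̂ is biased upward at large m (true 0.3
recovers ≈ 0.48) although the ordering across an m-grid is preserved;
estimates at large m should be read comparatively, not absolutely.

## Synthetic-data generator

The generator emulates a nested field survey: a regional pool of
log-normal abundances (shape `abundance_sigma`, default 1.5); a per-taxon
spatial log-abundance field over the plot's points with exponential-kernel
correlation exp(−`spatial_decay`·distance) (default 0.05 per metre, so
composition decays smoothly with distance; decay 0 means identical expected
composition everywhere); a plot-level Markov temporal field in which each
taxon's state is replaced with probability `temporal_turnover` per month
(default 0.25), initialised from the chain's stationary distribution; and
multinomial read sampling at Poisson depth (`depth_mean`, default 10,000).
Field magnitudes `spatial_sd` (1.0) and `temporal_sd` (2.5) set how strongly
the fields shape composition. The `homogenization` knob shrinks both the
spatial field (toward the point mean) and the temporal field (toward the
time mean) by the given fraction, emulating the loss of spatial and
temporal environmental heterogeneity under intensive monoculture; at 1 every
point of a plot carries one static composition.

Defaults were chosen so that a default single plot reproduces the scaling
magnitudes reported for soil bacterial communities in nested field surveys
of this kind — STAR z ≈ 0.15, w ≈ 0.36, u ≈ −0.04, model R² ≈ 0.88 — and
the default design is 2 sites × 2 treatments × 21 points × 17 months
(1,428 samples) with nested area levels of 1, 4, 16, 64, 256 m². The point
partition across levels is cumulative (21 points → 1/6/11/16/21,
configurable), with points laid on a plus-shaped (cross) grid and levels
taking the points nearest the centre. Neither the per-level areas nor the
point-to-level mapping of real cross designs is standardised; both are
declared defaults, not inferences.

What the generator does **not** emulate: sequencing error, chimeras and
OTU-calling artifacts; spatially explicit dispersal beyond the similarity
kernel; seasonality (the temporal field is a stationary Markov chain, not
periodic); taxon-specific detection bias. Passing tests on synthetic data
therefore demonstrate the correctness and calibration of the estimators and
tests under the assumed generative structure, not robustness to real
amplicon-pipeline noise.

Randomness: one root seed per generator; plot-level substreams derive from
`SeedSequence(seed, spawn_key=(plot_index,))`, so every stage is
independently byte-reproducible.

## Problem sizes in the shipped measurements

The test suite and `scripts/acceptance.py` use: 200 random toy matrices
(≤6 taxa, ≤3 levels, ≤3 months) for the set-union oracle; 300 structureless
surfaces × 199 permutations for type-I calibration; 200 noisy 5×17 grids
for recovery bias; 20 replicates for neutral-model recovery; and 50
replicate two-site experiments at the full default design for the
directional homogenization effect. Pipeline tests run on reduced designs
(e.g. 9 points × 8 months, 120-taxon pools) chosen as the smallest sizes
that still exercise every code path.
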