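# Methods

## ²¹⁰Pb geochronology

Excess (unsupported) ²¹⁰Pb is total ²¹⁰Pb minus ²²⁶Ra, per interval, with
λ = ln 2 / 22.3 yr⁻¹ (²¹⁰Pb half-life 22.3 yr). Excess values ≤ 0 mark the
equilibrium depth; to keep the age logarithms finite they are raised to a
floor of 0.1 % of the surface excess and flagged (`excess_clamped`), which
leaves the inventory essentially unchanged while marking the intervals as
undatable in practice.

**Inventories.** Each slab contributes excess [Bq kg⁻¹] × 10⁻³ × ρ
[g cm⁻³] × thickness [cm] = Bq cm⁻² (rectangular rule, matching 2-cm slab
sampling where the measured activity already is a slab average). The
unmeasured inventory below the deepest slab is estimated by log-linear
extrapolation of excess vs cumulative mass fitted to the deepest three
slabs (`tail=True`, default; exact when the profile decays exponentially,
zero with a warning when the deep profile is not decaying). With
`tail=False` a core whose bottom excess exceeds 2 % of the surface value is
rejected as an incomplete inventory.

**CRS.** Ages are reported at slab midpoints,
*t = λ⁻¹ ln(A(0)/A(z))*. The slab MAR uses the same CRS relation
*MAR = λ·Ā/C* but with Ā the logarithmic mean of the slab's top and bottom
inventories; for a slab this identity equals Δmass/Δage exactly, so the
estimator carries no midpoint-evaluation bias (the naive midpoint form is
biased by cosh(λ·Δm/2MAR) ≈ 1–3 % for slow-accumulating cores). Ages above
150 yr are reported but flagged `beyond_pb210_range`.

**CIC.** *t = λ⁻¹ ln(C₀/C(z))*. The reference C₀ is by default the excess
activity extrapolated to the true sediment surface (m = 0) from a
log-linear fit of ln excess vs cumulative mass; anchoring C₀ at the topmost
slab instead (`surface="first"`) would bias every CIC age downward by the
first slab midpoint's own age (several years for organic-rich cores), which
is most of the CRS–CIC disagreement on ideal cores. Non-monotone excess
violates the CIC premise and is monotonized by a running minimum, with a
warning above a 5 % relative inversion.

## Burial rates and whole-lake integration

Per-slab burial = SAR × ρ × %OC/100 × 10⁴; the 10⁴ converts the cm-based
product (g cm⁻² yr⁻¹) to the reporting unit g C m⁻² yr⁻¹. "Recent" burial
is a time-weighted mean over slabs younger than a window of 100 yr
(configurable within 50–150 yr; 100 chosen as the stable upper end of the
½–1-century horizon that excess ²¹⁰Pb resolves), with weights from the
midpoint-age spacing.

Whole-lake integration: (1) unweighted mean of ≥ 2 cores (no area weights,
since core "catchment areas" are rarely known); (2) single depocenter core
divided by SFF(mean slope); (3) single core divided by an SFF per
maximum-depth class (≤5, >5–10, >10–30, >30–90, >90 m). The SFF values and
the slope relation are conventions from the focusing-factor literature, not
measurements; they ship in `data/sff_default.yaml` as documented,
overridable assumptions (deeper lakes focus more; SFF(slope) = max(1,
1 + 0.06·slope%)).

## Classification

Human-altered land cover (cropland, urban, paddy field) overrides the
biome and splits by annual air temperature: cold < 7.5 °C ≤ moderate ≤
15.0 °C < warm (the moderate interval is closed on both ends, taking the
printed "7.5–15.0" inclusively). Natural covers keep the biome label. The
mapping is total and deterministic over the documented label sets; unknown
labels raise an error listing the accepted ones. Satellite processing is
out of scope: water-level scene filtering (|deviation| ≤ 8 %, boundary
inclusive) and per-buffer forest fractions
(100 × forest/(forest + field + flooded), excluded pixels dropped from the
denominator) operate on precomputed tabular counts.

## Upscaling

Class summaries are arithmetic mean, SE = sd/√n and CV on untransformed
rates (log-transforms are reserved for hypothesis tests; the reported
means are arithmetic). Class flux [Tg C yr⁻¹] = mean [g m⁻² yr⁻¹] × area
[km²] × 10⁻⁶; the weighted mean is total flux over the total area of
classes with data; classes without data contribute zero flux. Single-lake
classes report SE 0 and are flagged. No SE propagation into flux
uncertainty is attempted.

True per-class lake areas are not bundled; `data/class_areas_synthetic.yaml`
is an explicitly synthetic stand-in constructed to satisfy the published
aggregate constraints (2.67 × 10⁶ km² total; tropical-forest share ≈ 2.4 %;
weighted mean ≈ 29.7 g m⁻² yr⁻¹) so the pipeline runs end-to-end offline.

## Source apportionment

A sample is assigned to an endmember iff its (δ¹³C, C:N) point lies in that
endmember's rectangle, boundaries inclusive. Points in no rectangle, or in
more than one (no tie rule is defensible without a mixing model), count as
unclassified; contributions plus unclassified sum to 100 %. The default
boxes in `data/endmembers_default.yaml` are literature-informed
assumptions drawn pairwise disjoint (algae at low C:N; C3 plants ¹³C-
depleted at high C:N; C4 plants ¹³C-enriched; C3 soil at intermediate
C:N). Bayesian mixing models are out of scope — the procedure is a box
classification by design.

## Statistics

Temperature models are OLS on untransformed responses (linear for lake
burial, quadratic for forest OC accumulation). The forest-cover model
y = a·e^(b·x) is fitted by nonlinear least squares so coefficient SEs
refer to the original scale; the log-linear OLS fit supplies starting
values only (on noiseless data the two coincide). Confidence intervals are
t-based with n − 2 df.

Group comparisons run one-way ANOVA and Tukey HSD on natural-log rates
(base unstated in the source conventions; natural log chosen), with
Kruskal–Wallis, Kolmogorov–Smirnov (on pooled centred log residuals) and
Bartlett diagnostics reported alongside rather than used as gatekeepers —
the parametric and nonparametric routes are both returned. Tukey letters
use the insert-and-absorb compact-letter-display algorithm at family-wise
α = 0.05 (no further multiplicity correction). `post_hoc=False` skips the
Tukey step, whose studentized-range quantile dominates runtime, for
simulation studies of the omnibus test.

Buffer selection returns the buffer with the highest linear-regression r²,
ties broken toward the smaller (more local) buffer. Variance-stabilization
curves average the sample variance of seeded without-replacement
subsamples over a grid of n.

## Synthetic generators

All generators are pure functions of (scenario, seed).

**Cores.** Under constant ²¹⁰Pb flux P, the excess concentration at
cumulative mass m is P/MAR(t(m))·e^(−λ·t(m)); the deposition history is
integrated on a fine age grid and each slab reports the mass-weighted mean
concentration over the slab — what a homogenised slab actually measures —
scaled by mean-one lognormal noise of relative SD `noise_cv`, plus the
supported activity. Defaults: 60-cm core, 2-cm slabs, ρ = 0.25 g cm⁻³
(organic-rich sediment), supported 25 Bq kg⁻¹, flux 0.02 Bq cm⁻² yr⁻¹ and
MAR 0.08 g cm⁻² yr⁻¹ so the surface excess is ~10× supported. The truth
record (ages, MAR, burial per slab) scores any dating method without
reference to generator internals.

**Lake populations.** Burial per class is lognormal — positive and
right-skewed, consistent with rate data that require log transformation —
with moments matched to the target (mean, SE·√n): σ² = ln(1 + s²/m²),
μ = ln m − σ²/2. The default scenario encodes the published class
structure: humid tropical forest 113.5 ± 18.1 (n = 44), temperate forest
38.9 ± 8.4 (161), boreal 36.7 ± 3.2 (25), other mid-latitude 15.4 ± 3.9
(16), subpolar/polar 10.9 ± 2.7 (9); the three anthropic classes (90, 29,
24) share the pooled human-altered mean 47.6 with a common SD of
3.1·√143 ≈ 37 so the pooled SE matches its published value, since
per-class anthropic moments are not published. Temperatures are truncated
normals consistent with each class (anthropic ones inside their defining
bins), so classification recovers the generating class exactly.

**Sources.** Samples are uniform inside their endmember's rectangle;
the remainder is rejection-sampled outside all rectangles within a margin
around their joint bounding region. Optional isotropic jitter can push
points across box edges, which is exactly the ambiguity real signatures
have.

**Forest gradients.** Burial is a·e^(b·f) of the forest fraction f in the
6-km² buffer (defaults a = 56.21, b = 0.01608), with 15 % multiplicative
noise. Other buffers see a nested mosaic: their fraction mixes the signal
buffer's with an independent landscape draw, with per-octave correlation
0.4 — doubling the window brings in substantially different land cover.
These two choices together describe a landscape in which buffer size is
genuinely informative; with near-perfectly correlated buffers the selection
problem would be unidentifiable for any method.

## What the synthetic tests do and do not show

Passing the recovery suites shows the estimators are correct under their
own assumptions: constant ²¹⁰Pb flux, homogeneous slabs, lognormal rate
populations, rectangular source fields, exponential cover response. Real
cores violate these in ways the generators deliberately omit — flux
interruptions, mixing/bioturbation, compaction trends, dating-model
misspecification, spatially correlated lake populations — so field-data
uncertainty is larger than the synthetic recovery errors. Problem sizes in
the test suite (30-slab cores; 10⁴-lake moment checks; 200-replicate
coverage and 1000-replicate type-I simulations; 100-replicate buffer
consistency) were chosen so Monte-Carlo error is small relative to the
tolerances being checked.

## Known limitations

- SFF defaults and endmember boxes are external conventions, not fitted to
  any dataset; quantitative whole-lake rates and apportionments require
  site-appropriate overrides.
- The CIC implementation is a secondary check; no Monte-Carlo age
  uncertainty, ¹³⁷Cs validation or spectrometry corrections are provided.
- Upscaling propagates no uncertainty into fluxes.
- The bundled class-area table is synthetic (constraint-consistent), not
  measured.
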