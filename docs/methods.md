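# Methods

## Scope and model

The package operationalises a controlled-environment screening method for
nitrogen use efficiency (NUE) in wheat. Its measurement model is simple and
deliberately unit-free on the image side: after segmentation, the plant's
projected area in pixels is the trait. Estimated shoot biomass (EB) is the
pixel sum over three side views plus the top view, divided by exactly 1000
(1 kilopixel = 1000 pixels); top-view area (TVA) is the top view's pixel
sum alone. No geometric calibration to physical area is attempted — variety
comparisons are within-platform, where the pixel scale is constant.

## Segmentation chain

`segment_plant` runs, in order: (1) crop to the region of interest; (2)
classify pixels in hue/saturation space — plant hue window 60–180°, cage
window 200–260°, minimum saturation 0.25 to exclude the near-white
background; (3) suppress shadow pixels with a grey-intensity threshold
(default 0.08 on [0, 1]); (4) remove cage-class pixels (the pot cage is
painted blue precisely so it can be segmented out); (5) drop 8-connected
components smaller than `min_component_area` (default 5 px); (6) optional
binary closing of radius `morphology_radius` (default 0 — closing can add
pixels in concavities, so it is off whenever exact pixel counts matter).
The hue windows are explicit configuration because the original platform's
colour classifier is proprietary; the defaults are wide enough that 8-bit
quantisation cannot move a rendered class across a boundary. White-balance
or shading correction is deliberately not applied: raw pixels in, counts
out.

## Synthetic scenes

The scene generator is the ground-truth oracle for the segmentation chain,
not a botanical model. A plant is one 8-connected region grown pixel by
pixel from a contiguous "crown" at the pot rim, with upward moves favoured
so the blob is elongated like stems and leaves. Growing one connected
region (rather than a union of independent blobs) is a deliberate choice:
every prefix of the growth order is connected, so re-labelling a suffix as
cage occlusion can never shatter the visible plant into fragments smaller
than the component-area filter — which keeps "segmented count equals
ground-truth visible count" an exact, assertable invariant rather than an
approximate one. Cage uprights are also drawn over the background, and
optional 1–4 px green speckles (placed with a clearance margin from the
plant) exercise the small-object filter. The label raster records
background/plant/cage/speckle per pixel.

What the scenes do *not* emulate: specular highlights, soil, overlapping
leaves at high leaf-area index, depth-of-field blur, or illumination
gradients. Passing the exactness tests therefore demonstrates the chain's
logic (class windows, cage removal, component filtering) is correct, not
that the default thresholds are optimal for any particular camera.

## Growth model

EB trajectories are fitted with a continuous two-segment ("broken-stick")
linear regression. For a fixed breakpoint `c` the model
`y = a + b₁·min(x, c) + b₂·max(x − c, 0)` is linear in `(a, b₁, b₂)` and
solved by least squares; the profile SSE over `c` is minimised on a
0.1-DAS grid spanning the second to the penultimate observation, followed
by bounded golden-section refinement in the bracketing grid cell
(`xatol = 1e-10`). Grid ties break toward the earliest breakpoint. The time
axis is centred at the first observation before profiling — this keeps the
design matrix well conditioned and makes the fit exactly shift-equivariant
in DAS. Noiseless piecewise-linear series are recovered to 1e-6 in
breakpoint and slopes, and on noisy series the optimiser's SSE matches an
exhaustive 0.01-DAS profile search to 1e-6 (tested on 100 random series).

Choices the data cannot decide by themselves:

- **Continuity at the breakpoint** is imposed (split-line convention): a
  single (X, Y) breakpoint coordinate only makes sense for joined segments.
- **One breakpoint.** Within a typical imaging window only one bend of the
  sigmoid is visible. The synthetic generator can produce two-breakpoint
  (lag/linear/plateau) series to study this misspecification, but the
  fitter models one.
- **Variety-mean fitting** by default: replicate pots are averaged per DAS
  and one fit reported per variety × N level; per-pot fitting is available
  (`per_pot=True`).
- **adjusted R²** uses p = 4 estimated parameters (intercept, two slopes,
  breakpoint).
- **Degenerate inputs:** an all-constant series returns slopes (0, 0), SSE
  0 and phase "ambiguous" rather than an error.

Phase classification is the slope rule: `b₂ > b₁` → the breakpoint is the
*commencement* of the linear phase, `b₁ > b₂` → its *completion*; slopes
equal within a relative tolerance of 1e-6 → ambiguous. The rule is applied
uniformly to both N levels, even where a narrative reading of a screen
might label a late, flattening breakpoint otherwise — the slopes are the
evidence. The common linear-phase window per N level is
[max breakpoint over commencement fits, min over completion fits], falling
back to the observed DAS range when one kind is absent; the recommended
single screening day is the imaging day nearest the window midpoint, ties
to the later day (larger plants segment more reliably).

Estimation accuracy under noise is information-limited, not
optimiser-limited: at ~2% of the series range (noise SD 10 kPix on a
~600 kPix series, 12 time points) the median breakpoint error is below
1 DAS, and at every noise level tested the production fit's error equals
that of the exhaustive grid oracle. At 5% noise the *oracle itself* has a
median error near 3 DAS — denser imaging, not a better optimiser, is the
remedy.

## NUE and design statistics

NUE_b = W_biomass/W_N and NUE_g = W_grain/W_N per pot, with default N
inputs of 0.147 g (low, 5 mM) and 0.588 g (optimum, 20 mM) per pot,
configurable. Harvest index is 100·GY/DW per pot (or per variety mean when
only means are available; reconstructing the published summary from variety
means agrees to ~0.05 because the original means were computed over pots).

The ANOVA is a fixed-effects two-way model (N × variety with interaction),
Type-I sums of squares on balanced data (where the partition is exact and
order-free; tested against a direct summation oracle to 1e-9 relative),
with a Type-II fallback for unbalanced tables behind an explicit flag. The
original experiment was a split-plot with N as the main plot; its error
strata cannot be reconstructed from printed tables, so s.e.d. and l.s.d.
here use the single residual mean square: s.e.d. = √(2·MSE/n) per compared
mean, l.s.d.(0.05) = t₀.₉₇₅,df_error · s.e.d., CV% = 100·√MSE/grand mean.
Published split-plot s.e.d. values are therefore *not* reproduced, by
design. Significance stars follow the usual figure convention (\*≤0.05,
\*\*≤0.01, \*\*\*≤0.001) with no multiple-testing correction.

Outlier screening fences values at median ± 3 scaled MADs within variety ×
N (× DAS) groups, where the MAD carries the 1.4826 normal-consistency
factor so the fence is a 3σ fence on clean data (~0.3% false flags
asymptotically; at replicate-level group sizes of ~15 the MAD scale is
noisy and the empirical rate is nearer 2–3% — flagged rows are reported,
never dropped, so this only affects how much a human reviews). Groups
smaller than 4 are never flagged.

## Synthetic study and trait tables

The default pipeline study mirrors the screening design: 15 varieties × 2 N
levels × 15 replicate pots × 12 imaging days (twice-weekly, 26–70 DAS). At
low N roughly two thirds of varieties are early starters whose visible
breakpoint is a late linear-phase completion (first slope 8–13, second 3–6
kPix/day, breakpoint in the upper third of the window) and the rest
commence mid-window (4–7 then 9–16 kPix/day); at optimum N ~90% show
commencement breakpoints with much steeper slopes (15–27 then 28–57
kPix/day). Replicate pots scatter around the variety trajectory with a
multiplicative vigour factor (SD 8%) and additive observation noise.
Harvest dry biomass is proportional to final EB plus noise and grain yield
a noisy fraction (~0.48) of it, so vegetative performance genuinely
predicts harvest — the association the method is built to exploit — and
time-resolved EB-vs-DW/GY correlations rise with DAS as they should.

`generate_trait_table` draws the six core traits (EB, TVA, MB, LA, DW, GY)
from a multivariate normal with a configurable target correlation matrix
(validated positive semi-definite; default strongly positive among the
vegetative traits, e.g. corr(EB, MB) = 0.94, and 0.92 between DW and GY)
around per-variety effects. Variety effects default to one shared vigour
gradient scaled per trait — independent per-trait effects would wash out
the inter-trait correlation a real panel shows. Ancillary traits (spike and
grain counts, 1000-grain weight, N concentrations, WSC) are drawn at
N-level-specific means, with grain N% negatively coupled to grain yield as
observed in N screens. All values are truncated positive and GY capped
below DW.

## Determinism and problem sizes

Every generator and the pipeline flow all randomness from one integer seed
(numpy `default_rng`); identical config + seed gives byte-identical CSV
artifacts, and the run manifest records config hash, seed, version and
artifact checksums. Test problem sizes are chosen for signal per second:
segmentation exactness on 100 96×96 scenes, optimiser-vs-oracle on 100
twelve-point series, correlation recovery over 200 replicates of n = 90,
and the full default study for the end-to-end determinism check.

## Known limitations

- Pixel sums saturate as canopies overlap (high leaf-area index); the
  renderer does not model occlusion between leaves, so this regime is
  untested.
- The broken-stick model mis-specifies series in which both sigmoid bends
  fall inside the imaging window; the two-breakpoint generator exists to
  probe this, and the symptom is a depressed adjusted R².
- Split-plot error strata are approximated by a single-stratum ANOVA (see
  above).
- Phase classification near `b₁ ≈ b₂` is noise-sensitive by nature; the
  ambiguous label is surfaced rather than forced into either class.
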