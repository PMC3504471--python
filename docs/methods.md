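# Methods

## The FA maturation clock

Cortical FA is modelled as a plateau followed by exponential decay,

    FA(age) = FA_max,                                          age <  t_init
    FA(age) = (FA_max − FA_min)·exp(−(age − t_init)/τ) + FA_min,  age ≥ t_init,

with all ages kept internally in days post conception (floating point);
postnatal ages exist only at the I/O boundary, where they are converted by
adding the species' gestation length. The model is continuous at `t_init`,
monotone non-increasing, and tends to `FA_min` as age → ∞.

Parameters and defaults (units in parentheses):

| parameter        | meaning                                        | rat  | ferret | human |
|------------------|------------------------------------------------|------|--------|-------|
| `t_init` (dpc)   | end of pyramidal neurogenesis/migration        | 22   | 49     | 173   |
| `τ` (d)          | neuropil maturation time constant              | 5    | 10.7   | 39.8  |
| gestation (d)    | for postnatal↔postconceptional conversion      | 21.5 | 41     | 280   |

`FA_max`/`FA_min` default to the nominal (1, 0): every cross-species
prediction depends only on the decay fraction
`f(age) = exp(−(age − t_init)/τ)`, which cancels the FA range, so absolute
FA output under the defaults is nominal rather than species-calibrated. The
cat ships with gestation only (65 d); no cortical-FA clock is published for
it, and its literature comparisons are quoted directly in gestational days.
The human gestation length (280 d, 40-week clinical term) is this package's
choice; it affects only postnatal/gestational rendering, never the
fraction-matched predictions, which are already expressed in days post
conception.

## Cross-species translation

A window `[a, b]` in a source species maps to fractions
`(f(a), f(b))` and then to the target ages
`t_init_T + τ_T·ln(1/f)`. Because the fractions are species-free the
operation is exactly transitive and the identity on the source species, and
a window starting before `t_init` is rejected (`f` saturates at 1 on the
plateau, so the mapping is not invertible there). Reported ages round to
the nearest whole day and fractions to two decimals, ties away from zero —
this reproduces the quoted 201/217 (human) and PC56/PC61 (ferret)
renderings of the exact values 200.9/216.8 and 56.5/60.8. One published
figure caption quotes the ferret window as PC56–PC60; the computed upper
bound is 60.8, which rounds to 61, and the package follows the computation.
Predictions from the Translating Time event-timing regression are stored
only as printed reference constants (human PC138–150, ferret PC52–56.5,
cat gestational-day equivalents 61.9/66.8); that model itself is out of
scope, and FA-based windows can be compared against the constants as signed
per-bound offsets in days. Published clocks carry no uncertainty for
`t_init` or `τ`, so translated windows carry no confidence interval.

## Trajectory fitting

`fit_fa_params` estimates the free parameters by least squares. The plateau
breakpoint makes the objective non-smooth in `t_init`, so gradient descent
on all four parameters is avoided; instead a profile search over `t_init`
(coarse 1-day grid over the observed age range, then 0.1-day refinement
around the coarse optimum) is combined with variable projection: for fixed
`t_init` and `τ` the model is linear in the amplitude `FA_max − FA_min` and
offset `FA_min`, which are solved in closed form (clipped to the feasible
FA box), leaving a bounded scalar minimisation over `τ` (Brent,
`xatol = 1e-10`, bounds 1e-3 to 20× the age span). Any subset of
{`t_init`, `FA_max`, `FA_min`} may be pinned. The convergence flag is
honest: it reports the inner optimiser's status and flags `τ` pegged at a
search bound. `t_init` is identifiable only when observations exist on the
plateau; with decay-only data any `t_init` below the first age fits equally
well (the amplitude absorbs the shift) while `τ` remains identifiable.

Measured behaviour (computed by the test suite): noiseless data refit `τ`
to <1e-6; with 50 points and Gaussian noise sd 0.02, per-replicate `τ`
error is a few percent (sampling sd ≈6%), and over 200 replicates the mean
estimate is within ~0.5% of truth. Recovery assertions on noisy data are
therefore aggregate (mean over replicates), matching what the estimator's
sampling distribution supports.

## Neurite orientation pipeline

1. **Threshold** — global Otsu split after canonicalizing polarity (the
   image is negated when the stain is dark-on-light, the default), so
   complementary images with the matching polarity flag yield identical
   masks.
2. **Skeletonize** — scikit-image's thinning to one-pixel-wide centrelines.
3. **Segment extraction** — the skeleton is split at branch points (pixels
   with >2 neighbours), each remaining branch ordered into a pixel path and
   recursively subdivided at the point of maximum perpendicular deviation
   from its chord until every piece deviates ≤ `max_deviation_px`
   (default 2 px); pieces shorter than `min_length_px` (default 10 px) are
   discarded. This realises "approximate the stain as straight lines" while
   bounding curvature error.
4. **Polar angles** — each segment's angle from the radial (pial-normal)
   axis, a per-image declaration defaulting to image-vertical, folded into
   [0, 180). The direction vector is canonicalized first so θ and θ+180°
   fold bit-identically.
5. **Axial Von Mises fit** — angle doubling: fit on 2θ over the full
   circle, halve the mean direction back. κ is the MLE obtained by
   inverting A(κ) = I₁(κ)/I₀(κ) = R̄ with the standard piecewise series
   start and a few Newton steps (exponentially scaled Bessel functions for
   stability), capped at κ = 500 and flagged for near-degenerate samples.
   Fitting requires ≥10 angles (configurable floor).
6. **Bootstrap CI** — seeded percentile bootstrap on the angles
   (default 1000 replicates, vectorised); two regions are called
   differently concentrated when their 95% intervals are disjoint.

The angle-doubling convention, the κ estimator, and the percentile CI are
this package's choices; published κ values from the original micrographs
(2.08 enucleated vs 1.41 control) are not desk-reproducible without those
images and are used here only as generating truths in synthetic recovery
tests.

## Synthetic data

`gen_fa_observations` draws trajectory values plus Gaussian noise clipped
to [0, 1]. `gen_axial_angles` samples the doubled circle with numpy's
Von Mises generator (the standard Best–Fisher rejection sampler; numpy is
already a core dependency, so no re-implementation is warranted), halves
and folds. `gen_golgi_image` renders straight anti-aliased dark strokes
(capsule distance fields, default width 3 px, lengths 30–80 px) at sampled
orientations on a light noisy background and returns the generating angles
as ground truth; images are left un-thresholded so the pipeline's own
binarisation is exercised. All generators are pure functions of
(parameters, seed).

What the generator does **not** emulate: branching arborisation, somata,
staining-density gradients, uneven illumination, out-of-plane blur, and 3-D
structure. Passing recovery tests therefore demonstrate correctness of the
extraction-and-estimation chain on straight-process fields, not performance
on real histology.

Measured end-to-end behaviour (test suite, 1024² images, 600 strokes):
fitted κ within 25% of generating κ across κ ∈ [0.5, 3] (typically within
~10%), single-stroke angle recovery within 2°, and 92.5% empirical
coverage of the 95% bootstrap CI at κ = 2, n = 300 over 200 simulations
(the percentile bootstrap is known to under-cover slightly at this sample
size).
Problem sizes in the tests (image side 256–1024 px, 200 replicates for
Monte-Carlo checks, 1000 bootstrap replicates) were chosen to make the
statistical assertions sharp while keeping the suite quick to run.

## Area arithmetic

Percent reduction is 100·(control − treated)/control on per-region group
means; negative values (enlargements) are allowed and flagged at the
formatting layer. Reported at one decimal, ties away from zero. The
published cat extrastriate means (510.75 → 332.70 mm²) give 34.86%, which
rounds to 34.9; a printed figure of 34.8 reflects truncation, and the
package reports the computed arithmetic. Summaries are permutation-
invariant and scale-equivariant; a region missing one group is reported as
incomplete, never as a zero reduction.

## Known limitations

- Absolute FA values are nominal unless per-species `FA_max`/`FA_min` are
  supplied.
- `t_init` is unidentifiable without plateau observations (documented
  above); the fit still recovers `τ`.
- Segment extraction weights every extracted piece equally; long processes
  crossing many others contribute more pieces, which is the intended
  behaviour for stain-coverage statistics but is not a per-neuron measure.
- The Golgi simulator's simplifications mean real-image performance must be
  validated separately.
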