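# Methods

`wmbias` analyses trial-level continuous-report data from retro-cue
working-memory experiments: on each trial an observer sees four
orientations in sequence, is cued to reproduce one of them (the target),
and the question is whether — and how strongly — the report is pulled
toward (or pushed away from) the other three memorized orientations
(the distractors), the circular mean of the distractors, or the previous
trial's target/response.

## Orientation space

Orientations are axial: a grating at θ and at θ+180° are the same
stimulus. All angles live on [0°, 180°); signed differences live on
(−90°, +90°], with negative values meaning the reference is
counter-clockwise of the target, and the ±90° tie resolved to +90°.
(The tie has measure zero for continuous orientations, so the choice is a
convention, not a modelling decision.) All circular statistics
(means, resultant lengths, circular SDs) are computed by doubling the
angles onto the full circle, applying ordinary circular statistics, and
halving back — the standard treatment of axial data. A circular mean is
reported as degenerate (and the trial skipped, with a count) when the
doubled resultant length falls below 10⁻⁹, e.g. for two orthogonal
orientations.

## The bias tuning curve

The bias of the response error e as a function of the signed
target–reference difference Δ is modelled by a derivative-of-Gaussian
(DoG),

    f(Δ) = Δ · a · w · c · exp(−(wΔ)²),   c = √2·e^{1/2},

an odd function whose peak value equals the amplitude `a` (degrees of
bias; negative a = repulsion) and whose peak sits at Δ = 1/(w√2), so `w`
(1/degrees) is an inverse width. Fits are constrained to a ∈ [−10, 10]
and w ∈ [0.01, 0.08] (peak bias within ±10°, peak location roughly
between 9° and 71°) and always run on the raw data points; the moving
average over Δ-sorted errors (window = round(0.04·N), forced odd, ≥ 3,
shrinking at the edges) is display-only.

### Fitting

With w fixed, the model is linear in a, so the bounded least-squares
optimum is the clipped closed form a(w) = clip(Σgᵢeᵢ/Σgᵢ², ±10) with
g = g_w(Δ). `fit_dog` therefore profiles the amplitude out: the profiled
RSS is evaluated on a 141-point width grid and refined by bounded scalar
minimisation around the grid minimum. This finds the global constrained
minimiser of the same objective a generic two-parameter optimiser
targets (verified against a multi-start trust-region optimiser to 1e−6
on random data; noiseless data is recovered to better than 1e−6), is
deterministic,
and — because the basis matrix depends only on the Δ vector, which
permutation never changes as a multiset — makes the thousands of refits
inside a permutation test cheap. Start values are therefore not part of
the procedure. When the width is pinned (both bounds equal) the
amplitude is fitted by bounded-variable least squares instead, which
keeps the closed-form amplitude available as an independent oracle for
that path.

### Model-free bias

As a fit-free cross-check, the model-free bias statistic is the mean of
the pooled set {eᵢ : Δᵢ > 0} ∪ {−eᵢ : Δᵢ < 0} (Δ = 0 points ignored) —
the pooled mean, not the sum of the two one-sided means; positive values
indicate attraction. It is conservative (it averages the tuning curve
over all Δ rather than reading off its peak) but assumes nothing about
curve shape.

## Permutation inference

Amplitude significance: the Δ vector is shuffled against the error
vector and the DoG refitted per shuffle; p is the plain proportion of
null statistics at least as extreme as the observed one (no +1
smoothing), and p = 0 is displayed as "< 1/n_perm". The default is
two-sided on |a| so repulsive (negative-amplitude) curves are testable
on the same footing; the literal one-sided rule (count of null a ≥
observed a) is available as a switch. Condition contrasts (statistic
a_A − a_B, or the model-free difference) shuffle the condition labels
over the pooled points and refit both curves; two-sided by default. The
headline analyses use 10,000 permutations; the analysis drivers use
1,000–2,000 (the proportions stabilise well before 10,000 and every
report records its n_perm and seed).

One master seed drives everything; each test derives its own seed from
SHA-256 of (master seed, test name), so adding or reordering analyses
never perturbs another test's null distribution, and the threshold sweep
reuses one base seed across thresholds so its columns are comparable.

A property worth knowing when reading p-values: because the width is
free within [0.01, 0.08], the null distribution of the fitted |a| is
heavy-tailed relative to a fixed-width fit (boundary-width "ramp" fits
absorb weak linear trends). At ~12,000 data points, null fits of |a| ≈ 1°
are routine. The permutation test accounts for this automatically — the
null is built from the same width-free fit — but it means single-cohort
significance needs either large n or a large amplitude. Calibration is
nevertheless exact up to replicate noise: over 600 bias-free cohorts the
rejection rate at α = 0.05 was 0.048.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
per trial: four i.i.d. uniform orientations, a uniform target position,
and a response error drawn from a three-part mixture —

* guess (default 10%): error uniform on (−90°, 90°];
* swap (default 0%): the report tracks a uniformly chosen distractor
  (error = that distractor's Δ plus the usual report noise — swaps are
  reports of the wrong item, not noiseless copies);
* genuine report: Von Mises noise plus the sum of per-distractor DoG
  biases (multi-distractor biases combine additively; no saturation).

Report noise is Von Mises on the doubled circle, halved back; quoted κ
values refer to the doubled circle (a κ of 4 gives a circular SD of
~15.5° on the orientation scale, a realistic single-item recall
precision for this task). Which circle a published κ refers to is often
ambiguous; the doubled-circle reading is used throughout and recorded in
the generator's output metadata. Default κ per serial position is
(2.5, 3.0, 3.5, 5.0) — precision grows with recency, emulating the
recall-precision ordering such experiments show. Experiment templates
add per-item attributes: two stimulus-noise levels (with target κ scaled
×0.7/×1.4 for high/low noise targets, and per-distractor amplitudes
keyed by distractor noise), or two colours with or without a
target-colour pre-cue (amplitudes keyed by colour match). Confidence
ratings (generated only for the noise template, which is the design that
collected them) are a deterministic discretisation of |error| at 10°/25°
— only their ordering is meaningful. Optional switches add
temporal-distance weights, forward/backward asymmetry, an attraction
toward the previous trial's response, and latent component labels for
mixture audits.

What the generator does *not* emulate: between-trial dependence (unless
the previous-response switch is on), reaction times, observer-level
heterogeneity in bias strength, or any perceptual encoding stage.
Passing tests therefore show the pipeline recovers the parameters of
this generative family; they cannot show the family is the right model
of real observers.

### Estimand under guessing

Guess trials carry no Δ–error association, so with guess rate p_g the
fitted amplitude estimates ≈ (1 − p_g)·a_true: cohorts generated with
a = 2° and 10% guesses fit to a median ≈ 1.7–1.8°. The recovery check
bands (median a within 2.0 ± 0.3, w within 0.03 ± 25%) take this
attenuation into account.

## Preprocessing rules

* Flat-error exclusion: an observer is excluded when a χ² goodness-of-fit
  of their binned errors (12 bins over ±90°) against uniform *fails to
  reject* at α = 0.05 **and** the resultant length of their doubled
  errors is below 0.2. Both statistics are recorded; observers with
  fewer than 20 trials are marked insufficient and retained. The dual
  criterion keeps a single noisy statistic from excluding genuine
  observers (measured false-exclusion rate < 5% at κ = 4, 100 trials).
* First/last-target similarity: observers whose circular error SD for
  position-1 targets is within a tolerance of their position-4 SD are
  flagged (memory decay should show a gap), never auto-excluded.
* Large-error removal: whole trials with |error| > 45° are dropped
  (threshold 90° = no removal). Removal is trial-wise — all three data
  points of a dropped trial go — and idempotent.
* Confidence "1" (self-reported guess) points are excluded from the
  confidence contrast only; they stay in every other analysis.

## The swap-error confound

A swap puts the response on the identity line e = Δ for one of the three
distractors, which a DoG fit reads as attraction. The confound study
quantifies this on bias-free cohorts (a = 0, κ = 4, 10% guesses, 5%
swaps, ~12,000 points): the fitted amplitude is systematically positive
(mean ≈ 0.8° over 20 replicates; positive in every replicate), and
trimming at 45° roughly halves it. A single cohort of this size,
however, often fails to reach permutation significance (the heavy-tailed
width-free null above) — the inflation is a bias of the estimator,
demonstrated across replicates, not necessarily a per-dataset rejection.
Contrasts are the important part: with equal swap rates in both
conditions the estimated amplitude difference tracks the true difference
and is on average slightly *under*-estimated, never inflated — so
between-condition conclusions survive swap contamination even where
absolute amplitudes do not.

## Problem sizes and defaults

Validation studies run at the sizes they report: parameter recovery and
the swap studies use 40 observers × 100 trials (12,000 data points) over
20 replicate seeds; permutation calibration uses 200 cohorts of 12
observers × 50 trials (~1,800 points) with 500 shuffles each — the
calibration of an exact permutation test does not depend on n, so the
null cohorts are kept modest. Analysis defaults: error-removal threshold
45°, α = 0.05, moving-average fraction 0.04, n_perm 10,000.

## Known limitations

* One curve per condition, pooled over observers; no hierarchical
  per-observer fitting (amplitudes are cohort-level estimates and
  observer heterogeneity widens the null).
* Swap contamination at small |Δ| is indistinguishable from true bias on
  a per-trial basis; the 45° trim only removes swaps at large |Δ|.
* The ±90° boundary convention and the boundary-width behaviour of the
  fit (w clipped at 0.01 or 0.08 signals a poorly identified width, not
  a good fit; inspect `DoGFit.params.w` when amplitudes look odd).
* The canonical CSV schema is this package's own; external deposits must
  be mapped to it (an adapter step left to the user, by design).
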