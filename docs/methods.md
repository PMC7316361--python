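# Methods

This note documents the models, numerical choices and limitations behind
the package; the README covers usage.

## The closed loop

One iteration proposes latent codes, renders them to images, scores each
image with the target unit, and feeds the scalar scores back to the
optimizer. The contract is strict: no component ever passes gradients; a
unit is any `score(image) -> float`, so everything composes identically
with a deterministic model unit, a stochastic simulated neuron, or a live
recording.

The loop stops on a fixed budget only (generation count and a presentation
cap), because a realistic experiment has a fixed trial budget and no
reliable convergence signal under noise. The presentation counter is
exact: population size per GA generation, `2 * n_pairs` per FDGD step,
`n_samples` per NES step. The defaults — 500 generations × 20 images =
10,000 presentations — describe a session-sized experiment.

The *optimized image* is the best image of the final generation, selected
by the *observed* score (what an experimenter would see); logs always
record the underlying true activation alongside, so noisy runs can be
evaluated against ground truth.

Reproducibility: the run seed is expanded via `numpy.random.SeedSequence`
into independent streams for initialization, optimizer, noise calibration
and noise observation. Consequently toggling noise, or changing optimizer
hyperparameters, leaves the initial population untouched — paired
comparisons across conditions share their starting point.

## Generators

* **Pixel generator.** Each code entry is one pixel through the affine map
  `p = clip(255 (c+1)/2)`; the declared code domain is `[-1, 1]` with
  clipping outside. It is the minimal search space and makes ground-truth
  analyses exact (its inverse is affine).
* **Linear generator.** `image = quantize(255 · sigmoid(B c))` with a
  seeded Gaussian basis `B` (unit-norm columns). It gives a smooth,
  distributed, low-dimensional code → image map — a stand-in for a trained
  inverting generator at a scale where least-squares oracles are available.
* **Quantization** is fixed as round-half-up after clipping to `[0, 255]`,
  so generated images are bit-stable across platforms and golden-image
  tests are exact.
* **External adapters** plug in by dotted path and need only `d`,
  `image_shape` and `generate`. A DeePSiM-style fc6 inverter conventionally
  uses `d = 4096`; its code-space scaling is left to the adapter because no
  canonical normalization exists.

Default desk-scale dimensions are `d = 64` and images up to 64×64×3; the
experiments in the test suite mostly use the 8×8×1 pixel generator, where a
full 10,000-presentation run takes under a second on one CPU core.

## Target units

* **Matched filter:** `max(0, ⟨x̂, t̂⟩)` between mean-centered, unit-norm
  flattened image and template. Range [0, 1]; the template is the unique
  optimum — every optimizer result can be scored against it. Constant
  images score 0 by convention (they carry no pattern).
* **Gabor templates** (carrier × Gaussian envelope, affinely mapped to
  8-bit) provide structured optima; `sigma=None` gives a pure grating.
* **Center-surround units** model extra-classical surround suppression: a
  small zero-mean oriented filter is rectified pixelwise, summed over a
  central disc, and a concentric annulus (optionally a differently
  oriented channel) is subtracted with weight `beta ≥ 0`, then rectified.
  The score is provably non-increasing in `beta`, and a preferred pattern
  confined to the disc beats the same pattern covering disc + annulus.

## Poisson observation model

A single trial returns one draw from `Poisson(scale · max(a, 0))`, where
`a` is the true activation. Negative activations map to rate 0 because
spike counts are non-negative. `scale` is calibrated so that a *good
stimulus* — the expected maximum activation among `n_sample = 2500` images
drawn with replacement from a reference set, averaged over `repeats = 10`
resamples — evokes `n_good` expected spikes. The default `n_good = 20`
corresponds to 100 spikes/s over a 200 ms window; sweeps use
{2, 5, 10, 20, 40, 100} to span high-noise to near-noiseless regimes,
since sd/mean of a Poisson count is `1/sqrt(rate)`.

Noise metrics are defined operationally (they are design choices, not
canonical formulas): *self-correlation* is the Pearson correlation across
probe images between two independent single-trial response vectors;
*sd/mean at the good stimulus* is the analytic `1/sqrt(n_good)`; *SNR* is
the standard deviation of true rates across probes divided by the mean
single-trial standard deviation `sqrt(rate)`. Each proposed image is
observed once per generation (one trial per presentation); elites are
re-presented and re-scored every generation rather than keeping a cached
score, as in a physiology loop where every presentation is a fresh trial.

## Optimizers

**Genetic algorithm** (default; population 20, 1 elite, mutation rate
0.25, mutation sd 0.5 code units, heritability 0.5, selectivity 2): elites
are the top-scoring codes (ties to the lower index) passed unchanged in
their original order; parents are drawn independently from
`softmax(selectivity · zscore(scores))`, falling back to uniform when all
scores tie; each offspring gene comes from parent A with probability
`heritability`, then mutates with probability `mutation_rate` by Gaussian
noise. Softmax over z-scored fitness makes selection invariant to the
unit's output scale. All values are config-exposed and swept by the
hyperparameter harness; they are package defaults, not tuned optima.

**FDGD** uses antithetic central differences along random unit directions
— exact for linear fitness at any step size, variance-reduced otherwise.
**NES** uses rank-based zero-sum utilities (average ranks under ties, so
all-tied scores give exactly zero update); raw centered scores are
available by switching `rank_utilities` off.

Numerical edge cases: non-finite scores abort the run with the generation
index; all-tied GA scores select parents uniformly; the GA permits
`n_elites = population_size` (pure copying) even though ordinary runs keep
`n_elites < population_size`.

## Encoding

`ivt` inverts the generator structure directly: exact affine inverse
(pixel), or least squares on the pixelwise logit (linear; intensities are
clipped to `[1/512, 1 − 1/512]` of full scale so the logit stays finite —
the reported loss then matches a normal-equations solution to numerical
precision). `opt` runs the evolution loop against `−MSE` in pixel space,
keeping the black-box contract; its GA default uses a smaller mutation sd
(0.15) than activation maximization because pixel-loss minimization
rewards fine local steps over exploration. Reported losses are always
recomputed as `MSE(generate(code), target)` on the [0, 255] scale.

Seeded initial populations take a scored reference set and select the `k`
images at a rank band: ranks 1..k (*best*), the last k (*worst*), or the k
ranks centered on the median — ranks 41..60 of 100 for k = 20 (*middle*,
a documented convention). Random initialization draws codes i.i.d.
`N(0, init_scale² I)` with `init_scale` declared per generator (0.5 for
pixel, keeping draws mostly inside the code domain; 1.0 for linear).

## Analysis machinery

Relative activation always uses the maximum over the full local reference
set as denominator — the desk-scale analogue of normalizing by the best
image in a very large natural-image corpus. Baseline curves draw `n`
images per scheme (unrestricted: without replacement from the whole set;
group-restricted: `n_groups` random groups, `n / n_groups` from each) and
report median and quartiles of the max relative activation over repeats.
The initialization slope regresses band medians on x = {0, 1, 2}; for
three equally spaced points this is exactly `(m_best − m_worst)/2`.
Interpolation curves normalize by the α-nearer endpoint (α ≤ 0.5 → left).
Sweep reports aggregate with plain means per grid point; significance
testing across units is left to the caller's preferred paired test since
no single canonical choice exists.

## Synthetic fixtures and what they do (not) show

`make_reference_set` builds group-structured image sets — Gabor textures
whose orientation/wavelength vary by group (plus pixel noise), or noise
fields smoothed at group-specific scales — so units genuinely prefer some
groups, which the category-restricted baseline needs. `make_unit_battery`
rotates matched-filter (Gabor template), matched-filter (smoothed noise)
and center-surround units, all with finite responses and, for matched
filters, a known optimum of exactly 1.

These fixtures emulate the *structure* of the problem (a preferred-feature
landscape over a structured stimulus set, category concentration of good
stimuli, Poisson reliability) but not natural-image statistics, deep
nonlinear tuning, or generator mismatch with the target's feature space.
Passing tests therefore certify the algorithmic machinery — budget
accounting, update rules, calibration, metric definitions, reproducibility
and qualitative robustness trends — not absolute performance figures on
any particular network or neuron.

## Problem sizes

The test suite and the acceptance script run the 8×8×1 pixel generator
(d = 64), reference sets of 100–200 images, 10–20 seeds per condition, and
noise sweeps at 100 generations × 20 images per run. These sizes were
chosen so every study completes in seconds while leaving all qualitative
relations (noise-robustness ordering, baseline monotonicity, restriction
penalty) clearly resolved above Monte-Carlo error.

## Known limitations

* Pure homogeneous Poisson noise: no overdispersion, adaptation, or serial
  dependence across trials.
* `encode_opt` is gradient-free by design; it will not match
  backprop-through-generator encoders on large generators.
* FDGD/NES report the best probed image of the final step as the optimized
  image; the search center itself is not presented (keeping the
  presentation budget exact).
* Uniqueness of the 10,000 presented images is a statistical consequence
  of continuous mutation, not an enforced constraint.
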