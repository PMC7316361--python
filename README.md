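# xdream

Closed-loop, gradient-free synthesis of preferred stimuli for visual
neurons and model units.

## The problem

Which images drive a given visual neuron hardest? The space of possible
images is combinatorially vast, and a biological neuron offers only a few
thousand noisy spike-count measurements per session — with no gradients.
Hand-picked or category-restricted stimulus sets explore a sliver of image
space and can miss a neuron's true preference.

This package implements the closed-loop alternative: couple an **image
generator** `G : ℝᵈ → images` (the search space), a black-box **target
unit** `f : image → ℝ` (the fitness: a model unit's activation or a spike
count), and a **gradient-free optimizer** over latent codes `c ∈ ℝᵈ`.
Each generation the optimizer proposes codes `c₁,…,cₙ`, the generator
renders them, the unit returns scalar scores `yᵢ = f(G(cᵢ))`, and the
optimizer proposes the next generation — by default for 500 generations of
20 images (10,000 presentations, a realistic experiment budget). The
*optimized image* is the best image of the final generation.

Three optimizers are provided, all touching the unit only through scalars:

- a **genetic algorithm** (default): elitism, softmax parent selection over
  z-scored fitness, per-gene crossover and Gaussian mutation;
- **FDGD**, finite-difference gradient ascent with antithetic probe pairs
  `ĝ = meanₖ [(f(c+εuₖ) − f(c−εuₖ))/2ε] uₖ`;
- **NES**, natural evolution strategies: `c ← c + η/(nσ) Σᵢ uᵢ εᵢ` with
  rank-based zero-sum utilities `uᵢ` over Gaussian perturbations `εᵢ`.

Performance is measured as **relative activation** — the unit's response
divided by its maximum response over a full reference image set — so 1
marks the best reference image and values above 1 are **super stimuli**.
Biological response variability is modelled by a homogeneous Poisson
process: the true activation sets the rate, calibrated so a "good
stimulus" (the expected best of 2,500 random reference images) evokes a
target spike count (default 20 ≈ 100 spikes/s × 200 ms window).

Everything runs at desk scale with built-in generators (pixel-space and a
random linear basis) and toy receptive-field units (matched filters with
Gabor or smoothed-noise templates, and center-surround suppression units);
adapter contracts let you plug in a pretrained inverting generator (e.g.
DeePSiM-fc6, d = 4096) or any `image → scalar` scorer, including a live
recording.

## Worked example

```python
from xdream.experiment import RunConfig, run_evolution, build_unit
from xdream.fixtures import make_reference_set
from xdream.analysis import relative_activation, is_super_stimulus

config = RunConfig.from_dict({
    "generator": {"kind": "pixel", "d": 64, "image_shape": [8, 8, 1]},
    "unit": {"kind": "matched_gabor", "wavelength": 4.0, "sigma": 3.0},
    "loop": {"n_generations": 500, "max_presentations": 10_000},
    "seed": 0,
})
log = run_evolution(config)
print(f"presentations: {log.n_presentations}")
print(f"optimized true activation: {log.optimized_true_activation:.4f}")

refset = make_reference_set(200, 10, seed=0, image_shape=(8, 8, 1))
unit = build_unit(config.unit, (8, 8, 1))
a_ref_max = max(unit.score(img) for img in refset.images)
rel = relative_activation(log.optimized_true_activation, a_ref_max)
print(f"best reference activation: {a_ref_max:.4f}")
print(f"relative activation: {rel:.3f}  (super stimulus: {is_super_stimulus(rel)})")
```

prints

```
presentations: 10000
optimized true activation: 0.9779
best reference activation: 0.6614
relative activation: 1.479  (super stimulus: True)
```

The matched-filter unit's activation is the rectified normalized
correlation with its Gabor template (maximum 1, attained only by the
template itself). Within 10,000 presentations the genetic algorithm drives
a random initial population to 0.978 — handily beating the best of 200
structured reference images (0.661), i.e. the evolved image is a super
stimulus with relative activation 1.479.

The same experiment from the shell:

```bash
xdream run --config run.yaml --set seed=0 --out runs/demo
xdream analyze runs/demo --baseline refs/ --sizes 10,100 --out baseline.csv
xdream analyze runs/demo --interpolate runs/other --points 11 --out interp.csv
xdream analyze runs/demo --noise-sweep --out noise.csv
xdream encode --image target.png --generator pixel --method opt --out enc
xdream config-reference --out config-reference.md
```

A run directory contains `log_presentations.csv` (one row per
presentation), `log_generations.csv` (per-generation bests),
`codes.h5` (codes per generation + the optimized code), `optimized.png`,
and `config_resolved.yaml`; the same seed reproduces all of them
byte-for-byte.

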