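"""Image -> code encoding for seeded initialization and reconstruction.

Two routes convert an image into a latent code:

* ``ivt`` — direct inversion through the generator's structure: the exact
  affine inverse for the pixel generator, a least-squares pseudo-inverse in
  logit space for the linear generator, or a paired encoder exposed by an
  external adapter (an ``encode`` method).
* ``opt`` — black-box optimization: run the evolution loop with fitness
  equal to the negative mean squared pixel difference to the target, so
  that the code is found using only scalar losses, exactly as activations
  are maximized.

Both report the reconstruction loss as the mean squared pixel difference on
the [0, 255] intensity scale, recomputed from the returned code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from xdream.generators import Generator, LinearGenerator, PixelGenerator, as_code
from xdream.optimizers import GAConfig, GeneticOptimizer
from xdream.targets import TargetUnit

__all__ = [
    "EncodingResult",
    "encode_ivt",
    "encode_opt",
    "build_initial_population",
    "reconstruction_mse",
]


def reconstruction_mse(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Mean squared pixel difference on the [0, 255] scale."""
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


@dataclass
class EncodingResult:
    """A code, its rendered reconstruction, and the reconstruction loss."""

    code: np.ndarray
    reconstruction: np.ndarray
    loss: float
    method: str


_LOGIT_EPS = 1.0 / 512.0  # keeps logit finite at intensity 0 and 255

#: GA settings used by :func:`encode_opt` when no config is given.  Pixel-loss
#: minimization rewards fine steps near the optimum, so the mutation scale is
#: smaller than the exploration-oriented activation-maximization default.
DEFAULT_OPT_CONFIG = GAConfig(mutation_size=0.15)


def encode_ivt(image: np.ndarray, generator: Generator) -> EncodingResult:
    """Invert an image through the generator's analytic structure.

    Pixel generator: exact affine inverse (lossless up to quantization).
    Linear generator: the sigmoid is inverted pixelwise (intensities clipped
    away from 0/255 so the logit is finite), then the code is the
    least-squares solution of ``basis @ code = logit`` — the optimal code
    within the generator's linear structure.  External adapters must expose
    an ``encode(image) -> code`` method.
    """
    if isinstance(generator, PixelGenerator):
        code = generator.encode(image)
    elif isinstance(generator, LinearGenerator):
        scaled = np.clip(
            np.asarray(image, dtype=np.float64).ravel() / 255.0, _LOGIT_EPS, 1.0 - _LOGIT_EPS
        )
        logit = np.log(scaled / (1.0 - scaled))
        code, *_ = np.linalg.lstsq(generator.basis, logit, rcond=None)
    elif hasattr(generator, "encode"):
        code = as_code(generator.encode(image))
    else:
        raise NotImplementedError(
            f"generator {type(generator).__name__} provides no inverse map"
        )
    recon = generator.generate(code)
    return EncodingResult(
        code=np.asarray(code, dtype=np.float64),
        reconstruction=recon,
        loss=reconstruction_mse(recon, image),
        method="ivt",
    )


def encode_opt(
    image: np.ndarray,
    generator: Generator,
    config: GAConfig | None = None,
    budget: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> EncodingResult:
    """Find a code for an image by evolving against a scalar pixel loss.

    Runs the elitist genetic algorithm with fitness ``-MSE(generate(code),
    image)`` for ``budget // population_size`` generations and returns the
    best code ever scored.  Being elitist, the best-so-far loss is
    non-increasing across generations.
    """
    config = config or DEFAULT_OPT_CONFIG
    if budget < config.population_size:
        raise ValueError("budget must cover at least one generation")
    rng = np.random.default_rng(rng)
    target = np.asarray(image, dtype=np.float64)
    init_scale = getattr(generator, "init_scale", 1.0)
    init = [init_scale * rng.standard_normal(generator.d) for _ in range(config.population_size)]
    opt = GeneticOptimizer(init, config, rng)

    best_code, best_fitness = None, -np.inf
    n_generations = budget // config.population_size
    for _ in range(n_generations):
        codes = opt.ask()
        fitnesses = [-reconstruction_mse(generator.generate(c), target) for c in codes]
        gen_best = int(np.argmax(fitnesses))
        if fitnesses[gen_best] > best_fitness:
            best_fitness = fitnesses[gen_best]
            best_code = codes[gen_best]
        opt.tell(fitnesses)

    recon = generator.generate(best_code)
    return EncodingResult(
        code=best_code,
        reconstruction=recon,
        loss=reconstruction_mse(recon, target),
        method="opt",
    )


def _rank_band_indices(scores: np.ndarray, rank: str, k: int) -> np.ndarray:
    """Indices of the k reference images at a rank band (best/middle/worst).

    Images are ranked from best (rank 1) to worst by score, ties broken by
    lower index.  ``best`` takes ranks 1..k, ``worst`` the last k, and
    ``middle`` the k ranks centered on the median (ranks 41..60 for 100
    images and k=20).
    """
    n = scores.size
    order = np.argsort(-scores, kind="stable")
    if rank == "best":
        return order[:k]
    if rank == "worst":
        return order[n - k :]
    if rank == "middle":
        start = (n - k) // 2
        return order[start : start + k]
    raise ValueError(f"rank must be 'best', 'middle' or 'worst', got {rank!r}")


def build_initial_population(
    source: str,
    generator: Generator,
    unit: TargetUnit | None = None,
    reference_images: Sequence[np.ndarray] | None = None,
    rank: str = "best",
    k: int = 20,
    method: str = "ivt",
    rng: np.random.Generator | int | None = None,
    opt_budget: int = 2000,
) -> list[np.ndarray]:
    """Initial generation of k codes, random or seeded from scored images.

    ``source="random"`` draws k codes i.i.d. from N(0, I) scaled by the
    generator's declared ``init_scale`` (a fixed seed reproduces the same
    set exactly).  ``source="images"`` scores the reference set with the
    unit, selects the k images in the requested rank band, and encodes each
    with :func:`encode_ivt` or :func:`encode_opt`.
    """
    rng = np.random.default_rng(rng)
    if source == "random":
        scale = getattr(generator, "init_scale", 1.0)
        return [scale * rng.standard_normal(generator.d) for _ in range(k)]
    if source != "images":
        raise ValueError(f"source must be 'random' or 'images', got {source!r}")
    if unit is None or reference_images is None:
        raise ValueError("image-seeded initialization needs a unit and reference images")
    if k > len(reference_images):
        raise ValueError(f"k={k} exceeds reference set size {len(reference_images)}")
    scores = np.array([unit.score(img) for img in reference_images])
    chosen = _rank_band_indices(scores, rank, k)
    codes = []
    for idx in chosen:
        img = reference_images[idx]
        if method == "ivt":
            codes.append(encode_ivt(img, generator).code)
        elif method == "opt":
            codes.append(encode_opt(img, generator, budget=opt_budget, rng=rng).code)
        else:
            raise ValueError(f"method must be 'ivt' or 'opt', got {method!r}")
    return codes
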