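"""Gradient-free code-space optimizers.

All three optimizers interact with the target exclusively through scalar
scores — there is no gradient channel in the interface, matching the
constraints of a closed-loop physiology experiment.  Each optimizer follows
an ask/tell protocol driven by the experiment loop:

``ask()``
    propose the codes to present this generation/step,
``tell(scores)``
    consume the observed scores and update internal state.

The per-step presentation budget is fixed and explicit: ``population_size``
for the genetic algorithm, ``2 * n_pairs`` for finite-difference gradient
descent (FDGD, antithetic central differences), and ``n_samples`` for
natural evolution strategies (NES, rank-shaped perturbation weighting).

Functional single-step forms (:func:`ga_propose`, :func:`fdgd_propose`,
:func:`nes_propose`) are provided for direct use and for testing the update
rules against analytic oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from xdream.generators import ImageCode, as_code

__all__ = [
    "ScoredPopulation",
    "GAConfig",
    "FDGDConfig",
    "NESConfig",
    "GeneticOptimizer",
    "FDGDOptimizer",
    "NESOptimizer",
    "ga_propose",
    "fdgd_propose",
    "nes_propose",
    "build_optimizer",
]


@dataclass
class ScoredPopulation:
    """Codes of one generation together with their (observed) scores."""

    codes: list[np.ndarray]
    scores: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.codes) != self.scores.size:
            raise ValueError("codes and scores must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters.

    ``selectivity`` scales the softmax over z-scored fitness used for
    parent sampling (an inverse temperature: 0 = uniform parents, large =
    winner-takes-all).  ``heritability`` is the probability that an
    offspring gene is copied from the first of its two parents.  Mutation
    acts per gene: with probability ``mutation_rate`` add Gaussian noise of
    sd ``mutation_size`` (in code units).
    """

    population_size: int = 20
    n_elites: int = 1
    mutation_rate: float = 0.25
    mutation_size: float = 0.5
    heritability: float = 0.5
    selectivity: float = 2.0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.n_elites <= self.population_size:
            raise ValueError("n_elites must be in [0, population_size]")
        for name in ("mutation_rate", "heritability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_size < 0 or self.selectivity < 0:
            raise ValueError("mutation_size and selectivity must be >= 0")


@dataclass
class FDGDConfig:
    """Finite-difference gradient descent hyperparameters (antithetic pairs)."""

    n_pairs: int = 10
    perturbation_size: float = 0.1
    learning_rate: float = 0.5

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.perturbation_size <= 0 or self.learning_rate <= 0:
            raise ValueError("perturbation_size and learning_rate must be > 0")


@dataclass
class NESConfig:
    """Natural-evolution-strategies hyperparameters."""

    n_samples: int = 20
    sigma: float = 0.5
    learning_rate: float = 0.5
    rank_utilities: bool = True

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.sigma <= 0 or self.learning_rate <= 0:
            raise ValueError("sigma and learning_rate must be > 0")


# ---------------------------------------------------------------------------
# Update rules
# ---------------------------------------------------------------------------

def _parent_probabilities(scores: np.ndarray, selectivity: float) -> np.ndarray:
    """Softmax of z-scored fitness; uniform when all scores tie."""
    std = scores.std()
    if std == 0.0:
        return np.full(scores.size, 1.0 / scores.size)
    z = selectivity * (scores - scores.mean()) / std
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def ga_propose(
    pop: ScoredPopulation, config: GAConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """One generation of selection, crossover and mutation.

    The top ``n_elites`` codes (score ties broken toward lower index) pass
    unchanged, kept in their original order.  Each remaining offspring takes
    every gene from parent A with probability ``heritability`` (else parent
    B), where both parents are drawn independently from the softmax
    selection distribution, then mutates per-gene.
    """
    codes = [as_code(c) for c in pop.codes]
    scores = np.asarray(pop.scores, dtype=np.float64)
    d = codes[0].size
    n = config.population_size

    # stable sort on -score: ties broken by lower index
    order = np.argsort(-scores, kind="stable")
    elite_idx = np.sort(order[: config.n_elites])
    next_gen = [codes[i].copy() for i in elite_idx]

    probs = _parent_probabilities(scores, config.selectivity)
    for _ in range(n - config.n_elites):
        pa = rng.choice(len(codes), p=probs)
        pb = rng.choice(len(codes), p=probs)
        from_a = rng.random(d) < config.heritability
        child = np.where(from_a, codes[pa], codes[pb])
        mutate = rng.random(d) < config.mutation_rate
        noise = rng.normal(0.0, config.mutation_size, size=d) if config.mutation_size > 0 else np.zeros(d)
        next_gen.append(child + np.where(mutate, noise, 0.0))
    return next_gen


def fdgd_propose(
    current: ImageCode,
    config: FDGDConfig,
    evaluate: Callable[[ImageCode], float],
    rng: np.random.Generator,
) -> ImageCode:
    """One FDGD step: antithetic central differences along random directions.

    Draws ``n_pairs`` random unit directions u_k, estimates the directional
    derivative by the central difference (f(c + eps*u) - f(c - eps*u)) /
    (2*eps), averages g_hat = mean_k [derivative_k * u_k], and ascends
    ``learning_rate * g_hat``.  Consumes exactly ``2 * n_pairs`` evaluations.
    """
    opt = FDGDOptimizer(current, config, rng)
    probes = opt.ask()
    opt.tell([evaluate(p) for p in probes])
    return opt.current


def nes_propose(
    current: ImageCode,
    config: NESConfig,
    evaluate: Callable[[ImageCode], float],
    rng: np.random.Generator,
) -> ImageCode:
    """One NES step: fitness-shaped weighting of Gaussian perturbations.

    Samples eps_i ~ N(0, sigma^2 I), scores f(c + eps_i), converts scores to
    zero-sum utilities (rank-based by default), and updates
    ``c + learning_rate / (n_samples * sigma) * sum_i u_i * eps_i``.
    All-tied scores give a zero update.
    """
    opt = NESOptimizer(current, config, rng)
    probes = opt.ask()
    opt.tell([evaluate(p) for p in probes])
    return opt.current


def nes_utilities(scores: np.ndarray, rank_based: bool = True) -> np.ndarray:
    """Zero-sum utilities from raw scores (rank-normalized or centered)."""
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.size
    if np.ptp(scores) == 0.0:
        return np.zeros(n)
    if rank_based:
        from scipy.stats import rankdata

        ranks = rankdata(scores, method="average") - 1.0  # average ranks keep zero sum
        return ranks / (n - 1.0) - 0.5
    return scores - scores.mean()


# ---------------------------------------------------------------------------
# Ask/tell optimizers driving the closed loop
# ---------------------------------------------------------------------------

class GeneticOptimizer:
    """Elitist genetic algorithm over a population of codes.

    Elites are re-presented (and re-scored) every generation rather than
    carrying a cached score: with a stochastic unit every presentation is a
    fresh trial, as in a physiology loop.
    """

    def __init__(
        self,
        init_codes: Sequence[ImageCode],
        config: GAConfig | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.config = config or GAConfig()
        if len(init_codes) != self.config.population_size:
            raise ValueError(
                f"need {self.config.population_size} initial codes, got {len(init_codes)}"
            )
        self._codes = [as_code(c) for c in init_codes]
        self.rng = np.random.default_rng(rng)
        self.generation = 0

    @property
    def per_step_budget(self) -> int:
        return self.config.population_size

    def ask(self) -> list[np.ndarray]:
        return [c.copy() for c in self._codes]

    def tell(self, scores: Sequence[float]) -> None:
        pop = ScoredPopulation(self._codes, np.asarray(scores, float), self.generation)
        self._codes = ga_propose(pop, self.config, self.rng)
        self.generation += 1


class FDGDOptimizer:
    """Naive finite-difference gradient ascent with antithetic probes."""

    def __init__(
        self,
        init_code: ImageCode,
        config: FDGDConfig | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.config = config or FDGDConfig()
        self.current = as_code(init_code)
        self.rng = np.random.default_rng(rng)
        self.generation = 0
        self._directions: np.ndarray | None = None

    @property
    def per_step_budget(self) -> int:
        return 2 * self.config.n_pairs

    def ask(self) -> list[np.ndarray]:
        d = self.current.size
        dirs = self.rng.standard_normal((self.config.n_pairs, d))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        self._directions = dirs
        eps = self.config.perturbation_size
        probes = []
        for u in dirs:
            probes.append(self.current + eps * u)
            probes.append(self.current - eps * u)
        return probes

    def tell(self, scores: Sequence[float]) -> None:
        if self._directions is None:
            raise RuntimeError("tell() before ask()")
        scores = np.asarray(scores, dtype=np.float64)
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite score passed to optimizer")
        if scores.size != self.per_step_budget:
            raise ValueError(f"expected {self.per_step_budget} scores, got {scores.size}")
        eps = self.config.perturbation_size
        f_plus, f_minus = scores[0::2], scores[1::2]
        derivs = (f_plus - f_minus) / (2.0 * eps)
        g_hat = (derivs[:, None] * self._directions).mean(axis=0)
        self.current = self.current + self.config.learning_rate * g_hat
        self._directions = None
        self.generation += 1


class NESOptimizer:
    """Natural evolution strategies with isotropic Gaussian search."""

    def __init__(
        self,
        init_code: ImageCode,
        config: NESConfig | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.config = config or NESConfig()
        self.current = as_code(init_code)
        self.rng = np.random.default_rng(rng)
        self.generation = 0
        self._perturbations: np.ndarray | None = None

    @property
    def per_step_budget(self) -> int:
        return self.config.n_samples

    def ask(self) -> list[np.ndarray]:
        eps = self.config.sigma * self.rng.standard_normal(
            (self.config.n_samples, self.current.size)
        )
        self._perturbations = eps
        return [self.current + e for e in eps]

    def tell(self, scores: Sequence[float]) -> None:
        if self._perturbations is None:
            raise RuntimeError("tell() before ask()")
        scores = np.asarray(scores, dtype=np.float64)
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite score passed to optimizer")
        if scores.size != self.per_step_budget:
            raise ValueError(f"expected {self.per_step_budget} scores, got {scores.size}")
        u = nes_utilities(scores, rank_based=self.config.rank_utilities)
        step = (u[:, None] * self._perturbations).sum(axis=0)
        n, sigma = self.config.n_samples, self.config.sigma
        self.current = self.current + self.config.learning_rate / (n * sigma) * step
        self._perturbations = None
        self.generation += 1


_CONFIG_CLASSES = {"ga": GAConfig, "fdgd": FDGDConfig, "nes": NESConfig}


def make_optimizer_config(name: str, overrides: dict | None = None):
    """Build a GA/FDGD/NES config dataclass from a name and override dict."""
    try:
        cls = _CONFIG_CLASSES[name]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_CONFIG_CLASSES)}")
    return cls(**(overrides or {}))


def build_optimizer(
    name: str,
    init_codes: Sequence[ImageCode],
    config=None,
    rng: np.random.Generator | int | None = None,
):
    """Instantiate an optimizer by name from an initial population.

    FDGD and NES are single-point methods; they start from the first
    initial code.
    """
    if config is None or isinstance(config, dict):
        config = make_optimizer_config(name, config)
    if name == "ga":
        return GeneticOptimizer(init_codes, config, rng)
    if name == "fdgd":
        return FDGDOptimizer(init_codes[0], config, rng)
    if name == "nes":
        return NESOptimizer(init_codes[0], config, rng)
    raise ValueError(f"unknown optimizer {name!r}")
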