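"""The closed loop: propose codes, render, score, log, iterate.

One run couples a generator, a target unit (optionally observed through a
calibrated Poisson spiking model) and an optimizer, and iterates until a
generation cap or a presentation budget is reached.  The default protocol
is 500 generations of 20 images — 10,000 total image presentations, a
number accessible in a single recording session — and the *optimized
image* is the best image of the final generation.

Reproducibility: one global seed is expanded through
``numpy.random.SeedSequence`` into independent per-component streams
(initialization, optimizer, noise calibration, noise observation), so e.g.
toggling noise does not perturb the initial population.  The same config
and seed reproduce a run byte-for-byte, including persisted logs.

Persisted outputs per run directory:

* ``log_presentations.csv`` — one row per presentation (generation,
  image id, true activation, observed score),
* ``log_generations.csv`` — per-generation summaries (best/mean true
  activation, best observed score, running best-so-far true activation),
* ``codes.h5`` — datasets ``codes/<generation>`` plus the optimized code,
* ``optimized.png`` — the optimized image,
* ``config_resolved.yaml`` — the fully resolved configuration.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from xdream import fixtures
from xdream.encoding import build_initial_population
from xdream.generators import (
    Generator,
    build_generator,
    save_codes,
    save_image,
)
from xdream.optimizers import build_optimizer, make_optimizer_config
from xdream.targets import (
    MatchedFilterUnit,
    NoisyUnit,
    OrientedChannel,
    SurroundSuppressionUnit,
    SurroundUnitSpec,
    TargetUnit,
    build_gabor_template,
    calibrate_rate_scale,
    resolve_unit,
)

__all__ = ["RunConfig", "EvolutionLog", "run_evolution", "load_run", "sweep", "build_unit"]


DEFAULTS: dict = {
    "generator": {"kind": "linear", "d": 64, "image_shape": [64, 64, 3], "seed": 0},
    "unit": {"kind": "battery", "seed": 0, "index": 0},
    "noise": {
        "enabled": False,
        "n_good": 20.0,
        "window_s": 0.2,
        "n_sample": 2500,
        "repeats": 10,
        "reference": {"n": 200, "n_groups": 10, "kind": "gabor-textures", "seed": 0},
    },
    "optimizer": {"name": "ga"},
    "init": {"source": "random", "rank": "best", "method": "ivt"},
    "loop": {"n_generations": 500, "max_presentations": 10_000},
    "seed": 0,
    "output_dir": None,
}


def _merge(defaults: dict, overrides: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class RunConfig:
    """Fully resolved configuration of one evolution run.

    Construct via :meth:`from_dict` / :meth:`from_yaml`, which merge user
    settings over the documented defaults.  ``seed`` fixes every stochastic
    component of the run.
    """

    generator: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["generator"]))
    unit: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["unit"]))
    noise: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["noise"]))
    optimizer: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["optimizer"]))
    init: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["init"]))
    n_generations: int = 500
    max_presentations: int = 10_000
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, settings: dict) -> "RunConfig":
        merged = _merge(DEFAULTS, settings)
        return cls(
            generator=merged["generator"],
            unit=merged["unit"],
            noise=merged["noise"],
            optimizer=merged["optimizer"],
            init=merged["init"],
            n_generations=int(merged["loop"]["n_generations"]),
            max_presentations=int(merged["loop"]["max_presentations"]),
            seed=int(merged["seed"]),
            output_dir=merged["output_dir"],
        )

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            settings = yaml.safe_load(fh) or {}
        return cls.from_dict(_merge(settings, overrides or {}))

    def to_dict(self) -> dict:
        return {
            "generator": copy.deepcopy(self.generator),
            "unit": copy.deepcopy(self.unit),
            "noise": copy.deepcopy(self.noise),
            "optimizer": copy.deepcopy(self.optimizer),
            "init": copy.deepcopy(self.init),
            "loop": {
                "n_generations": self.n_generations,
                "max_presentations": self.max_presentations,
            },
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def build_unit(spec: dict, image_shape: Sequence[int]) -> TargetUnit:
    """Instantiate a target unit from a config dict.

    Kinds: ``matched_gabor`` (matched filter on a Gabor template),
    ``matched_random`` (matched filter on seeded smoothed noise),
    ``surround`` (center-surround unit), ``battery`` (unit ``index`` of
    :func:`xdream.fixtures.make_unit_battery`), or ``adapter`` with a
    dotted ``path`` to any object satisfying the unit contract.
    """
    shape = tuple(int(s) for s in image_shape)
    kind = spec.get("kind", "battery")
    if kind == "matched_gabor":
        template = build_gabor_template(
            wavelength=float(spec.get("wavelength", shape[0] / 3.0)),
            orientation=float(spec.get("orientation", 0.0)),
            phase=float(spec.get("phase", 0.0)),
            sigma=spec.get("sigma", shape[0] / 3.0),
            shape=shape,
        )
        return MatchedFilterUnit(template, name="matched_gabor")
    if kind == "matched_random":
        from scipy import ndimage

        rng = np.random.default_rng(int(spec.get("seed", 0)))
        field_ = ndimage.gaussian_filter(rng.standard_normal(shape[:2]), 1.0)
        span = field_.max() - field_.min()
        plane = np.floor(255.0 * (field_ - field_.min()) / span + 0.5).astype(np.uint8)
        template = np.repeat(plane[:, :, None], shape[2], axis=2)
        return MatchedFilterUnit(template, name=f"matched_random_{spec.get('seed', 0)}")
    if kind == "surround":
        h, w = shape[0], shape[1]
        channel = OrientedChannel(
            wavelength=float(spec.get("wavelength", 4.0)),
            orientation=float(spec.get("orientation", 0.0)),
            sigma=float(spec.get("channel_sigma", 2.0)),
        )
        surround_channel = OrientedChannel(
            wavelength=float(spec.get("wavelength", 4.0)),
            orientation=float(spec.get("surround_orientation", spec.get("orientation", 0.0))),
            sigma=float(spec.get("channel_sigma", 2.0)),
        )
        sspec = SurroundUnitSpec(
            center=tuple(spec.get("center", ((h - 1) / 2.0, (w - 1) / 2.0))),
            r_exc=float(spec.get("r_exc", h / 6.0)),
            r_sur=float(spec.get("r_sur", h / 3.0)),
            beta=float(spec.get("beta", 1.0)),
            center_channel=channel,
            surround_channel=surround_channel,
        )
        return SurroundSuppressionUnit(sspec)
    if kind == "battery":
        battery = fixtures.make_unit_battery(int(spec.get("seed", 0)), image_shape=shape)
        return battery[int(spec.get("index", 0)) % len(battery)]
    if kind == "adapter":
        return resolve_unit(spec["path"])
    raise ValueError(f"unknown unit kind {kind!r}")


@dataclass
class EvolutionLog:
    """Complete record of one run.

    ``presentations`` has one row per presented image; ``generations`` one
    row per generation.  ``best_so_far`` tracks the running maximum of the
    true activation over everything presented, which is non-decreasing by
    construction; the per-generation best of an elitist noiseless GA run is
    additionally non-decreasing because the elite is re-presented.
    """

    presentations: pd.DataFrame
    generations: pd.DataFrame
    codes_by_generation: dict[int, np.ndarray]
    optimized_code: np.ndarray
    optimized_image: np.ndarray
    optimized_true_activation: float
    n_presentations: int
    config: RunConfig


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Expand the global seed into independent component streams."""
    root = np.random.SeedSequence(seed)
    names = ("init", "optimizer", "calibration", "noise")
    return {name: np.random.default_rng(s) for name, s in zip(names, root.spawn(len(names)))}


def run_evolution(config: RunConfig | dict) -> EvolutionLog:
    """Execute the closed loop described by ``config``.

    Stops at ``n_generations`` or as soon as the next generation would
    exceed ``max_presentations``, whichever comes first; the presentation
    counter is exact (population size per GA generation, ``2 * n_pairs``
    per FDGD step, ``n_samples`` per NES step).  With noise enabled the
    optimizer sees single-trial Poisson spike counts while the log also
    records the underlying true activations.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    rngs = _spawn_rngs(config.seed)

    generator = build_generator(config.generator)
    base_unit = build_unit(config.unit, generator.image_shape)

    scoring_unit: TargetUnit = base_unit
    if config.noise.get("enabled", False):
        ref_cfg = config.noise["reference"]
        refset = fixtures.make_reference_set(
            n=int(ref_cfg["n"]),
            n_groups=int(ref_cfg["n_groups"]),
            seed=int(ref_cfg.get("seed", 0)),
            kind=ref_cfg.get("kind", "gabor-textures"),
            image_shape=generator.image_shape,
        )
        calib = calibrate_rate_scale(
            base_unit,
            refset.images,
            n_sample=int(config.noise.get("n_sample", 2500)),
            repeats=int(config.noise.get("repeats", 10)),
            rng=rngs["calibration"],
            n_good=float(config.noise.get("n_good", 20.0)),
            window_s=float(config.noise.get("window_s", 0.2)),
        )
        scoring_unit = NoisyUnit(base_unit, calib, rngs["noise"])

    opt_cfg = dict(config.optimizer)
    opt_name = opt_cfg.pop("name", "ga")
    optimizer_config = make_optimizer_config(opt_name, opt_cfg)
    k = optimizer_config.population_size if opt_name == "ga" else 1
    init_cfg = config.init
    init_codes = build_initial_population(
        source=init_cfg.get("source", "random"),
        generator=generator,
        unit=base_unit,
        reference_images=init_cfg.get("reference_images"),
        rank=init_cfg.get("rank", "best"),
        k=k,
        method=init_cfg.get("method", "ivt"),
        rng=rngs["init"],
    )
    optimizer = build_optimizer(opt_name, init_codes, optimizer_config, rngs["optimizer"])

    pres_rows: list[tuple] = []
    gen_rows: list[tuple] = []
    codes_by_generation: dict[int, np.ndarray] = {}
    n_presentations = 0
    best_so_far = -np.inf
    last_codes: list[np.ndarray] = []
    last_true: np.ndarray = np.array([])
    last_observed: np.ndarray = np.array([])

    for gen in range(1, config.n_generations + 1):
        if n_presentations + optimizer.per_step_budget > config.max_presentations:
            break
        codes = optimizer.ask()
        images = [generator.generate(c) for c in codes]
        true_acts = np.array([base_unit.score(img) for img in images], dtype=np.float64)
        if scoring_unit is base_unit:
            observed = true_acts.copy()
        else:
            observed = np.array([scoring_unit.score(img) for img in images], dtype=np.float64)
        if not np.all(np.isfinite(observed)):
            raise RuntimeError(f"non-finite score at generation {gen}")

        for i, (t, o) in enumerate(zip(true_acts, observed)):
            pres_rows.append((gen, f"g{gen:04d}_i{i:02d}", t, o))
        n_presentations += len(codes)
        best_so_far = max(best_so_far, float(true_acts.max()))
        best_idx = int(np.argmax(observed))
        gen_rows.append(
            (
                gen,
                float(true_acts.max()),
                float(true_acts.mean()),
                float(observed[best_idx]),
                best_so_far,
                f"g{gen:04d}_i{best_idx:02d}",
            )
        )
        codes_by_generation[gen] = np.stack(codes)
        last_codes, last_true, last_observed = codes, true_acts, observed
        try:
            optimizer.tell(observed)
        except ValueError as exc:
            raise RuntimeError(f"optimizer failed at generation {gen}: {exc}") from exc

    if not gen_rows:
        raise ValueError("budget too small to run a single generation")

    # the optimized stimulus: best image (by observed score) of the last generation
    opt_idx = int(np.argmax(last_observed))
    optimized_code = last_codes[opt_idx]
    optimized_image = generator.generate(optimized_code)
    log = EvolutionLog(
        presentations=pd.DataFrame(
            pres_rows, columns=["generation", "image_id", "true_activation", "observed_score"]
        ),
        generations=pd.DataFrame(
            gen_rows,
            columns=[
                "generation",
                "best_true",
                "mean_true",
                "best_observed",
                "best_so_far_true",
                "best_image_id",
            ],
        ),
        codes_by_generation=codes_by_generation,
        optimized_code=optimized_code,
        optimized_image=optimized_image,
        optimized_true_activation=float(last_true[opt_idx]),
        n_presentations=n_presentations,
        config=config,
    )
    if config.output_dir:
        persist_run(log, config.output_dir)
    return log


def persist_run(log: EvolutionLog, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    log.presentations.to_csv(directory / "log_presentations.csv", index=False)
    log.generations.to_csv(directory / "log_generations.csv", index=False)
    codes = dict(log.codes_by_generation)
    save_codes(directory / "codes.h5", codes, seed=log.config.seed)
    import h5py

    with h5py.File(directory / "codes.h5", "a") as fh:
        fh.create_dataset("optimized_code", data=log.optimized_code, track_times=False)
    save_image(log.optimized_image, directory / "optimized.png")
    with open(directory / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(log.config.to_dict(), fh, sort_keys=False)


@dataclass
class LoadedRun:
    """A persisted run read back from disk."""

    presentations: pd.DataFrame
    generations: pd.DataFrame
    codes_by_generation: dict[int, np.ndarray]
    optimized_code: np.ndarray
    config: RunConfig


def load_run(directory: str | Path) -> LoadedRun:
    """Read a persisted run; round-trips the logged trajectories exactly."""
    import h5py

    directory = Path(directory)
    presentations = pd.read_csv(directory / "log_presentations.csv")
    generations = pd.read_csv(directory / "log_generations.csv")
    with h5py.File(directory / "codes.h5", "r") as fh:
        codes = {int(name): np.array(ds) for name, ds in fh["codes"].items()}
        optimized_code = np.array(fh["optimized_code"])
    with open(directory / "config_resolved.yaml") as fh:
        config = RunConfig.from_dict(yaml.safe_load(fh))
    return LoadedRun(
        presentations=presentations,
        generations=generations,
        codes_by_generation=codes,
        optimized_code=optimized_code,
        config=config,
    )


def _set_nested(d: dict, dotted_key: str, value) -> None:
    keys = dotted_key.split(".")
    node = d
    for key in keys[:-1]:
        node = node.setdefault(key, {})
    node[keys[-1]] = value


def sweep(
    template: RunConfig | dict,
    grid: dict[str, Sequence],
    unit_indices: Sequence[int] = (0,),
    seeds: Sequence[int] = (0,),
    refset: fixtures.ReferenceSet | None = None,
) -> pd.DataFrame:
    """Hyperparameter sweep: vary config keys on a grid across units and seeds.

    ``grid`` maps dotted config keys (e.g. ``"optimizer.mutation_rate"``)
    to value lists; the full cross-product of grid points x units x seeds
    is run.  Each row of the tidy result records the optimized true
    activation and, when a reference set is supplied, the relative
    activation against that unit's best reference image.  Failures of
    individual child runs are recorded (``error`` column) and the sweep
    continues.
    """
    if isinstance(template, RunConfig):
        template = template.to_dict()
    keys = list(grid.keys())
    rows = []
    ref_max_cache: dict[int, float] = {}
    for values in itertools.product(*(grid[k] for k in keys)):
        for unit_index in unit_indices:
            for seed in seeds:
                settings = copy.deepcopy(template)
                for key, value in zip(keys, values):
                    _set_nested(settings, key, value)
                _set_nested(settings, "unit.index", int(unit_index))
                _set_nested(settings, "seed", int(seed))
                settings["output_dir"] = None
                row = {k: v for k, v in zip(keys, values)}
                row.update({"unit_index": unit_index, "seed": seed})
                try:
                    config = RunConfig.from_dict(settings)
                    log = run_evolution(config)
                    row["optimized_true_activation"] = log.optimized_true_activation
                    row["n_presentations"] = log.n_presentations
                    if refset is not None:
                        if unit_index not in ref_max_cache:
                            gen = build_generator(config.generator)
                            unit = build_unit(config.unit, gen.image_shape)
                            ref_max_cache[unit_index] = max(
                                unit.score(img) for img in refset.images
                            )
                        row["relative_activation"] = (
                            log.optimized_true_activation / ref_max_cache[unit_index]
                        )
                    row["error"] = ""
                except Exception as exc:  # noqa: BLE001 — sweep must continue
                    row["optimized_true_activation"] = np.nan
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)
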