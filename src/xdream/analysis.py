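"""Evaluation metrics and study designs for closed-loop optimization runs.

The central yardstick is *relative activation*: a unit's response to an
image divided by its maximum response over a full reference image set.  By
construction the best reference image has relative activation 1, which
bounds what any random sampling of the reference set can achieve; an
optimized image exceeding 1 is a *super stimulus* — stronger than every
image in the reference set.

Around this metric the module implements the standard study designs:
random-sampling baseline curves (unrestricted vs. category-restricted),
code-space interpolation between separately optimized stimuli, the
initialization-quality slope (worst/middle/best seeded starts), and
fractional-change statistics across random re-initializations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from xdream.fixtures import ReferenceSet
from xdream.generators import Generator, interpolate_codes
from xdream.targets import TargetUnit

__all__ = [
    "relative_activation",
    "is_super_stimulus",
    "BaselineCurve",
    "random_sampling_baseline",
    "interpolation_curve",
    "SlopeFit",
    "initialization_slope",
    "FractionalChangeStats",
    "fractional_change_stats",
]


def relative_activation(a: float, a_ref_max: float) -> float:
    """Activation relative to the best reference image (``a / a_ref_max``)."""
    if a_ref_max <= 0:
        raise ValueError("reference maximum activation must be positive")
    return float(a) / float(a_ref_max)


def is_super_stimulus(rel_activation: float) -> bool:
    """True when an image beats every reference image (relative activation > 1)."""
    return rel_activation > 1.0


@dataclass
class BaselineCurve:
    """Max relative activation expected from random sampling, vs. sample size."""

    sizes: np.ndarray
    medians: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    scheme: str


def _grouped_sample(
    refset: ReferenceSet, n: int, n_groups: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices for category-restricted sampling: n_groups groups, n/n_groups each."""
    names = refset.group_names
    chosen_groups = rng.choice(len(names), size=n_groups, replace=False)
    per_group = max(1, n // n_groups)
    idx: list[int] = []
    for g in chosen_groups:
        members = refset.indices_of_group(names[g])
        replace = per_group > members.size
        idx.extend(rng.choice(members, size=per_group, replace=replace))
    return np.array(idx[:n])


def random_sampling_baseline(
    unit: TargetUnit,
    refset: ReferenceSet,
    sizes: Sequence[int],
    scheme: str = "unrestricted",
    n_groups: int = 10,
    repeats: int = 100,
    rng: np.random.Generator | int | None = None,
) -> BaselineCurve:
    """How good a stimulus does random sampling of ``n`` reference images find?

    For each sample size and repeat, draw images per the scheme —
    ``"unrestricted"``: n distinct images from the whole set;
    ``"grouped"``: first pick ``n_groups`` groups at random, then
    ``n / n_groups`` images from each (emulating stimulus selection
    restricted to a few categories) — and record the maximum relative
    activation in the draw.  The denominator is always the maximum
    activation over the full reference set, so sampling the entire set
    yields exactly 1.
    """
    sizes = np.asarray(list(sizes), dtype=int)
    if np.any(sizes < 1) or np.any(sizes > len(refset)):
        raise ValueError("sample sizes must be in [1, len(refset)]")
    if scheme not in ("unrestricted", "grouped"):
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    if scheme == "grouped" and len(refset.group_names) < n_groups:
        raise ValueError(
            f"grouped scheme needs >= {n_groups} groups, set has {len(refset.group_names)}"
        )
    rng = np.random.default_rng(rng)
    activations = np.array([unit.score(img) for img in refset.images])
    a_max = activations.max()
    if a_max <= 0:
        raise ValueError("unit does not respond to any reference image")
    rel = activations / a_max

    medians, q25s, q75s = [], [], []
    for n in sizes:
        maxima = np.empty(repeats)
        for r in range(repeats):
            if scheme == "unrestricted":
                idx = rng.choice(len(refset), size=n, replace=False)
            else:
                idx = _grouped_sample(refset, int(n), n_groups, rng)
            maxima[r] = rel[idx].max()
        q25, med, q75 = np.percentile(maxima, [25, 50, 75])
        medians.append(med)
        q25s.append(q25)
        q75s.append(q75)
    return BaselineCurve(
        sizes=sizes,
        medians=np.array(medians),
        q25=np.array(q25s),
        q75=np.array(q75s),
        scheme=scheme,
    )


def interpolation_curve(
    unit: TargetUnit,
    generator: Generator,
    c1: np.ndarray,
    c2: np.ndarray,
    n_points: int = 11,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit activation along the code-space line between two optimized codes.

    Evaluates the unit on images generated at ``n_points`` evenly spaced
    interpolation locations alpha in [0, 1].  With ``normalize=True`` each
    activation is divided by the activation of the nearer endpoint
    (alpha <= 0.5 -> left), so the curve equals 1 at both ends and dips
    below 1 wherever intermediate images are weaker stimuli — evidence that
    the two optima are not connected by a high-activation straight path.

    Returns ``(alphas, activations)``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    alphas = np.linspace(0.0, 1.0, n_points)
    acts = np.array(
        [unit.score(generator.generate(interpolate_codes(c1, c2, a))) for a in alphas]
    )
    if normalize:
        a0, a1 = acts[0], acts[-1]
        if a0 <= 0 or a1 <= 0:
            raise ValueError("cannot normalize: an endpoint activation is <= 0")
        acts = acts / np.where(alphas <= 0.5, a0, a1)
    return alphas, acts


@dataclass
class SlopeFit:
    """Least-squares line through three rank-band medians at x = {0, 1, 2}."""

    slope: float
    intercept: float
    fitted: np.ndarray


def initialization_slope(medians_by_quality: Sequence[float]) -> SlopeFit:
    """Improvement per initialization-quality step (worst -> middle -> best).

    Takes the median relative activation achieved from worst-, middle- and
    best-seeded initial populations, regresses on x = {0, 1, 2}, and
    returns the fit.  For three equally spaced points the least-squares
    slope reduces to ``(m_best - m_worst) / 2``.
    """
    y = np.asarray(list(medians_by_quality), dtype=np.float64)
    if y.size != 3 or not np.all(np.isfinite(y)):
        raise ValueError("expected three finite medians (worst, middle, best)")
    x = np.array([0.0, 1.0, 2.0])
    slope, intercept = np.polyfit(x, y, 1)
    return SlopeFit(slope=float(slope), intercept=float(intercept), fitted=slope * x + intercept)


@dataclass
class FractionalChangeStats:
    """Spread of optimized activation across random re-initializations."""

    changes: np.ndarray
    mean: float
    sd: float


def fractional_change_stats(
    optimized_activations: Sequence[float], reference_activation: float
) -> FractionalChangeStats:
    """Fractional change ``(a_i - a_ref) / a_ref`` per re-initialization.

    ``a_ref`` is the optimized activation of the original initialization;
    a small spread means the search outcome is insensitive to the random
    starting population.  The sd is the sample standard deviation (ddof=1).
    """
    if reference_activation <= 0:
        raise ValueError("reference activation must be positive")
    a = np.asarray(list(optimized_activations), dtype=np.float64)
    changes = (a - reference_activation) / reference_activation
    sd = float(changes.std(ddof=1)) if changes.size > 1 else 0.0
    return FractionalChangeStats(changes=changes, mean=float(changes.mean()), sd=sd)
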