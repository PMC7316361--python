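"""Target units (the fitness function) and the Poisson observation model.

A *target unit* is any black box mapping an image to a scalar activation —
in silico, a model unit; in an experiment, a neuron's spike count.  The
optimizers only ever see these scalars, so everything here is exchangeable
with a live recording through the same ``score(image) -> float`` contract.

Built-in units are deliberately simple receptive-field models with known
optima, so that optimizer behaviour can be checked against ground truth:

* :class:`MatchedFilterUnit` — normalized correlation with a template; the
  template itself is the unique optimum (score 1).
* :class:`SurroundSuppressionUnit` — an oriented filter pooled over a
  central excitatory disc minus a weighted concentric suppressive annulus,
  a toy model of extra-classical surround suppression.

Biological response variability is modelled as a homogeneous Poisson
process: the true activation sets the rate, and a single trial returns one
Poisson draw.  The rate scale is calibrated so that a "good stimulus" — the
expected best image among ``n_sample`` random reference images — yields a
target expected spike count (default 20, i.e. 100 spikes/s over a 200 ms
window).  Because sd/mean of a Poisson count is ``1/sqrt(rate)``, this
single number controls the noise level.
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from xdream.generators import quantize

__all__ = [
    "TargetUnit",
    "MatchedFilterUnit",
    "SurroundSuppressionUnit",
    "SurroundUnitSpec",
    "OrientedChannel",
    "NoisyUnit",
    "NoiseCalibration",
    "NoiseMetrics",
    "matched_filter_score",
    "build_gabor_template",
    "oriented_response_map",
    "pool_center_surround",
    "surround_suppression_score",
    "calibrate_rate_scale",
    "poisson_observe",
    "noise_metrics",
    "resolve_unit",
]


@runtime_checkable
class TargetUnit(Protocol):
    """Contract for a deterministic image -> scalar activation scorer."""

    name: str

    def score(self, image: np.ndarray) -> float: ...


def resolve_unit(dotted_path: str) -> TargetUnit:
    """Import a unit adapter by dotted path ``pkg.module:attr``."""
    module_name, _, attr = dotted_path.replace(":", ".").rpartition(".")
    if not module_name:
        raise ValueError(f"not a dotted path: {dotted_path!r}")
    obj = getattr(importlib.import_module(module_name), attr)
    if callable(obj) and not hasattr(obj, "score"):
        obj = obj()
    if not isinstance(obj, TargetUnit):
        raise TypeError(f"{dotted_path!r} does not satisfy the unit contract")
    return obj


# ---------------------------------------------------------------------------
# Matched-filter units
# ---------------------------------------------------------------------------

def _center_unit_norm(arr: np.ndarray) -> np.ndarray | None:
    """Mean-center and L2-normalize a flattened array; None if constant."""
    flat = np.asarray(arr, dtype=np.float64).ravel()
    flat = flat - flat.mean()
    norm = np.linalg.norm(flat)
    if norm == 0.0:
        return None
    return flat / norm


def matched_filter_score(image: np.ndarray, template: np.ndarray) -> float:
    """Rectified normalized cross-correlation of image with a template.

    ``max(0, <x_hat, t_hat>)`` where both arrays are mean-centered and
    unit-normalized after flattening.  Range [0, 1]; the template itself
    scores exactly 1.  A constant image scores 0 (it carries no pattern).
    """
    if np.shape(image) != np.shape(template):
        raise ValueError(
            f"shape mismatch: image {np.shape(image)} vs template {np.shape(template)}"
        )
    t_hat = _center_unit_norm(template)
    if t_hat is None:
        raise ValueError("template must not be constant")
    x_hat = _center_unit_norm(image)
    if x_hat is None:
        return 0.0
    return float(max(0.0, x_hat @ t_hat))


@dataclass
class MatchedFilterUnit:
    """Target unit scoring rectified template correlation; optimum = template."""

    template: np.ndarray
    name: str = "matched_filter"
    gain: float = 1.0  # output scale; relative activation is gain-invariant

    def score(self, image: np.ndarray) -> float:
        return self.gain * matched_filter_score(image, self.template)


def build_gabor_template(
    wavelength: float,
    orientation: float,
    phase: float = 0.0,
    sigma: float | None = None,
    shape: tuple[int, int, int] = (64, 64, 3),
) -> np.ndarray:
    """Gabor patch (sinusoidal carrier x Gaussian envelope) as an 8-bit image.

    Parameters
    ----------
    wavelength:
        Carrier wavelength in pixels (> 0).
    orientation:
        Carrier orientation in radians; the carrier varies along this axis.
    phase:
        Carrier phase in radians.
    sigma:
        Envelope standard deviation in pixels; ``None`` or ``inf`` gives a
        pure grating (envelope identically 1).
    shape:
        Output image shape ``(H, W, C)``; channels are identical.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if sigma is not None and not np.isinf(sigma) and sigma <= 0:
        raise ValueError("sigma must be positive (or None/inf for a grating)")
    h, w, c = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    u = (xx - cx) * np.cos(orientation) + (yy - cy) * np.sin(orientation)
    carrier = np.cos(2.0 * np.pi * u / wavelength + phase)
    if sigma is None or np.isinf(sigma):
        envelope = 1.0
    else:
        rr2 = (xx - cx) ** 2 + (yy - cy) ** 2
        envelope = np.exp(-rr2 / (2.0 * sigma**2))
    values = carrier * envelope  # in [-1, 1]
    plane = quantize(255.0 * (values + 1.0) / 2.0)
    return np.repeat(plane[:, :, None], c, axis=2)


# ---------------------------------------------------------------------------
# Surround-suppression units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientedChannel:
    """Parameters of a small oriented (Gabor) filter used as a feature channel."""

    wavelength: float = 4.0
    orientation: float = 0.0
    phase: float = 0.0
    sigma: float = 2.0
    size: int = 9  # kernel side length (odd)

    def kernel(self) -> np.ndarray:
        if self.wavelength <= 0 or self.sigma <= 0:
            raise ValueError("wavelength and sigma must be positive")
        half = self.size // 2
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
        u = xx * np.cos(self.orientation) + yy * np.sin(self.orientation)
        carrier = np.cos(2.0 * np.pi * u / self.wavelength + self.phase)
        envelope = np.exp(-(xx**2 + yy**2) / (2.0 * self.sigma**2))
        k = carrier * envelope
        return k - k.mean()  # zero-mean: constant images respond 0


@dataclass(frozen=True)
class SurroundUnitSpec:
    """Center-surround pooling geometry over oriented-filter responses.

    A circular excitatory disc of radius ``r_exc`` around ``center`` pools
    the (rectified) response of ``center_channel``; the concentric annulus
    out to ``r_sur`` pools ``surround_channel`` with weight ``beta`` and
    suppresses the unit.  With distinct channels the unit prefers e.g. a
    horizontal pattern in the center with no vertical energy around it.
    """

    center: tuple[float, float]  # (row, col) in pixels
    r_exc: float
    r_sur: float
    beta: float = 1.0
    center_channel: OrientedChannel = OrientedChannel()
    surround_channel: OrientedChannel = OrientedChannel()

    def validate(self, image_shape: tuple[int, ...]) -> None:
        h, w = image_shape[0], image_shape[1]
        half_extent = min(h, w) / 2.0
        if not (0 < self.r_exc < self.r_sur <= half_extent):
            raise ValueError(
                f"radii must satisfy 0 < r_exc < r_sur <= {half_extent}, "
                f"got r_exc={self.r_exc}, r_sur={self.r_sur}"
            )
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def masks(self, image_shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
        h, w = image_shape[0], image_shape[1]
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        dist = np.hypot(yy - self.center[0], xx - self.center[1])
        disc = dist <= self.r_exc
        annulus = (dist > self.r_exc) & (dist <= self.r_sur)
        return disc, annulus


def oriented_response_map(image: np.ndarray, channel: OrientedChannel) -> np.ndarray:
    """Rectified per-pixel response of an oriented filter (grayscale input)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    img = img / 255.0
    response = ndimage.correlate(img, channel.kernel(), mode="constant", cval=img.mean())
    return np.maximum(response, 0.0)


def pool_center_surround(
    e_center: np.ndarray, e_surround: np.ndarray, spec: SurroundUnitSpec
) -> float:
    """Pool response maps: rectified (disc sum - beta * annulus sum)."""
    spec.validate(e_center.shape)
    disc, annulus = spec.masks(e_center.shape)
    drive = float(e_center[disc].sum()) - spec.beta * float(e_surround[annulus].sum())
    return max(0.0, drive)


def surround_suppression_score(image: np.ndarray, spec: SurroundUnitSpec) -> float:
    """Activation of a center-surround unit on an image.

    The center channel's rectified oriented response is summed inside the
    excitatory disc; the surround channel's response over the annulus is
    subtracted with weight ``beta``; the total is rectified.
    """
    spec.validate(np.shape(image))
    e_center = oriented_response_map(image, spec.center_channel)
    if spec.surround_channel == spec.center_channel:
        e_surround = e_center
    else:
        e_surround = oriented_response_map(image, spec.surround_channel)
    return pool_center_surround(e_center, e_surround, spec)


@dataclass
class SurroundSuppressionUnit:
    spec: SurroundUnitSpec
    name: str = "surround_suppression"

    def score(self, image: np.ndarray) -> float:
        return surround_suppression_score(image, self.spec)


# ---------------------------------------------------------------------------
# Poisson observation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseCalibration:
    """Calibrated activation -> spike-rate mapping for the Poisson model.

    ``a_good`` is the good-stimulus activation (the expected best among
    ``n_sample`` random reference images); ``n_good`` is the expected spike
    count it should evoke.  The rate for any activation ``a`` is then
    ``scale * max(a, 0)`` with ``scale = n_good / a_good``.
    """

    a_good: float
    n_good: float = 20.0
    window_s: float = 0.2
    rate_hz: float = 100.0

    def __post_init__(self):
        if self.a_good <= 0:
            raise ValueError("a_good must be positive")
        if self.n_good <= 0:
            raise ValueError("n_good must be positive")
        if not np.isclose(self.n_good, self.rate_hz * self.window_s):
            raise ValueError(
                f"inconsistent calibration: n_good={self.n_good} != "
                f"rate_hz*window_s={self.rate_hz * self.window_s}"
            )

    @classmethod
    def from_spike_count(cls, a_good: float, n_good: float = 20.0, window_s: float = 0.2):
        """Build a calibration from a target spike count, deriving the rate."""
        return cls(a_good=a_good, n_good=n_good, window_s=window_s, rate_hz=n_good / window_s)

    @property
    def scale(self) -> float:
        return self.n_good / self.a_good

    def rate(self, activation: float) -> float:
        return self.scale * max(float(activation), 0.0)


def calibrate_rate_scale(
    unit: TargetUnit,
    reference_images: Sequence[np.ndarray],
    n_sample: int = 2500,
    repeats: int = 10,
    rng: np.random.Generator | int | None = None,
    n_good: float = 20.0,
    window_s: float = 0.2,
) -> NoiseCalibration:
    """Calibrate the Poisson rate scale against a reference image set.

    The good-stimulus activation ``a_good`` is estimated as the average,
    over ``repeats`` resamples, of the maximum activation among ``n_sample``
    images drawn with replacement from the reference set — a Monte-Carlo
    estimate of the expected best-of-``n_sample`` activation.
    """
    if len(reference_images) == 0:
        raise ValueError("reference set must be non-empty")
    if repeats < 1 or n_sample < 1:
        raise ValueError("repeats and n_sample must be >= 1")
    rng = np.random.default_rng(rng)
    activations = np.array([unit.score(img) for img in reference_images])
    maxima = [
        activations[rng.integers(0, activations.size, size=n_sample)].max()
        for _ in range(repeats)
    ]
    a_good = float(np.mean(maxima))
    if a_good <= 0:
        raise ValueError("calibration failed: unit never responds to the reference set")
    return NoiseCalibration.from_spike_count(a_good=a_good, n_good=n_good, window_s=window_s)


def poisson_observe(
    activation: float, calib: NoiseCalibration, rng: np.random.Generator
) -> int:
    """One single-trial spike count: a Poisson draw at the calibrated rate.

    Negative activations map to rate 0 (spike counts are non-negative).
    """
    return int(rng.poisson(calib.rate(activation)))


@dataclass
class NoisyUnit:
    """A target unit observed through single-trial Poisson spike counts.

    ``score`` returns a fresh stochastic observation each call — repeated
    presentations of the same image give different counts, as for a real
    neuron.  ``true_score`` exposes the underlying deterministic activation
    for evaluation purposes only; the optimizers never see it.
    """

    base: TargetUnit
    calib: NoiseCalibration
    rng: np.random.Generator
    name: str = "noisy"

    def __post_init__(self):
        self.name = f"noisy({self.base.name})"

    def score(self, image: np.ndarray) -> float:
        return float(poisson_observe(self.base.score(image), self.calib, self.rng))

    def true_score(self, image: np.ndarray) -> float:
        return float(self.base.score(image))


@dataclass(frozen=True)
class NoiseMetrics:
    """Empirical noise level of a calibrated unit.

    self_correlation:
        Pearson correlation, across probe images, between two independent
        single-trial response vectors (trial-to-trial reliability).
    sd_over_mean_at_good:
        Analytic Poisson sd/mean at the good stimulus, ``1/sqrt(n_good)``.
    snr:
        Spread of true rates across probes divided by the mean single-trial
        standard deviation ``sqrt(rate)``.
    """

    self_correlation: float
    sd_over_mean_at_good: float
    snr: float


def noise_metrics(
    unit: TargetUnit,
    calib: NoiseCalibration,
    probe_images: Sequence[np.ndarray],
    rng: np.random.Generator | int | None = None,
) -> NoiseMetrics:
    """Quantify the calibrated noise level on a battery of probe images."""
    if len(probe_images) < 20:
        raise ValueError("need at least 20 probe images")
    rng = np.random.default_rng(rng)
    rates = np.array([calib.rate(unit.score(img)) for img in probe_images])
    if np.allclose(rates, rates[0]):
        raise ValueError("probe activations are constant; correlation undefined")
    trial_a = rng.poisson(rates)
    trial_b = rng.poisson(rates)
    r, _ = pearsonr(trial_a, trial_b)
    lam_good = calib.scale * calib.a_good  # == n_good by construction
    return NoiseMetrics(
        self_correlation=float(r),
        sd_over_mean_at_good=float(1.0 / np.sqrt(lam_good)),
        snr=float(rates.std() / np.sqrt(rates).mean()),
    )
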