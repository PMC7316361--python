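"""Image generators: deterministic maps from latent codes to 8-bit images.

A generator defines the search space of the closed loop.  Every generator
exposes the same minimal contract:

``d``
    latent dimensionality (length of an image code),
``image_shape``
    ``(H, W, C)`` of the produced images, ``C`` in ``{1, 3}``,
``generate(code) -> uint8 array``
    a pure function of the code: identical codes give bit-identical images.

Two desk-scale generators are built in.  :class:`PixelGenerator` represents
images directly as pixels (an affine map from code entries in ``[-1, 1]`` to
intensities), the simplest possible search space and a useful control.
:class:`LinearGenerator` pushes a low-dimensional code through a fixed random
linear basis and a sigmoid, giving a smooth non-trivial code -> image map
with far fewer degrees of freedom than pixels.  Pretrained inverting
generators (e.g. DeePSiM, whose fc6 variant conventionally uses d=4096 codes)
plug in through the same contract via :func:`resolve_adapter`.
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import h5py
import numpy as np
from PIL import Image as PILImage

__all__ = [
    "ImageCode",
    "GeneratorSpec",
    "PixelGenerator",
    "LinearGenerator",
    "build_generator",
    "resolve_adapter",
    "interpolate_codes",
    "quantize",
    "save_image",
    "load_image",
    "save_codes",
    "load_codes",
]

# An image code is a 1-D float vector; images are (H, W, C) uint8 arrays.
ImageCode = np.ndarray


def as_code(values, d: int | None = None) -> np.ndarray:
    """Validate and coerce ``values`` to a finite float64 code vector."""
    code = np.asarray(values, dtype=np.float64).ravel()
    if code.size == 0:
        raise ValueError("image code must be non-empty")
    if not np.all(np.isfinite(code)):
        raise ValueError("image code entries must be finite")
    if d is not None and code.size != d:
        raise ValueError(f"code has length {code.size}, generator expects {d}")
    return code


def quantize(values: np.ndarray) -> np.ndarray:
    """Map float intensities to uint8: clip to [0, 255], round half up.

    Half-up rounding (rather than numpy's banker's rounding) is fixed so
    that golden images are bit-stable across platforms.
    """
    clipped = np.clip(values, 0.0, 255.0)
    return np.floor(clipped + 0.5).clip(0, 255).astype(np.uint8)


def interpolate_codes(c1: ImageCode, c2: ImageCode, alpha: float) -> ImageCode:
    """Linear interpolation ``(1 - alpha) * c1 + alpha * c2`` in code space.

    Interpolating between two separately optimized codes and rendering the
    intermediate images probes whether the strong stimuli found from
    different initializations lie on a connected high-activation manifold.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    c1 = as_code(c1)
    c2 = as_code(c2, d=c1.size)
    return (1.0 - alpha) * c1 + alpha * c2


@runtime_checkable
class Generator(Protocol):
    """Structural contract for any code -> image generator."""

    d: int
    image_shape: tuple[int, int, int]

    def generate(self, code: ImageCode) -> np.ndarray: ...


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a generator, resolvable from config.

    Parameters
    ----------
    kind:
        ``"pixel"``, ``"linear"``, or a dotted import path to an external
        adapter object/factory satisfying the :class:`Generator` contract.
    d:
        Latent dimensionality.  For the pixel generator ``d`` must equal
        ``H * W * C``; passing ``d`` alone implies a square single-channel
        image when the shape is omitted.
    image_shape:
        ``(H, W, C)`` of generated images.
    seed:
        Seed of the random basis (linear generator only).
    """

    kind: str = "linear"
    d: int = 64
    image_shape: tuple[int, int, int] = (64, 64, 3)
    seed: int = 0

    def build(self) -> "Generator":
        return build_generator(self)


class PixelGenerator:
    """Generator representing images directly as pixels.

    Each code entry is one pixel; intensity ``p = clip(255 * (c + 1) / 2)``,
    i.e. the declared code domain is ``[-1, 1]`` with clipping outside it.
    """

    #: standard deviation used when drawing random initial codes, chosen so
    #: draws mostly fall inside the declared [-1, 1] code domain
    init_scale = 0.5

    def __init__(self, image_shape: tuple[int, int, int] = (8, 8, 1)):
        h, w, c = image_shape
        if c not in (1, 3):
            raise ValueError("channel count must be 1 or 3")
        self.image_shape = (int(h), int(w), int(c))
        self.d = int(h) * int(w) * int(c)

    def generate(self, code: ImageCode) -> np.ndarray:
        code = as_code(code, d=self.d)
        return quantize(255.0 * (code + 1.0) / 2.0).reshape(self.image_shape)

    def encode(self, image: np.ndarray) -> ImageCode:
        """Exact affine inverse of :meth:`generate` (up to quantization)."""
        pixels = np.asarray(image, dtype=np.float64).ravel()
        if pixels.size != self.d:
            raise ValueError("image shape does not match generator")
        return 2.0 * pixels / 255.0 - 1.0


class LinearGenerator:
    """Low-dimensional generator: fixed random basis + sigmoid + quantize.

    ``image = quantize(255 * sigmoid(B @ code))`` with ``B`` a seeded
    ``(H*W*C, d)`` Gaussian matrix with unit-norm columns.  The sigmoid keeps
    intensities in range for any code, and the random basis gives every code
    direction a distributed, smooth effect on the image.
    """

    init_scale = 1.0

    def __init__(self, d: int = 64, image_shape: tuple[int, int, int] = (64, 64, 3), seed: int = 0):
        h, w, c = image_shape
        if c not in (1, 3):
            raise ValueError("channel count must be 1 or 3")
        if d <= 0:
            raise ValueError("latent dimensionality must be positive")
        self.d = int(d)
        self.image_shape = (int(h), int(w), int(c))
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        basis = rng.standard_normal((h * w * c, self.d))
        basis /= np.linalg.norm(basis, axis=0, keepdims=True)
        self.basis = basis

    def generate(self, code: ImageCode) -> np.ndarray:
        code = as_code(code, d=self.d)
        from scipy.special import expit

        intensities = 255.0 * expit(self.basis @ code)
        return quantize(intensities).reshape(self.image_shape)


def resolve_adapter(dotted_path: str):
    """Import an external adapter by dotted path ``pkg.module:attr``.

    The resolved object (or the result of calling it, if it is a class or
    factory taking no arguments) must expose ``d``, ``image_shape`` and
    ``generate``.
    """
    module_name, _, attr = dotted_path.replace(":", ".").rpartition(".")
    if not module_name:
        raise ValueError(f"not a dotted path: {dotted_path!r}")
    obj = getattr(importlib.import_module(module_name), attr)
    if callable(obj) and not hasattr(obj, "generate"):
        obj = obj()
    if not isinstance(obj, Generator):
        raise TypeError(f"{dotted_path!r} does not satisfy the generator contract")
    return obj


def build_generator(spec: GeneratorSpec | dict) -> Generator:
    """Instantiate a generator from a :class:`GeneratorSpec` or config dict."""
    if isinstance(spec, dict):
        spec = GeneratorSpec(
            kind=spec.get("kind", "linear"),
            d=int(spec.get("d", 64)),
            image_shape=tuple(spec.get("image_shape", (64, 64, 3))),
            seed=int(spec.get("seed", 0)),
        )
    if spec.kind == "pixel":
        gen = PixelGenerator(image_shape=spec.image_shape)
        if gen.d != spec.d:
            raise ValueError(
                f"pixel generator requires d == H*W*C ({gen.d}), got d={spec.d}"
            )
        return gen
    if spec.kind == "linear":
        return LinearGenerator(d=spec.d, image_shape=spec.image_shape, seed=spec.seed)
    return resolve_adapter(spec.kind)


# ---------------------------------------------------------------------------
# I/O: images as 8-bit PNG, codes in an HDF5 container
# ---------------------------------------------------------------------------

def save_image(image: np.ndarray, path: str | Path) -> None:
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[2] == 1:
        image = image[:, :, 0]
    PILImage.fromarray(image.astype(np.uint8)).save(str(path), format="PNG")


def load_image(path: str | Path) -> np.ndarray:
    arr = np.asarray(PILImage.open(str(path)))
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def save_codes(path: str | Path, codes_by_generation: dict[int, np.ndarray], seed: int | None = None) -> None:
    """Checkpoint codes as datasets ``codes/<generation>`` with a ``seed`` attr."""
    with h5py.File(str(path), "w") as fh:
        grp = fh.create_group("codes")
        if seed is not None:
            fh.attrs["seed"] = int(seed)
        for gen_idx, codes in codes_by_generation.items():
            grp.create_dataset(str(int(gen_idx)), data=np.asarray(codes, dtype=np.float64), track_times=False)


def load_codes(path: str | Path) -> tuple[dict[int, np.ndarray], int | None]:
    with h5py.File(str(path), "r") as fh:
        seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
        codes = {int(name): np.array(ds) for name, ds in fh["codes"].items()}
    return codes, seed
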