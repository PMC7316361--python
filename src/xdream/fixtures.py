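"""Synthetic reference sets and target-unit batteries.

Real applications of the closed loop compare optimized stimuli against a
large natural-image reference set and evaluate many units per processing
stage.  At desk scale those are replaced by deterministic synthetic
stand-ins: structured image sets with category-like groups (so that some
units genuinely prefer some groups), and batteries of toy receptive-field
units with analytically known optima.  Everything is a pure function of its
seed, so tests and experiments are exactly reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from xdream.generators import load_image, quantize, save_image
from xdream.targets import (
    MatchedFilterUnit,
    OrientedChannel,
    SurroundSuppressionUnit,
    SurroundUnitSpec,
    TargetUnit,
    build_gabor_template,
)

__all__ = [
    "ReferenceSet",
    "make_reference_set",
    "make_unit_battery",
    "save_reference_dir",
    "load_reference_dir",
]


@dataclass
class ReferenceSet:
    """A deterministic set of images with category-like group labels."""

    images: list[np.ndarray]
    groups: list[str]
    seed: int

    def __post_init__(self):
        if len(self.images) != len(self.groups):
            raise ValueError("one group label per image required")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups))

    def indices_of_group(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group])


def _gabor_texture_image(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    wavelength: float,
    orientation: float,
    noise_sd: float,
) -> np.ndarray:
    """A group-typical Gabor patch with jittered envelope plus pixel noise."""
    sigma = max(shape[0] / 4.0 * rng.uniform(0.8, 1.2), 1.0)
    base = build_gabor_template(wavelength, orientation, 0.0, sigma, shape).astype(np.float64)
    noisy = base + rng.normal(0.0, noise_sd, size=base.shape)
    return quantize(noisy)


def _filtered_noise_image(
    rng: np.random.Generator, shape: tuple[int, int, int], smoothing: float
) -> np.ndarray:
    """White noise smoothed at a group-specific scale, stretched to [0, 255]."""
    h, w, c = shape
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), smoothing)
    span = field.max() - field.min()
    plane = (field - field.min()) / span if span > 0 else np.full((h, w), 0.5)
    return np.repeat(quantize(255.0 * plane)[:, :, None], c, axis=2)


def make_reference_set(
    n: int,
    n_groups: int,
    seed: int,
    kind: str = "gabor-textures",
    image_shape: tuple[int, int, int] = (16, 16, 1),
    noise_sd: float = 40.0,
) -> ReferenceSet:
    """Build a synthetic reference set of ``n`` images in ``n_groups`` groups.

    Groups differ systematically — by carrier orientation and wavelength for
    ``"gabor-textures"``, by smoothing scale for ``"filtered-noise"`` — so a
    unit built from one group's generating parameters prefers that group.
    ``n`` must be divisible by ``n_groups``; images per group is ``n /
    n_groups`` and the set is fully determined by ``seed``.
    """
    if n <= 0 or n_groups <= 0 or n % n_groups != 0:
        raise ValueError("n must be a positive multiple of n_groups")
    if kind not in ("gabor-textures", "filtered-noise"):
        raise ValueError(f"unknown reference-set kind {kind!r}")
    rng = np.random.default_rng(seed)
    per_group = n // n_groups
    images: list[np.ndarray] = []
    groups: list[str] = []
    for g in range(n_groups):
        params = group_parameters(g, n_groups, image_shape)
        for _ in range(per_group):
            if kind == "gabor-textures":
                img = _gabor_texture_image(
                    rng, image_shape, params["wavelength"], params["orientation"], noise_sd
                )
            else:
                img = _filtered_noise_image(rng, image_shape, params["smoothing"])
            images.append(img)
            groups.append(f"group{g:02d}")
    return ReferenceSet(images=images, groups=groups, seed=seed)


def group_parameters(g: int, n_groups: int, image_shape: tuple[int, int, int]) -> dict:
    """Generating parameters of group ``g``: orientation/wavelength bands."""
    h = image_shape[0]
    return {
        "orientation": np.pi * g / n_groups,
        "wavelength": max(3.0, h / 4.0) * (1.0 + 0.5 * (g % 3)),
        "smoothing": 0.5 + 0.5 * g,
    }


def make_unit_battery(
    seed: int,
    image_shape: tuple[int, int, int] = (16, 16, 1),
    n_units: int = 12,
) -> list[TargetUnit]:
    """A deterministic battery of toy units with known preferred stimuli.

    Mixes three families in rotation: matched filters on Gabor templates
    (known optimum: the template, score exactly 1), matched filters on
    smoothed-noise templates (same property, less structured optimum), and
    center-surround units (optimum not in closed form, but blank images
    score 0 and center-confined patterns beat full-field ones).
    """
    rng = np.random.default_rng(seed)
    h, w, _ = image_shape
    units: list[TargetUnit] = []
    for i in range(n_units):
        family = i % 3
        if family == 0:
            template = build_gabor_template(
                wavelength=float(rng.uniform(max(3.0, h / 5.0), h / 2.0)),
                orientation=float(rng.uniform(0.0, np.pi)),
                phase=0.0,
                sigma=float(rng.uniform(h / 5.0, h / 2.0)),
                shape=image_shape,
            )
            units.append(MatchedFilterUnit(template, name=f"gabor_mf_{i}"))
        elif family == 1:
            field = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.0)
            span = field.max() - field.min()
            plane = quantize(255.0 * (field - field.min()) / span)
            template = np.repeat(plane[:, :, None], image_shape[2], axis=2)
            units.append(MatchedFilterUnit(template, name=f"noise_mf_{i}"))
        else:
            r_exc = float(rng.uniform(h / 6.0, h / 4.0))
            r_sur = float(rng.uniform(h / 3.0, h / 2.0))
            channel = OrientedChannel(
                wavelength=4.0,
                orientation=float(rng.uniform(0.0, np.pi)),
                sigma=2.0,
                size=min(9, h if h % 2 == 1 else h - 1),
            )
            spec = SurroundUnitSpec(
                center=((h - 1) / 2.0, (w - 1) / 2.0),
                r_exc=r_exc,
                r_sur=r_sur,
                beta=float(rng.uniform(0.5, 1.5)),
                center_channel=channel,
                surround_channel=channel,
            )
            units.append(SurroundSuppressionUnit(spec, name=f"surround_{i}"))
    return units


# ---------------------------------------------------------------------------
# Directory-based reference sets (PNG files + optional groups.csv)
# ---------------------------------------------------------------------------

def save_reference_dir(refset: ReferenceSet, directory: str | Path) -> None:
    """Write a reference set as PNG files plus a ``groups.csv`` manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "groups.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "group"])
        for i, (img, group) in enumerate(zip(refset.images, refset.groups)):
            fname = f"img_{i:05d}.png"
            save_image(img, directory / fname)
            writer.writerow([fname, group])


def load_reference_dir(directory: str | Path) -> ReferenceSet:
    """Load PNG images (and groups.csv, if present) from a directory."""
    directory = Path(directory)
    manifest = directory / "groups.csv"
    if manifest.exists():
        with open(manifest, newline="") as fh:
            rows = list(csv.DictReader(fh))
        images = [load_image(directory / row["filename"]) for row in rows]
        groups = [row["group"] for row in rows]
    else:
        paths = sorted(directory.glob("*.png"))
        if not paths:
            raise FileNotFoundError(f"no PNG images in {directory}")
        images = [load_image(p) for p in paths]
        groups = ["all"] * len(images)
    return ReferenceSet(images=images, groups=groups, seed=-1)
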