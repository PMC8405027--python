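"""Seeded mammogram-like phantoms for desk-scale training and testing.

Each phantom is a square grayscale tile containing one mass over a
smoothed random background that mimics parenchymal texture.  Morphology
follows the clinical rule of thumb that benign masses have regular
borders while malignant masses are irregular and spiculated:

* **benign** — a plain ellipse whose intensity edge is Gaussian-blurred;
* **malignant** — an ellipse whose radius is modulated by a random
  low-order Fourier series plus ``k`` triangular spicules.

The binary ground-truth mask is the exact analytic support of the mass
(spicules included), so segmentation targets are noise-free even though
the image itself is noisy and low-contrast.  Identical spec + label +
seed reproduces identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import LABELS, SampleRecord


class PhantomSpecError(ValueError):
    """Raised when a PhantomSpec field is out of range."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    image_size : pixels per side of the square tile (>= 16).
    mass_radius_range : min/max mass semi-axis as a fraction of image
        size, each in (0, 0.5).
    contrast : mass-over-background intensity offset in (0, 1].
    noise_sigma : std of additive Gaussian pixel noise (intensity units).
    spicule_count_range : min/max number of spicules on malignant masses.
    boundary_roughness : amplitude of the radial Fourier perturbation and
        of the spicule length, as a fraction of the mass radius
        (malignant only).
    background_smoothness : correlation length (pixels) of the low-pass
        filtered background field.
    seed : base random seed for everything derived from this spec.
    """

    image_size: int = 64
    mass_radius_range: tuple[float, float] = (0.12, 0.22)
    contrast: float = 0.35
    noise_sigma: float = 0.03
    spicule_count_range: tuple[int, int] = (4, 8)
    boundary_roughness: float = 0.25
    background_smoothness: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise PhantomSpecError(f"image_size must be >= 16, got {self.image_size}")
        rmin, rmax = self.mass_radius_range
        if not (0 < rmin <= rmax < 0.5):
            raise PhantomSpecError(
                f"mass_radius_range must satisfy 0 < min <= max < 0.5, got {self.mass_radius_range}")
        if not (0 < self.contrast <= 1):
            raise PhantomSpecError(f"contrast must be in (0, 1], got {self.contrast}")
        if self.noise_sigma < 0:
            raise PhantomSpecError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        smin, smax = self.spicule_count_range
        if not (0 <= smin <= smax):
            raise PhantomSpecError(
                f"spicule_count_range must satisfy 0 <= min <= max, got {self.spicule_count_range}")
        if self.boundary_roughness < 0:
            raise PhantomSpecError(
                f"boundary_roughness must be >= 0, got {self.boundary_roughness}")
        if self.background_smoothness <= 0:
            raise PhantomSpecError(
                f"background_smoothness must be > 0, got {self.background_smoothness}")


def _background(rng: np.random.Generator, size: int, smoothness: float) -> np.ndarray:
    """Low-pass filtered white noise, rescaled into a mid-gray band."""
    field = gaussian_filter(rng.standard_normal((size, size)), smoothness)
    lo, hi = field.min(), field.max()
    if hi > lo:
        field = (field - lo) / (hi - lo)
    else:  # pragma: no cover - essentially impossible for real sizes
        field = np.zeros_like(field)
    return 0.15 + 0.3 * field


def _mass_mask(rng: np.random.Generator, spec: PhantomSpec, label: str) -> np.ndarray:
    """Analytic support of one mass; malignant borders are perturbed."""
    size = spec.image_size
    rmin, rmax = spec.mass_radius_range
    a = rng.uniform(rmin, rmax) * size
    b = rng.uniform(rmin, rmax) * size
    theta = rng.uniform(0.0, np.pi)
    # keep the whole perturbed mass inside the tile
    rough = spec.boundary_roughness if label == "malignant" else 0.0
    max_extent = max(a, b) * (1.0 + 2.0 * rough)
    jitter = max(0.0, size / 2.0 - max_extent - 1.0)
    jitter = min(jitter, 0.1 * size)
    cy = size / 2.0 + rng.uniform(-jitter, jitter)
    cx = size / 2.0 + rng.uniform(-jitter, jitter)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame and compute the normalized radius
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)

    if label == "benign":
        return (r <= 1.0).astype(np.uint8)

    phi = np.arctan2(v / b, u / a)
    # random low-order Fourier modulation of the boundary radius
    modes = np.arange(2, 6)
    coef_c = rng.uniform(-1.0, 1.0, size=modes.size)
    coef_s = rng.uniform(-1.0, 1.0, size=modes.size)
    mod = np.zeros_like(phi)
    for m, cc, cs in zip(modes, coef_c, coef_s):
        mod += cc * np.cos(m * phi) + cs * np.sin(m * phi)
    scale = np.sum(np.abs(coef_c)) + np.sum(np.abs(coef_s))
    if scale > 0:
        mod = mod / scale  # bounded in [-1, 1]
    boundary = 1.0 + rough * mod

    # triangular spicules: narrow angular bumps extending the radius
    smin, smax = spec.spicule_count_range
    k = int(rng.integers(smin, smax + 1))
    width = 0.18  # radians, half-width of each spicule
    for center in rng.uniform(-np.pi, np.pi, size=k):
        d = np.angle(np.exp(1j * (phi - center)))
        boundary += rough * np.maximum(0.0, 1.0 - np.abs(d) / width)
    boundary = np.clip(boundary, 1.0 - rough, 1.0 + 2.0 * rough)
    return (r <= boundary).astype(np.uint8)


def generate_phantom(spec: PhantomSpec, label: str) -> SampleRecord:
    """Generate one phantom tile with its exact mask and pathology label."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng([spec.seed, LABELS.index(label)])
    size = spec.image_size
    bg = _background(rng, size, spec.background_smoothness)
    mask = _mass_mask(rng, spec, label)

    edge_sigma = 1.5 if label == "benign" else 0.6
    soft = gaussian_filter(mask.astype(np.float64), edge_sigma)
    img = bg + spec.contrast * soft
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SampleRecord(id=f"phantom_{label}_{spec.seed}", image=img,
                        mask=mask, label=label)


def generate_dataset(spec: PhantomSpec, n_weak: int, n_full: int,
                     benign_fraction: float = 0.5) -> list[SampleRecord]:
    """Generate a weakly-annotated subset followed by a fully-annotated one.

    The first ``n_weak`` records carry a label but no mask (teacher
    pretraining data); the next ``n_full`` carry mask and label (student
    data).  Within each subset the benign count is ``round(fraction * n)``,
    so proportions are within one sample of ``benign_fraction``.  Record
    seeds are spawned deterministically from ``spec.seed``.
    """
    if n_weak < 0 or n_full < 0:
        raise ValueError("n_weak and n_full must be >= 0")
    if not 0.0 <= benign_fraction <= 1.0:
        raise ValueError(f"benign_fraction must be in [0, 1], got {benign_fraction}")

    seed_rng = np.random.default_rng(spec.seed)
    records: list[SampleRecord] = []
    for prefix, n, keep_mask in (("weak", n_weak, False), ("full", n_full, True)):
        n_benign = int(round(benign_fraction * n))
        labels = ["benign"] * n_benign + ["malignant"] * (n - n_benign)
        # deterministic label interleaving so batches stay mixed
        order = np.random.default_rng([spec.seed, n, int(keep_mask)]).permutation(n)
        labels = [labels[i] for i in order]
        for i, label in enumerate(labels):
            sub_seed = int(seed_rng.integers(0, 2**31 - 1))
            rec = generate_phantom(replace(spec, seed=sub_seed), label)
            records.append(replace(
                rec, id=f"{prefix}_{i:04d}",
                mask=rec.mask if keep_mask else None))
    return records
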