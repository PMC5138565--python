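"""Synthetic two-class nodule-like image generator.

Generates labelled (image, mask) pairs that emulate region-of-interest crops
of segmented lung lesions: benign lesions are rendered as smooth, round,
mildly textured blobs, malignant lesions as irregular blobs with rough
internal texture.  Optional bright "calcification" and dark "cavity" disks
are stamped inside the mask.  Shapes are star-convex radial perturbations of
a disk, so boundary roundness, Hu moments and boundary Fourier descriptors
respond monotonically to the irregularity knob — exactly the descriptors the
feature extractor measures.

Every image is deterministic given ``(class_label, seed)``; datasets derive
per-image seeds from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

BENIGN = 0
MALIGNANT = 1

# Fraction of the irregularity / texture_sigma budget each class draws from.
# Benign lesions sit at the low end of both ranges, malignant at the high end.
_CLASS_FRACTION_RANGES = {
    BENIGN: {"irregularity": (0.00, 0.25), "texture": (0.10, 0.35)},
    MALIGNANT: {"irregularity": (0.55, 1.00), "texture": (0.60, 1.00)},
}

_N_HARMONICS = (2, 3, 4, 5)  # low-order sinusoids perturbing the radius


@dataclass(frozen=True)
class NoduleParams:
    """Generator knobs for a single synthetic nodule.

    Parameters
    ----------
    base_radius : float
        Nominal lesion radius in pixels.
    irregularity : float
        Upper bound of the radial-perturbation amplitude, in ``[0, 1)``
        relative to the radius.  Each image draws its actual amplitude from a
        class-dependent sub-range of ``[0, irregularity]``.
    texture_sigma : float
        Upper bound of the interior gray-level noise scale, in ``[0, 1]``.
    calc_prob, cavity_prob : float
        Probability of stamping a small bright (>= 0.9) calcification disk /
        dark (<= 0.1) cavity disk inside the mask.
    image_size : int
        Side length of the square crop; must be >= 4 * base_radius.
    seed : int
        Nonnegative per-image seed.
    """

    base_radius: float = 13.0
    irregularity: float = 0.4
    texture_sigma: float = 0.22
    calc_prob: float = 0.30
    cavity_prob: float = 0.20
    image_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 4 * self.base_radius:
            raise ValueError(
                f"image_size={self.image_size} must be >= 4 * base_radius "
                f"({4 * self.base_radius:g}) so the lesion fits with margin"
            )
        if not (0.0 <= self.irregularity < 1.0):
            raise ValueError(f"irregularity={self.irregularity} must be in [0, 1)")
        for name in ("texture_sigma", "calc_prob", "cavity_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.seed < 0:
            raise ValueError(f"seed={self.seed} must be nonnegative")


@dataclass(frozen=True)
class NoduleImage:
    """A grayscale lesion crop with its segmentation mask and label.

    ``pixels`` are floats in [0, 1]; ``mask`` is a boolean grid of the same
    shape with a single nonempty connected component; ``label`` is 0 (benign)
    or 1 (malignant).
    """

    pixels: np.ndarray
    mask: np.ndarray
    label: int
    id: str

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must have identical shapes")
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"label must be 0 (benign) or 1 (malignant), got {self.label}")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground pixel")


def _single_component(mask: np.ndarray) -> bool:
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return n == 1


def generate_nodule(class_label: int, params: NoduleParams) -> NoduleImage:
    """Render one synthetic nodule of the requested class.

    The boundary is the star-convex radial function
    ``r(theta) = base_radius * (1 + a * sum_h w_h cos(h*theta + phi_h))``
    with seeded random weights/phases and a class-dependent amplitude
    ``a <= irregularity``; the interior is filled with smoothed seeded noise.
    Deterministic given ``(class_label, params.seed)``.
    """
    if class_label not in (BENIGN, MALIGNANT):
        raise ValueError(f"class_label must be 0 (benign) or 1 (malignant), got {class_label}")
    rng = np.random.default_rng(np.random.SeedSequence([int(class_label), int(params.seed)]))

    frac = _CLASS_FRACTION_RANGES[class_label]
    irr = params.irregularity * rng.uniform(*frac["irregularity"])
    tex = params.texture_sigma * rng.uniform(*frac["texture"])

    size = params.image_size
    center = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dr, dc = rows - center, cols - center
    theta = np.arctan2(dr, dc)
    rad = np.hypot(dr, dc)

    # Radial perturbation: weights normalized so the total amplitude is irr,
    # keeping the boundary star-convex (irr < 1 => radius stays positive).
    weights = rng.uniform(0.5, 1.0, size=len(_N_HARMONICS))
    weights *= irr / weights.sum() if weights.sum() > 0 else 0.0
    phases = rng.uniform(0.0, 2 * np.pi, size=len(_N_HARMONICS))
    perturb = np.zeros_like(theta)
    for h, w, ph in zip(_N_HARMONICS, weights, phases):
        perturb += w * np.cos(h * theta + ph)
    boundary_r = params.base_radius * (1.0 + perturb)
    mask = rad <= boundary_r

    # Interior: base intensity plus band-limited noise; background stays dark.
    base = rng.uniform(0.50, 0.62)
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=1.0)
    std = smooth.std()
    if std > 0:
        smooth = smooth / std
    pixels = np.full((size, size), 0.10) + 0.02 * ndimage.gaussian_filter(
        rng.standard_normal((size, size)), sigma=2.0
    )
    pixels[mask] = base + tex * smooth[mask]

    # Optional stamped signs: bright calcification spot, dark cavity.
    inner_r = max(1.0, 0.45 * params.base_radius)
    if rng.random() < params.calc_prob:
        pixels = _stamp_disk(pixels, rng, center, inner_r, params.base_radius, value=0.95)
    if rng.random() < params.cavity_prob:
        pixels = _stamp_disk(pixels, rng, center, inner_r, params.base_radius, value=0.05)

    pixels = np.clip(pixels, 0.0, 1.0)
    tag = "b" if class_label == BENIGN else "m"
    return NoduleImage(pixels=pixels, mask=mask, label=class_label, id=f"{tag}{params.seed}")


def _stamp_disk(
    pixels: np.ndarray,
    rng: np.random.Generator,
    center: float,
    offset_r: float,
    base_radius: float,
    value: float,
) -> np.ndarray:
    """Stamp a small constant disk at a seeded spot near the lesion centre."""
    ang = rng.uniform(0.0, 2 * np.pi)
    off = rng.uniform(0.0, offset_r)
    cy, cx = center + off * np.sin(ang), center + off * np.cos(ang)
    radius = rng.uniform(1.2, max(1.3, 0.22 * base_radius))
    size = pixels.shape[0]
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    spot = np.hypot(rows - cy, cols - cx) <= radius
    out = pixels.copy()
    out[spot] = value
    return out


def generate_dataset(
    n_benign: int,
    n_malignant: int,
    master_seed: int,
    params: NoduleParams | None = None,
) -> list[NoduleImage]:
    """Generate a labelled dataset with per-image seeds spawned from one master seed.

    Returns ``n_benign`` benign images followed by ``n_malignant`` malignant
    ones, with unique ids ``benign-###`` / ``malig-###``.  Two calls with
    equal arguments produce identical datasets.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be nonnegative")
    params = params or NoduleParams()
    total = n_benign + n_malignant
    if total == 0:
        return []
    children = np.random.SeedSequence(master_seed).spawn(total)
    images: list[NoduleImage] = []
    for i, child in enumerate(children):
        label = BENIGN if i < n_benign else MALIGNANT
        seed = int(child.generate_state(1)[0])
        img = generate_nodule(label, replace(params, seed=seed))
        tag = "benign" if label == BENIGN else "malig"
        idx = i if label == BENIGN else i - n_benign
        images.append(replace(img, id=f"{tag}-{idx:03d}"))
    return images
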