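"""104-dimensional handcrafted feature vector for segmented lesion crops.

The descriptor concatenates, in fixed order:

==========  =====  =====================================================
slots       count  content
==========  =====  =====================================================
f1-f3         3    gray: mean, variance, entropy (bits) over mask pixels
f4-f10        7    Hu invariant moments of the binary mask
f11-f15       5    geometry: perimeter, area, max diameter,
                   rectangularity, roundness 4*pi*A/L^2
f16-f19       4    medical signs: calcification area/degree,
                   cavity area/ratio (thresholded intensities)
f20           1    boundary Fourier descriptor (harmonics 2-8 energy)
f21-f104     84    GLCM texture: 14 Haralick statistics x 4 angles
                   (angle-major) + per-statistic mean and variance
==========  =====  =====================================================

All gray statistics and co-occurrence pairs are restricted to pixels inside
the mask: the lesion, not the crop window, is the object described.
Entropies use log base 2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPoint
from skimage import measure

from .synthetic import NoduleImage

GLCM_ANGLES = (0, 45, 90, 135)

#: Row/col offsets for the standard GLCM directions (row-major, origin
#: top-left): 0 deg = (0,+d), 45 = (-d,+d), 90 = (-d,0), 135 = (-d,-d).
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "mcc",
)


@dataclass(frozen=True)
class SignThresholds:
    """Intensity cutoffs for the medical-sign counts, on [0, 1] gray values.

    A mask pixel brighter than ``tau_cal`` counts as calcified; darker than
    ``tau_cav`` as cavitary.
    """

    tau_cal: float = 0.85
    tau_cav: float = 0.15

    def __post_init__(self) -> None:
        if not self.tau_cav < self.tau_cal:
            raise ValueError(
                f"tau_cav={self.tau_cav} must be strictly below tau_cal={self.tau_cal}"
            )


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction parameters: gray quantization, GLCM offset, sign cutoffs."""

    k_levels: int = 16
    distance: int = 1
    thresholds: SignThresholds = field(default_factory=SignThresholds)


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix at one offset."""

    G: np.ndarray
    angle: int
    distance: int

    def __post_init__(self) -> None:
        G = self.G
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("G must be square")
        if (G < 0).any() or not np.isclose(G.sum(), 1.0, atol=1e-8):
            raise ValueError("G entries must be nonnegative and sum to 1")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 104-component descriptor with fixed names f1..f104."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (104,):
            raise ValueError(f"feature vector must have length 104, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector must be finite")

    @property
    def names(self) -> list[str]:
        return feature_names()


def feature_names() -> list[str]:
    return [f"f{i}" for i in range(1, 105)]


# ---------------------------------------------------------------------------
# gray features (f1-f3)


def gray_features(img: NoduleImage, k_levels: int = 16) -> tuple[float, float, float]:
    """Mean, variance and histogram entropy (bits) of the mask pixels.

    The entropy is H = -sum_i p_i log2 p_i over a ``k_levels``-bin histogram
    of the [0, 1] intensity range, with 0*log(0) = 0.
    """
    if k_levels < 2:
        raise ValueError("k_levels must be >= 2")
    vals = img.pixels[img.mask]
    if vals.size == 0:
        raise ValueError("mask is empty")
    hist, _ = np.histogram(vals, bins=k_levels, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return float(vals.mean()), float(vals.var()), entropy


# ---------------------------------------------------------------------------
# morphology (f4-f20)


def hu_moments(mask: np.ndarray) -> np.ndarray:
    """The seven Hu invariant moments of the binary mask (f4-f10)."""
    if not np.asarray(mask).any():
        raise ValueError("mask is empty")
    m = measure.moments_central(mask.astype(float))
    return measure.moments_hu(measure.moments_normalized(m))


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed 8-connected boundary of a single-component mask.

    Moore-neighbour tracing with Jacob's stopping criterion; returns an
    (n, 2) array of (row, col) pixel coordinates, first pixel not repeated
    at the end.  The chain visits every boundary pixel in order, stepping to
    4- or 8-neighbours only.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    if rows.size == 0:
        raise ValueError("mask is empty")
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    if rows.size == 1:
        return np.array([[start[0] - 1, start[1] - 1]])

    # Clockwise Moore neighbourhood starting north.
    neigh = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    contour = [start]
    backtrack = (start[0], start[1] - 1)  # west of start is background by scan order
    cur = start
    first_next: tuple[int, int] | None = None
    max_steps = 4 * int(padded.sum()) + 8  # the trace visits each pixel at most 4x
    for _ in range(max_steps):
        off = (backtrack[0] - cur[0], backtrack[1] - cur[1])
        k0 = neigh.index(off)
        nxt = None
        for step in range(1, 9):
            cand_off = neigh[(k0 + step) % 8]
            cand = (cur[0] + cand_off[0], cur[1] + cand_off[1])
            if padded[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel (cannot happen: size==1 handled above)
            break
        if cur == start:
            if first_next is None:
                first_next = nxt
            elif nxt == first_next and len(contour) > 1:
                break  # re-entered the start with the same exit: loop closed
        cur = nxt
        if cur == start:
            # candidate stop; confirmed on the next iteration via first_next
            if first_next is None:
                break
            continue
        contour.append(cur)
    return np.asarray(contour) - 1  # undo padding


def _chain_length(contour: np.ndarray) -> float:
    """Closed-chain perimeter: unit steps weighted 1, diagonal steps sqrt(2)."""
    if len(contour) < 2:
        return 4.0  # single pixel: its square outline
    closed = np.vstack([contour, contour[:1]])
    steps = np.diff(closed, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def geometric_features(mask: np.ndarray) -> tuple[float, float, float, float, float]:
    """Perimeter, area, max diameter, rectangularity, roundness (f11-f15).

    Area is the foreground pixel count; perimeter is the traced boundary
    chain length (diagonal steps weighted sqrt(2)); roundness is
    F = 4*pi*A/L^2 (1 for a perfect circle); rectangularity is area over the
    minimal rotated bounding rectangle of the boundary pixels' corners.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    from scipy import ndimage

    _, ncomp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if ncomp != 1:
        raise ValueError(f"mask must have exactly one connected component, found {ncomp}")

    area = float(mask.sum())
    contour = trace_boundary(mask)
    perimeter = _chain_length(contour)
    if len(contour) >= 2:
        max_diameter = float(pdist(contour.astype(float)).max())
    else:
        max_diameter = 0.0

    # Pixel corners so a filled axis-aligned square scores exactly 1.
    corners = np.concatenate(
        [contour + np.array(d) for d in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    rect = MultiPoint([tuple(p) for p in corners]).minimum_rotated_rectangle
    rect_area = rect.area if rect.area > 0 else area
    rectangularity = float(area / rect_area)

    roundness = float(4.0 * np.pi * area / perimeter**2)
    return perimeter, area, max_diameter, rectangularity, roundness


def medical_signs(
    img: NoduleImage, th: SignThresholds | None = None
) -> tuple[float, float, float, float]:
    """Calcification area/degree and cavity area/ratio (f16-f19).

    Counts mask pixels brighter than ``tau_cal`` (calcified) and darker than
    ``tau_cav`` (cavitary); degrees are those counts over the mask area.
    """
    th = th or SignThresholds()
    vals = img.pixels[img.mask]
    if vals.size == 0:
        raise ValueError("mask is empty")
    calc_area = float((vals > th.tau_cal).sum())
    cavity_area = float((vals < th.tau_cav).sum())
    n = float(vals.size)
    return calc_area, calc_area / n, cavity_area, cavity_area / n


def fourier_descriptor(mask: np.ndarray) -> float:
    """Scalar boundary irregularity from the Fourier series of the contour (f20).

    The closed boundary is traced as a complex sequence z = col + i*row and
    discrete-Fourier-transformed; coefficient magnitudes are normalized by the
    first harmonic (which carries a circle's entire shape energy).  The
    descriptor is the energy in harmonics 2..8 (both signs) relative to
    harmonic 1 — translation, scale, rotation and start-point invariant, near
    0 for a disk and growing with boundary irregularity.
    """
    contour = trace_boundary(np.asarray(mask, dtype=bool))
    if len(contour) < 8:
        raise ValueError(f"boundary too short for a Fourier descriptor ({len(contour)} < 8 pixels)")
    z = contour[:, 1].astype(float) + 1j * contour[:, 0].astype(float)
    Z = np.fft.fft(z) / len(z)
    mag2 = np.abs(Z) ** 2
    first = mag2[1] + mag2[-1]
    if first <= 0:
        raise ValueError("degenerate boundary: no first-harmonic energy")
    n = len(z)
    num = sum(
        mag2[k] + (mag2[n - k] if n - k != k else 0.0) for k in range(2, 9) if k < n - 1
    )
    return float(num / first)


# ---------------------------------------------------------------------------
# texture (f21-f104)


def quantize(pixels: np.ndarray, k_levels: int) -> np.ndarray:
    """Equal-width quantization of [0, 1] gray values to integer levels."""
    return np.clip((pixels * k_levels).astype(int), 0, k_levels - 1)


def compute_glcm(
    img: NoduleImage, k_levels: int = 16, angle: int = 0, distance: int = 1
) -> GLCMatrix:
    """Symmetric normalized co-occurrence matrix over mask-interior pixel pairs.

    Ordered pairs (p, p + offset) with both endpoints inside the mask are
    counted, the count matrix is symmetrized (transpose added) and normalized
    to sum 1.
    """
    if k_levels < 2:
        raise ValueError("k_levels must be >= 2")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}, got {angle}")
    dr, dc = (d * distance for d in _ANGLE_OFFSETS[angle])
    q = quantize(img.pixels, k_levels)
    mask = img.mask

    h, w = mask.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    src_ok = mask[r0, c0] & mask[r1, c1]
    if not src_ok.any():
        raise ValueError("no valid mask-interior pixel pair for this offset")
    i = q[r0, c0][src_ok]
    j = q[r1, c1][src_ok]
    counts = np.zeros((k_levels, k_levels))
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    return GLCMatrix(G=counts / counts.sum(), angle=angle, distance=distance)


def glcm_features(G: GLCMatrix | np.ndarray) -> np.ndarray:
    """The 14 Haralick statistics of a normalized GLCM, in HARALICK_NAMES order.

    Includes the four classical measures — contrast, angular second moment,
    entropy (bits) and inverse difference moment — plus correlation, variance,
    sum/difference statistics, the two information measures of correlation and
    the maximal correlation coefficient (square root of the second-largest
    eigenvalue of the standard Q matrix).
    """
    P = G.G if isinstance(G, GLCMatrix) else np.asarray(G, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("G must be square")
    if (P < 0).any() or not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("G must be normalized (nonnegative, summing to 1)")
    k = P.shape[0]
    idx = np.arange(k)
    I, J = np.meshgrid(idx, idx, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    asm = float((P**2).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float((((I - mu_x) * (J - mu_y) * P).sum()) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((I - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())
    entropy = float(_nent(P))

    # sum (i+j) and difference |i-j| marginals
    psum = np.zeros(2 * k - 1)
    np.add.at(psum, (I + J).ravel(), P.ravel())
    pdiff = np.zeros(k)
    np.add.at(pdiff, np.abs(I - J).ravel(), P.ravel())
    s_idx = np.arange(2 * k - 1)
    d_idx = np.arange(k)
    sum_average = float((s_idx * psum).sum())
    sum_variance = float(((s_idx - sum_average) ** 2 * psum).sum())
    sum_entropy = float(_nent(psum))
    diff_mean = float((d_idx * pdiff).sum())
    difference_variance = float(((d_idx - diff_mean) ** 2 * pdiff).sum())
    difference_entropy = float(_nent(pdiff))

    hx, hy = float(_nent(px)), float(_nent(py))
    outer = np.outer(px, py)
    pos = outer > 0
    hxy1 = float(-(P[pos] * np.log2(outer[pos])).sum())
    hxy2 = float(-(outer[pos] * np.log2(outer[pos])).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    # Maximal correlation coefficient: sqrt of the 2nd-largest eigenvalue of
    # Q_ij = sum_k P_ik P_jk / (px_i py_k), on rows/cols with mass.
    live = px > 0
    livec = py > 0
    if live.sum() >= 2 and livec.sum() >= 2:
        Pl = P[np.ix_(live, livec)]
        Q = (Pl / px[live, None]) @ (Pl / py[livec][None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, ev[-2])))
    else:
        mcc = 0.0

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
            mcc,
        ]
    )


def _nent(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log(0)=0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def texture_block(img: NoduleImage, k_levels: int = 16, distance: int = 1) -> np.ndarray:
    """84 texture components: 14 Haralick statistics at 4 angles, plus the
    per-statistic mean and (population) variance across angles (f21-f104).

    Layout is angle-major: 14 values at 0 deg, then 45, 90, 135, then 14
    means, then 14 variances.
    """
    per_angle = np.array(
        [glcm_features(compute_glcm(img, k_levels, angle, distance)) for angle in GLCM_ANGLES]
    )
    return np.concatenate([per_angle.ravel(), per_angle.mean(axis=0), per_angle.var(axis=0)])


# ---------------------------------------------------------------------------
# assembly and standardization


def assemble_feature_vector(img: NoduleImage, config: FeatureConfig | None = None) -> FeatureVector:
    """Concatenate gray, morphology and texture blocks into the 104-vector."""
    config = config or FeatureConfig()
    gray = gray_features(img, config.k_levels)
    hu = hu_moments(img.mask)
    geom = geometric_features(img.mask)
    signs = medical_signs(img, config.thresholds)
    fd = fourier_descriptor(img.mask)
    tex = texture_block(img, config.k_levels, config.distance)
    values = np.concatenate([gray, hu, geom, signs, [fd], tex])
    return FeatureVector(values=values)


def extract_feature_matrix(
    images: list[NoduleImage], config: FeatureConfig | None = None
) -> np.ndarray:
    """Stack per-image feature vectors into an (n, 104) matrix."""
    return np.array([assemble_feature_vector(img, config).values for img in images])


@dataclass(frozen=True)
class Standardizer:
    """Per-component z-scoring fitted on training features.

    Zero-variance components keep scale 1 so constant features pass through
    centred but unscaled.
    """

    mean: np.ndarray
    scale: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def invert(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.mean


def fit_standardizer(X: np.ndarray) -> Standardizer:
    """Fit per-component mean/scale on a training matrix (n >= 2 rows)."""
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors to fit a standardizer")
    sc = StandardScaler().fit(X)
    return Standardizer(mean=sc.mean_.copy(), scale=sc.scale_.copy())
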