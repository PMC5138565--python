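"""Kernelized supervised hashing (KSH) of feature vectors into short binary codes.

Each of the r hash functions is a sign-thresholded Gaussian-kernel expansion
over m anchor samples,

    h_k(x) = sgn( sum_j kappa(x_(j), x) A[j,k] - b_k ),
    kappa(x, y) = exp(-||x - y||^2 / (2 sigma^2)),

with the bias b_k chosen so every f_k has exact mean zero over the training
set (equivalently: the kernel rows are centred by the training kernel mean).
Training minimizes the Frobenius error between the l x l code inner-product
matrix of l labelled samples and r*S, where S is the +/-1 same-class /
different-class label matrix:

    Q(A) = || sum_k sgn(Kbar a_k) sgn(Kbar a_k)^T  -  r S ||_F^2 .

The optimizer is the standard greedy KSH recipe: bits are learned one at a
time against the residual target R (initially r*S, reduced by each realized
bit's outer product); each bit is initialized by spectral relaxation and
refined by gradient ascent on a sigmoid-smoothed surrogate of the sign.

Codes are stored packed (one bit per entry, +1 <-> 1), and the code inner
product is recovered as r - 2 * popcount(xor) — the standard inner-product /
Hamming-distance correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

_MAX_GRAD_ITERS = 500
_REL_TOL = 1e-6


@dataclass(frozen=True)
class LabelMatrix:
    """l x l pairwise supervision: +1 same class, -1 different class."""

    S: np.ndarray
    sample_ids: np.ndarray  # indices of the l selected training rows


@dataclass(frozen=True)
class HashModel:
    """Trained hash functions: anchors, coefficients, bandwidth and biases."""

    anchors: np.ndarray  # (m_anchor, d) standardized feature vectors
    A: np.ndarray  # (m_anchor, r) coefficient columns a_1..a_r
    sigma: float  # Gaussian kernel bandwidth
    bias: np.ndarray  # (r,) per-function bias (training kernel mean @ A)
    r: int  # code length in bits
    kernel_mean: np.ndarray = field(default=None)  # (m_anchor,) training mean kernel row

    def __post_init__(self) -> None:
        if self.A.shape != (self.anchors.shape[0], self.r):
            raise ValueError("A must be (m_anchor, r)")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A must be finite")


@dataclass(frozen=True)
class TrainingDiagnostics:
    """Bookkeeping from the greedy optimization, for objective cross-checks."""

    objective_trace: np.ndarray  # Q after 0..r bits (trace[0] = ||rS||_F^2)
    label_matrix: LabelMatrix
    anchor_ids: np.ndarray


def kernel_row(x: np.ndarray, anchors: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel map of one vector against the anchor set."""
    return kernel_matrix(np.atleast_2d(x), anchors, sigma)[0]


def kernel_matrix(X: np.ndarray, anchors: np.ndarray, sigma: float) -> np.ndarray:
    """Rows of kappa(x_i, anchor_j) = exp(-||x_i - anchor_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    sq = cdist(np.asarray(X, dtype=float), np.asarray(anchors, dtype=float), "sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


def build_label_matrix(labels: np.ndarray, sample_ids: np.ndarray | None = None) -> LabelMatrix:
    """Pairwise +/-1 supervision matrix from per-image class labels."""
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 labels")
    S = np.where(labels[:, None] == labels[None, :], 1.0, -1.0)
    if sample_ids is None:
        sample_ids = np.arange(labels.size)
    return LabelMatrix(S=S, sample_ids=np.asarray(sample_ids))


def compute_bias(a: np.ndarray, training_kernel_rows: np.ndarray) -> float:
    """Bias b = (1/n) sum_i sum_j kappa(x_(j), x_i) a_j.

    Centres f(x) = kappa(x) . a - b to exact mean zero over the training set.
    """
    return float(np.asarray(training_kernel_rows).mean(axis=0) @ np.asarray(a))


def _sgn(v: np.ndarray) -> np.ndarray:
    """Sign with sgn(0) = +1."""
    return np.where(np.asarray(v) >= 0, 1.0, -1.0)


def _refine_bit(Kbar: np.ndarray, R: np.ndarray, a0: np.ndarray) -> np.ndarray:
    """Gradient ascent on the sigmoid-smoothed bit objective phi(Ka)^T R phi(Ka).

    phi(x) = tanh(x/2) is the shifted logistic; the discrete objective
    sgn(Ka)^T R sgn(Ka) is tracked and the best-seen coefficient vector
    returned.
    """

    def smooth(a: np.ndarray) -> float:
        ph = np.tanh(0.5 * (Kbar @ a))
        return float(ph @ (R @ ph))

    def discrete(a: np.ndarray) -> float:
        h = _sgn(Kbar @ a)
        return float(h @ (R @ h))

    a = a0.copy()
    best_a, best_val = a.copy(), discrete(a)
    prev = smooth(a)
    step = 1.0
    for _ in range(_MAX_GRAD_ITERS):
        u = Kbar @ a
        ph = np.tanh(0.5 * u)
        grad = Kbar.T @ ((R @ ph) * 0.5 * (1.0 - ph**2)) * 2.0
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-12:
            break
        # backtracking line search on the ascent direction
        old = prev
        improved = False
        for _ in range(20):
            cand = a + step * grad / gnorm
            val = smooth(cand)
            if val > old:
                a, prev = cand, val
                step *= 1.5
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        d = discrete(a)
        if d > best_val:
            best_val, best_a = d, a.copy()
        if abs(prev - old) <= _REL_TOL * max(1.0, abs(old)):
            break
    return best_a


def train_ksh(
    X_train: np.ndarray,
    labels: np.ndarray,
    r: int = 48,
    m_anchor: int = 300,
    l: int | None = None,
    sigma: float | None = None,
    seed: int = 0,
) -> tuple[HashModel, TrainingDiagnostics]:
    """Learn r supervised hash functions from standardized training features.

    ``m_anchor`` anchors and ``l`` label-matrix samples are seeded uniform
    draws without replacement (``m_anchor < l <= n``).  Returns the trained
    model together with diagnostics carrying the per-bit objective trace
    Q(A restricted to the first k bits), which is checkable against a direct
    evaluation of the Frobenius objective.
    """
    X = np.asarray(X_train, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if r < 1:
        raise ValueError("r must be >= 1")
    if l is None:
        l = min(1000, n)
    if l > n:
        raise ValueError(f"l={l} exceeds the training size n={n}")
    if m_anchor >= l:
        raise ValueError(f"m_anchor={m_anchor} must be < l={l}")

    rng = np.random.default_rng(seed)
    anchor_ids = np.sort(rng.choice(n, m_anchor, replace=False))
    label_ids = np.sort(rng.choice(n, l, replace=False))
    anchors = X[anchor_ids]

    if sigma is None:
        sub = X[rng.choice(n, min(n, 200), replace=False)]
        d = cdist(sub, anchors).ravel()
        d = d[d > 0]
        sigma = float(np.median(d)) if d.size else 1.0

    K_full = kernel_matrix(X, anchors, sigma)  # (n, m)
    kernel_mean = K_full.mean(axis=0)
    Kbar = K_full[label_ids] - kernel_mean  # centred (l, m): bias folded in

    lm = build_label_matrix(labels[label_ids], sample_ids=label_ids)
    R = float(r) * lm.S
    KtK = Kbar.T @ Kbar + 1e-8 * np.eye(m_anchor)

    A = np.zeros((m_anchor, r))
    trace = [float(np.sum(R**2))]
    for k in range(r):
        M = Kbar.T @ R @ Kbar
        M = (M + M.T) / 2.0
        _, vec = eigh(M, KtK, subset_by_index=(m_anchor - 1, m_anchor - 1))
        a0 = vec[:, 0]
        Ka = Kbar @ a0
        nrm = np.linalg.norm(Ka)
        if nrm > 0:
            a0 = a0 * (np.sqrt(l) / nrm)  # scale into the sigmoid's active range
        a = _refine_bit(Kbar, R, a0)
        # a bit and its negation realize the same outer product; keep as-is
        h = _sgn(Kbar @ a)
        A[:, k] = a
        R = R - np.outer(h, h)
        trace.append(float(np.sum(R**2)))

    bias = kernel_mean @ A
    model = HashModel(
        anchors=anchors, A=A, sigma=float(sigma), bias=bias, r=r, kernel_mean=kernel_mean
    )
    diag = TrainingDiagnostics(
        objective_trace=np.array(trace), label_matrix=lm, anchor_ids=anchor_ids
    )
    return model, diag


def ksh_objective(model: HashModel, X_train: np.ndarray, lm: LabelMatrix) -> float:
    """Direct Frobenius-norm evaluation of the KSH objective on a trained model:
    || H H^T - r S ||_F^2 with H the l x r matrix of realized bits."""
    H = encode_signs(np.asarray(X_train)[lm.sample_ids], model)
    return float(np.sum((H @ H.T - model.r * lm.S) ** 2))


def encode_signs(X: np.ndarray, model: HashModel) -> np.ndarray:
    """Encode standardized vectors to an (n, r) matrix of +/-1 bits."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.anchors.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model "
            f"({model.anchors.shape[1]})"
        )
    K = kernel_matrix(X, model.anchors, model.sigma)
    return _sgn(K @ model.A - model.bias)


def encode(X: np.ndarray, model: HashModel) -> np.ndarray:
    """Encode standardized vectors to packed codes (uint8, one bit per entry)."""
    return pack_codes(encode_signs(X, model))


def pack_codes(bits: np.ndarray) -> np.ndarray:
    """Pack an (n, r) +/-1 bit matrix into (n, ceil(r/8)) uint8, +1 <-> 1."""
    bits = np.atleast_2d(bits)
    return np.packbits(bits > 0, axis=1)


def unpack_codes(packed: np.ndarray, r: int) -> np.ndarray:
    """Exact inverse of pack_codes for codes of length r."""
    packed = np.atleast_2d(packed)
    bits = np.unpackbits(packed, axis=1, count=r)
    return bits.astype(np.int8) * 2 - 1


def code_inner_products(packed_q: np.ndarray, packed_db: np.ndarray, r: int) -> np.ndarray:
    """Inner products of one packed query code against packed database codes.

    Computed as r - 2 * popcount(q XOR x); equals the +/-1 dot product.
    """
    packed_db = np.atleast_2d(packed_db)
    if packed_q.shape[-1] != packed_db.shape[-1]:
        raise ValueError("code lengths do not match")
    x = np.bitwise_xor(packed_db, packed_q[None, :] if packed_q.ndim == 1 else packed_q)
    return r - 2 * np.bitwise_count(x).sum(axis=1).astype(int)
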