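# Methods

This note records the modelling choices behind `nodulehash`: what each stage
computes, the parameters that matter, what the synthetic generator does and
does not emulate, and the numerical conventions adopted where the design was
genuinely open.

## Feature extraction

The descriptor is a fixed-order 104-vector; all intensity statistics and
co-occurrence pairs are restricted to pixels inside the lesion mask, on the
view that the lesion — not the crop window — is the object of interest.

**Gray (f1–f3).** Mean, variance and histogram entropy of the mask pixels.
Entropy uses a `k_levels`-bin histogram of the [0, 1] range (default 16
bins) and log base 2, with 0·log 0 = 0. Base 2 is a convention; any fixed
base only rescales the feature and is absorbed by standardization.

**Hu moments (f4–f10).** The standard seven invariants of the binary mask,
computed from normalized central moments (via scikit-image). Rotation by
90° and translation are exact invariances up to float error; scale
invariance is approximate on digital masks (within ~1e-2 on 4× upsampling).

**Geometry (f11–f15).** Area is the foreground pixel count. The perimeter
is the length of the Moore-traced 8-connected boundary chain with diagonal
steps weighted √2 — a definition that keeps the roundness F = 4πA/L² of a
large digital disk near 1 (measured ≈ 0.92 at radius 32; the chain
overestimates a smooth contour's length by a few percent, which is why the
disk check accepts [0.9, 1.1]). Maximum diameter is the largest pairwise
distance between boundary pixel centres. Rectangularity divides the area by
the minimal rotated bounding rectangle of the boundary pixels' *corners*
(shapely), so an axis-aligned filled square scores exactly 1 and no digital
shape exceeds 1.

**Medical signs (f16–f19).** Counts of mask pixels above a calcification
threshold and below a cavity threshold, plus their fractions of the mask
area. Defaults `tau_cal = 0.85`, `tau_cav = 0.15` on normalized intensity:
far enough from typical soft-tissue interior values (~0.5) that only
deliberately bright/dark structures trigger them; both are configurable.

**Fourier descriptor (f20).** The closed boundary, traced in order, is read
as a complex sequence and DFT'd; the descriptor is the energy in harmonics
2–8 (both signs) relative to harmonic 1. Harmonic 1 carries a circle's
entire shape energy, so a disk scores ≈ 0 and the value grows with boundary
irregularity; magnitude normalization makes it translation-, scale-,
rotation- and start-point-invariant. The 2–8 band was chosen to cover the
low-order lobing that distinguishes smooth from lobulated lesions while
staying insensitive to pixel-level boundary noise.

**Texture (f21–f104).** Gray values are quantized to 16 equal-width levels
(standard Haralick practice; the count is configurable) and co-occurrence
matrices are accumulated at distance 1 for the four standard offsets
0° = (0,+d), 45° = (−d,+d), 90° = (−d,0), 135° = (−d,−d), counting ordered
pairs whose *both* endpoints lie in the mask, symmetrized and normalized.
From each matrix the canonical 14 Haralick statistics are computed (ASM,
contrast, correlation, variance, inverse difference moment, sum average/
variance/entropy, entropy, difference variance/entropy, the two information
measures of correlation, and the maximal correlation coefficient as the
square root of the second-largest eigenvalue of the standard Q matrix).
Entropies are log-2. The inverse difference moment is the standard positive
homogeneity measure Σ G_ij/(1+(i−j)²). The block stores the 4×14 values
angle-major, then per-statistic means and population variances across
angles (isotropy summaries).

Degenerate inputs: a constant image yields a single-entry GLCM (ASM = 1,
entropies 0); rows/columns without mass are dropped before the eigenvalue
step of the maximal correlation coefficient, which is defined as 0 when
fewer than two live levels remain; correlation is 0 when either marginal is
degenerate.

**Standardization.** Features are z-scored with training-set statistics;
zero-variance components keep scale 1 (centred, not divided). Queries are
always standardized with the *training* standardizer, never re-fitted.

## Spectral partition

Similarity W_ij = exp(−‖x_i−x_j‖²/2δ²) with δ defaulting to the median
pairwise distance of a seeded subsample of at most 200 training points — a
scale-free bandwidth that adapts to the feature mix. The symmetric
normalized Laplacian is densely eigendecomposed (databases here are at most
thousands of images), the bottom-k eigenvector rows are normalized to unit
length (Ng–Jordan–Weiss), and seeded k-means with 10 restarts clusters
them; an empty cluster triggers a re-seeded retry (at most 5). Cluster
centers are recomputed as per-cluster means in the original standardized
feature space, because queries are compared to centers on their features,
which are never embedded. Default k = 35, clipped to n for small sets.

## Supervised hashing

Kernel: Gaussian with the squared norm in the exponent; σ defaults to the
median distance between a seeded subsample and the anchors. Anchors
(default 300, clipped below the label-sample count) and the l label samples
(default min(1000, n)) are seeded uniform draws without replacement.

Training minimizes Q(A) = ‖Σ_k sgn(K̄a_k) sgn(K̄a_k)ᵀ − rS‖²_F over the
centred kernel matrix K̄ of the label samples (centring folds the bias into
the expansion: each hash output has exact mean zero over the n training
vectors). Bits are learned greedily against the residual target (rS minus
the accumulated outer products of realized bits): each bit is initialized
by the top generalized eigenvector of K̄ᵀRK̄ against K̄ᵀK̄ (ridge 1e-8),
scaled so the activations sit in the sigmoid's active range, then refined
by backtracking gradient ascent on the smoothed surrogate
φ(K̄a)ᵀRφ(K̄a), φ(x) = tanh(x/2), for at most 500 iterations or until
the relative change drops below 1e-6; the best coefficient vector under the
*discrete* objective seen during refinement is kept. sgn(0) = +1
everywhere.

The per-bit objective trace (Frobenius norm of the residual after each bit)
is stored and is checkable against a direct evaluation of Q(A) on the
returned model; the greedy construction makes the trace non-increasing in
practice because each accepted bit captures at least half the residual's
diagonal energy on separable data.

Codes persist packed, one bit per code position (+1 ↔ 1), and inner
products are computed as r − 2·popcount(xor), which is exactly the ±1 dot
product for any code length 1–64 (verified bit-for-bit in the tests).

## Retrieval and classification

Pruning ranks clusters by squared distance ‖q−μ_i‖² (squared vs unsquared
is order-equivalent; squared is used throughout) and keeps the m nearest
(default 8), ties to the lower cluster index. Candidate records are ranked
by code inner product descending; records with equal inner product are
ordered by their cluster's distance to the query (closer cluster first) —
the cached distances from the pruning step are reused — and remaining ties
fall back to ascending record id so the order is total and the exhaustive-
search equivalence test can demand exact equality. If the candidate pool is
smaller than p the whole pool is returned with a logged warning.

The class prediction is a majority vote over the p returned labels; an
exact tie predicts malignant — the safety-first reading of a two-branch
rule whose "otherwise" covers the tie. Evaluation averages per-query
precision@p over all queries and reports overall plus per-class vote
accuracy; an empty class stratum is reported as not applicable (`None`)
rather than 0.

## Synthetic data

The generator emulates segmented region-of-interest crops of lung lesions
as star-convex radial perturbations of a disk: r(θ) = R(1 + Σ_h w_h
cos(hθ+φ_h)) with harmonics 2–5, seeded phases, and a total amplitude drawn
per image from a class-dependent fraction of the `irregularity` budget
(benign 0–25%, malignant 55–100% of it). Interior texture is smoothed
Gaussian noise whose amplitude is likewise drawn low for benign (10–35% of
`texture_sigma`) and high for malignant (60–100%); bright (0.95)
calcification and dark (0.05) cavity disks are stamped with probabilities
`calc_prob`/`cavity_prob` independent of class. Defaults — radius 13 px in
a 64-px crop, irregularity budget 0.4, texture budget 0.22, calc 0.30,
cavity 0.20 — were chosen so benign lesions average visibly higher
roundness (~0.96 vs ~0.83) and the two classes are separable but not by a
single trivial feature alone.

What it deliberately does not emulate: CT physics (no Hounsfield units,
beam hardening or slice thickness), anatomical context (no vessels, pleura
or juxtapleural attachment), segmentation error (masks are exact), and
inter-reader label noise. Consequently, passing tests demonstrate that the
pipeline's mechanics are correct and that supervision and pruning behave as
designed under class structure the features can express; they do not
predict absolute precision/accuracy on clinical images, where class overlap
is far larger. On the synthetic conditions the classes are in fact fully
separable, so the held-out precision and accuracy sit at their ceiling of
1.0 and the chance-floor assertions (> 0.5) are conservative.

## Problem sizes

The test suite and the acceptance script run the full pipeline at desk
scale: 400 training / 100 test images, 48-bit codes, 10 clusters, 4
candidate clusters, top-5 — sizes at which the dense eigendecompositions
and the greedy bit optimization complete in seconds while exercising every
stage at its default code length. The package itself imposes no such
limits.

## Known limitations

- The greedy bit optimizer is a local method; on adversarial label
  matrices a bit can fail to reduce the residual, in which case the trace
  monotonicity observed on separable data is not guaranteed.
- Dense n×n similarity and kernel matrices bound the practical database
  size to a few thousand images; no sparse-graph or out-of-core path.
- Alternative hashing backends are not implemented; the packed-code
  database is backend-agnostic so they could be slotted in.
- Retrieval quality on real data depends on the handcrafted features;
  no feature selection or learning is performed.
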