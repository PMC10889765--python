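# Methods

## Model

`virts` represents a grayscale image S (an M×N real matrix, M, N ≥ 3) by a
single vector in a 3-dimensional "texture space". A 3×3 observation window
slides across the image at stride 1 with no padding, so there are exactly
N_P = (M−2)(N−2) window positions, each detecting a pattern P = (p_ij) of
nine gray levels (1-based i, j inside the window). The pattern entries are
read as the coefficient matrix of a homogeneous linear system C_P·T = 0.
A homogeneous system has nontrivial solutions only when its determinant
vanishes; a scalar K multiplying p33 is chosen to force det = 0,

    K = [p31(p12 p23 − p22 p13) + p32(p13 p21 − p23 p11)]
        / [p33(p21 p12 − p11 p22)],

after which the system has infinitely many solutions. Solving the first
two equations by Cramer's rule, with the p_i3 t3 terms carried to the
right-hand side with positive sign, gives the one-parameter family

    t1 = (p13 p22 − p23 p12)/D · λ,
    t2 = (p11 p23 − p21 p13)/D · λ,
    t3 = λ,            D = p11 p22 − p12 p21.

The triple T = (t1, t2, t3) is the window's texture unit. Two consequences
of taking this formula as the definition are worth stating plainly:

- The unit satisfies p11 t1 + p12 t2 = **+**p13 t3 (and likewise for row
  2), i.e. the sign convention of the reduced system, not the homogeneous
  form with −p_i3 t3. The residual tests assert exactly what the formula
  satisfies.
- Pattern row 3 and the K value never enter the solution. `compute_K` is
  therefore exposed as a diagnostic (its contract — the K-modified matrix
  is singular — is property-tested) but the transform never calls it.

The image's texture vector is the componentwise sum over all windows,
C = (a1, a2, a3) with a_k = Σ_n t_k^(n), accumulated in double precision
(components reach ~10⁶–10⁷ at megapixel scale). Since t3 = λ for every
window, a3 = λ·N_P structurally; a1 and a2 carry all texture information.
λ is a pure scale factor on C. Geometric descriptors — magnitude and
direction cosines with cos²α + cos²β + cos²γ = 1 — are provided; the
direction of the zero vector is undefined and requesting it raises.

## Similarity and classification

Images are compared through the cosine of the angle between their texture
vectors, sim = (C_test · C_c)/(|C_test||C_c|), derived from the law of
cosines applied to the difference vector C_test − C_c (the derivation is
covered by a tested identity rather than a separate code path). A test
image is assigned to the prototype class of maximal similarity. Results
over a test set are reported as a confusion matrix H (rows = prototype
classes assigned, columns = true test classes) with efficiency
Ef% = 100·trace(H)/ΣH.

Because λ cancels in the cosine, similarity matrices and classification
results are invariant to the choice of λ (of the same sign); this is
tested at λ = 2 versus λ = 25 to 1e−9. Texture vectors can have negative
components, so similarities in [−1, 1] are admitted even though typical
natural-texture vectors cluster in the positive orthant; the argmax rule
is unchanged. Ties at the argmax are broken by earliest prototype in
insertion order, with a logged warning. Similarities of bitwise-identical
vectors are returned as exactly 1.0 (floating-point sqrt rounding can
otherwise leave the self-similarity one ulp below 1); all other values are
clamped to [−1, 1] against overshoot.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lam`) | 2 | free parameter of the parametric solution; pure scale factor on C. Any nonzero real works; 2 is the conventional small choice. λ = 0 yields the all-zero vector and is permitted only via `allow_zero_lambda`. |
| `degenerate_policy` | `zero-ratio` | handling of windows with D = 0 (see below); `skip` and `error` selectable. |
| `degeneracy_tol` | 1e−12 | relative tolerance ε of the test \|D\| ≤ ε·max(1, \|p11 p22\| + \|p12 p21\|). For integer-valued pixels the test is effectively exact. |

## Degenerate windows

The solution formula divides by D = p11 p22 − p12 p21, which vanishes on
flat patches and whenever the window's upper-left 2×2 block is singular.
The default `zero-ratio` policy substitutes (0, 0, λ): it contributes
nothing to a1/a2, preserves the a3 = λ·N_P structure, and never poisons
the sum with non-finite values. `skip` omits such windows from all three
sums (so a3 = λ·(N_P − n_degenerate)); `error` raises with the window's
origin. The per-image degenerate count is recorded on every result and
independently auditable via `count_degenerate_windows`.

## Input handling

Rasters (PNG/TIFF/JPEG/BMP) are loaded with imageio. Single-channel images
pass through as real values; RGB is reduced with ITU-R BT.601 luma weights
0.2989 R + 0.5870 G + 0.1140 B — the classic MATLAB `rgb2gray` convention —
and kept as real values without requantization (so pure white maps to
254.9745, not 255: the pinned weights sum to 0.9999; BT.709 would be a
deliberate config extension, not silent drift). 16-bit images are used at
native scale. Vector CSVs render floats with `repr`, so a save/load round
trip is bit-exact.

## Synthetic data

The generator stands in for photographed natural textures (the motivating
data are tree-bark photographs, which are not redistributable):

- `random_image(m, n, seed, low, high)`: integer-valued uniform field,
  seed-deterministic. Useful for structural checks (pattern counts, the
  a3 identity) that hold for *any* image.
- `texture_classes(n_classes, m, n, seed)`: one image per class, an
  oriented sinusoidal grating (class-specific spatial frequency 3 + 2k
  cycles/image and orientation 180k/n_classes degrees, amplitude 60 gray
  levels around offset 128) plus Gaussian noise of amplitude 8 gray
  levels, rounded and clamped to [1, 255]. The pixel floor of 1 keeps
  accidental D = 0 events rare; constant patches exercise the degenerate
  path deliberately. Defaults (10 classes, 64×64) keep the full multiclass
  experiment under a second while giving well-separated, pairwise
  non-parallel class vectors — this is checked after rendering, with a
  bounded seed-incrementing retry, and each class's noise stream is
  derived from a content hash of its recipe so that duplicated recipes
  render identical (parallel) images and are rejected.

What the synthetic set emulates: distinct oriented spatial-frequency
structure per class with pixel-level noise, 8-bit intensity range,
controllable degeneracy. What it does not: natural-image statistics
(1/f spectra, illumination gradients, shadows, JPEG artifacts), so a
passing suite demonstrates the transform's algebraic contracts and the
classifier's behavior on separable classes, not field performance on
photographs.

## Numerical choices

- Sums accumulate in float64 regardless of input dtype.
- The transform is vectorized over all windows with numpy slicing; an
  independent naive double-loop implementation lives in the test suite
  and must agree within 1e−6 relative on random images up to 64×64.
- Residual identity tolerance 1e−9 relative; direction-cosine identity
  1e−12; λ-invariance of similarity matrices 1e−9.
- Problem sizes in the examples and acceptance script (64×64 class
  images, 300×300 structural checks, 10,000-pattern property sweeps) are
  desk-scale choices: every quantity checked is either size-independent
  or pinned by the (M−2)(N−2) count, so nothing is lost relative to
  megapixel inputs, which the transform also handles (a 3120×4160 image
  takes a few hundred ms).

## Known limitations

- Resubstitution (classifying the prototype images themselves) is the
  evaluated regime; generalization to held-out images of the same class
  is not claimed and depends on how stable a class's texture vector is
  across acquisitions.
- The representation is not rotation- or scale-invariant, and only
  grayscale input is supported (color is reduced to luma).
- The window is fixed at 3×3; the two final components of the texture
  unit are ratios of 2×2 minors of the window's top two rows, so the
  bottom row of each pattern influences C only through window overlap.
- Similarity between texture vectors concentrates near 1 for large
  images at small λ, because a3 = λ·N_P dominates when a1, a2 ≪ λ·N_P;
  classification still works because the argmax compares like against
  like, but the dynamic range of similarities shrinks with image size.
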