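# Methods

## The model

A tooth surface is a triangular mesh M = (V, F), V ⊂ R³, F a list of vertex
triples. The classifier never sees the mesh directly; it sees a fixed-length
sequence derived from it. Simplifying every crown to exactly T triangles
makes the sequence length uniform; encoding each triangle as the 12-vector
(v1, v2, v3, centroid) ∈ R¹² makes each timestep a fixed-width feature row;
joint min–max normalization maps the whole T×12 matrix onto a single [0, 1]
intensity scale, the "grayscale image". Two stacked recurrent layers (the
first emitting its full hidden sequence, the second its final state) read
the rows in storage order, followed by a 64-unit ReLU layer and a softmax
head sized to the label scheme (16 sided types / 8 anatomical types /
4 categories). The loss is sparse categorical cross-entropy; the optimizer
Adam.

Assumptions worth making explicit:

- **Row order is part of the data contract.** Recurrent networks are not
  permutation-invariant, and nothing canonicalizes triangle order by
  default: the encoder emits faces in stored order, which for decimated
  meshes is the deterministic survivor order of the collapse sequence. An
  optional centroid sort (`canonical_order`) exists for order-sensitivity
  experiments.
- **Min–max normalization is per mesh.** It removes global scale and offset
  but not rotation: augmented variants of one tooth produce genuinely
  different images, which is the point of the augmentation.
- **Rigid motions carry no class information.** Rotation and translation are
  isometries; augmentation enlarges the pose distribution without touching
  shape.

## The rotation operator

The one-angle rotation matrix R(α) used for augmentation is specified
entry-wise (cos²α, cos α(sin²α − sin α), …). Algebraically it equals the
extrinsic Euler composition R_z(α)·R_y(α)·R_x(α) with all three angles
equal — the test suite verifies orthogonality, unit determinant and the
compositional identity to 1e-9 over random angles. Because a plausible
alternative reading is three *independent* Euler angles, `RotationSpec`
supports both: `single` (default, the entry-wise matrix) and `triple`
(independent α_x, α_y, α_z composed Z·Y·X). Angles are degrees in [0, 360);
translations are per-axis offsets drawn from [0, 90] in scanner units.

The expansion policy counts the identity copy: `variants_per_original = 6`
turns 448 originals into 2688 objects (one untransformed copy plus five
rotated-then-translated variants each). The draw order is fixed — per mesh,
per variant, rotation angle(s) before translation components — from one
seeded generator, so augmentation is bitwise reproducible.

## Decimation to an exact budget

The simplifier is greedy quadric-error-metric (QEM) edge collapse:
per-vertex quadrics are sums of incident-face plane quadrics, edges are
ranked by the cost of the cheapest placement among {v_i, v_j, midpoint}
under the summed quadric, and a lazy priority queue with per-vertex
versions processes collapses in cost order (ties break on vertex indices, so
the result is deterministic). Collapses violating the link condition or
flipping a surviving face normal are rejected. The candidate-subset
placement, rather than the optimal-point linear solve, keeps cost evaluation
fully vectorized; on a depth-5 icosphere decimated to 900 faces the mean
sampled surface deviation is ~0.2% of the bounding-box diagonal (the test
bound is 1%).

Exact counts: collapses stop at the first state ≤ target; if skips left the
count below target, longest-edge splits (+2 faces interior, +1 boundary)
restore it exactly. Closed manifold meshes have even face parity, which
collapses and interior splits preserve — an odd target on a closed mesh is
therefore unreachable and raises rather than silently approximating.

## Label schemes and splitting

The 16 canonical labels are the 8 maxillary types × (L)/(R). Collapsing to 8
drops the side (fan-in 2 everywhere); collapsing to 4 groups central+lateral
incisors → incisors, canine → canines, both premolars → premolars, all three
molars → molars (fan-ins 4, 2, 4, 6). Integer codes are alphabetical within
a scheme.

Splitting defaults to fraction 0.70 with floor rounding — chosen because
floor(0.70 × 2688) = 1881 reproduces the reference arithmetic exactly — and
stratifies by class: per-class floor quotas, topped up from the largest
classes to hit the global count. The default splits *after* augmentation,
so variants of one physical tooth can land on both sides; this replicates
the protocol the counts come from, and the report should be read as
augmented-pose accuracy, not subject-generalization accuracy. A
`group_aware` flag splits by source tooth instead (approximate counts, no
leakage).

## The networks

All four variants run on a small numpy engine (forward, BPTT, Adam) written
for this package; analytic gradients are checked against finite differences
in the test suite for every variant.

- GRU (default): update gate z, reset gate r, candidate
  n = tanh(W_n x + r ⊙ (U_n h)), h′ = z⊙h + (1−z)⊙n. Parameters per layer:
  3·(d_in·U + U² + U).
- LSTM and vanilla RNN mirror the GRU stack (2 layers × same units + FC64)
  for a matched-capacity comparison.
- CNN: two blocks of 3×3 convolution (32 then 64 filters, ReLU, 2×2
  max-pool) over the feature image as a 1-channel 2D image, then FC64 and
  the softmax head. When a feature subset makes the image too narrow to
  pool (centers-only: 3 columns), pooling degrades to 2×1 along that axis.

Initialization: Glorot-uniform input weights, orthogonal recurrent weights
(sign-fixed QR for determinism), zero biases except the LSTM forget gate
(1.0). Training defaults: 100 epochs, batch 32, a 10% validation carve-out
with patience-10 early stopping on validation loss, best-checkpoint
restore; everything keyed to a single seed — two runs with the same seed
are bitwise identical. Argmax ties at prediction resolve to the lowest
class index. Precision for classes with no predicted positives is defined
as 0.

## Synthetic data: what it emulates and what it does not

The generator replaces an unavailable intraoral-scan dataset (28 subjects ×
16 maxillary types = 448 crowns, ~10⁵ triangles each). Each anatomical type
is a superellipsoid crown — unit sphere mapped through sign(p)|p|^e, scaled
by per-class (width, depth, height) half-extents of ~4 mm — with
class-specific Gaussian cusp bumps on the occlusal face (incisors 0–1,
canine 1 tall, premolars 2, molars 3–4), placed on a circle whose phase is
random per tooth. Subject variation multiplies every shape parameter by
(1 + N(0, 0.05)). Right-side teeth are exact x-mirrors of left-side ones
drawn from the same stream. Default density is ~20k faces (raised to ≥100k
only where scan-density decimation itself is under test); class signatures
were fixed once so that a trivial classifier on (bounding-box aspect,
summit count) separates the 4 categories — the learning benchmark must be
winnable from geometry before a sequence model is asked to win it.

What passing tests therefore show: the pipeline's bookkeeping, operators and
learner work end to end on class-separable 3D shapes of realistic size. What
they do not show: performance on real dental anatomy — real crowns differ in
roots, wear, scan noise, inter-class similarity (2nd vs 3rd molars) and
class imbalance, none of which the generator models. Published accuracies on
private scan data are not reproducible here for that reason, and nothing in
this package claims them.

## Numerical and scale choices

- Float64 throughout the networks; softmax is max-shifted; sigmoid is
  evaluated branch-wise for stability.
- Degenerate min–max range (constant feature matrix) maps to the all-zero
  image rather than dividing by zero.
- STL input is welded at exact coordinate equality (tolerance 0) so
  reloaded topology is reproducible; OBJ's 1-based indices are converted at
  the boundary; no unit rescaling at I/O time.
- Desk-scale benchmark (`benchmark_config`): 28 subjects at 320 dense faces,
  120-triangle budget, 2×64-unit GRU, no augmentation expansion, 80 epochs
  with patience 12. These sizes keep one run to roughly a minute on one CPU
  core while leaving the 4-category task comfortably learnable; the
  accuracy bar (≥95% median over 3 seeds) is asserted in the acceptance
  suite. The ablation grid (4 variants × 3 subsets) runs at 8 subjects,
  120 triangles, 32 units, 80 epochs with patience 20 — the GRU needs
  ~15 warm-up epochs before its loss moves at this scale, which is why the
  patience is generous.
- The full-scale configuration (900 triangles, 128 units, 2688 objects)
  is expressible through the same configs and is exercised for its
  *arithmetic* (counts, shapes) in the acceptance suite; training at that
  scale is a long-running job, not a test.

## Known limitations

- QEM with candidate-subset placement yields slightly higher geometric error
  than optimal-point placement; for classification budgets (900 faces) the
  difference is far below the class signal.
- The numpy engine is single-threaded-friendly but not fast; it targets
  correctness and determinism at desk scale, not GPU-scale training.
- Group-aware splitting changes train counts away from the floor-exact
  arithmetic (whole groups move between sides).
- The generator's cusp geometry is stylized; summit-based cusp counting on
  real molars would need a watershed-style detector instead.
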