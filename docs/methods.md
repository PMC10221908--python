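# Methods

## The skeleton tree and its Euler tour

The OpenPose BODY_25 limb graph is a tree on 25 joints with 24 edges,
rooted here at the nose (joint 0). Columns of the encoded image follow
a depth-first walk that re-emits a joint each time the walk returns to
it, so a tree with E edges yields 2E + 1 = 49 columns and neighboring
columns are always neighboring joints — the property that makes limb
trajectories appear as coherent vertical bands in the image.

The walk's child ordering is a free choice; we fix it left-side
branches before right-side, distal chains before sibling branches
(neck's children in the order left arm, trunk, right arm). The
resulting 49-entry sequence is frozen as `CANONICAL_TOUR` and
regression-tested against a brute-force recursive walk. Any other
consistent ordering would work; what matters is that encode and decode
share one ordering.

Frames with no detected person become zero-confidence skeletons rather
than errors, so long recordings with detector dropouts still encode;
when a frame lists several people, the first is taken as the subject.

## Preprocessing

**Confidence gating.** Keypoints with confidence below a threshold
(default 0.3) are treated as noise: they contribute nothing to the
normalization extents and are overwritten by left-completion.

**Orientation.** Home recordings arrive rotated by 0/90/180/270
degrees. Rotation is applied in a centered frame where each axis is
mapped affinely onto [-0.5, 0.5], because there the quarter-turn
rotations are pure coordinate swaps/negations; coordinates are restored
to the original scale afterwards, with the x/y extents exchanged for
quarter turns (the frame's long and short sides swap). An explicit
user-supplied angle always takes precedence; the automatic fallback
returns the rotation after which the median neck-to-mid-hip vector
points downward in image coordinates. The heuristic needs at least one
frame where both anchors are confident and is otherwise indeterminate.

**Joint min-max normalization.** All sampled frames of a buffer are
normalized together — per-frame normalization would make the skeleton
jump between rows. The default form is x̂ = (x − x_min)/x_len, which
lands gated coordinates exactly in [0, 1]; a `eq4_literal` flag selects
the scale-only variant x̂ = x/x_len (which only stays in [0, 1] when
the minimum is zero; it is provided for comparison and is reproduced
without clipping). The parameters (x_min, x_len, y_min, y_len,
threshold, form flag) travel with the image as a JSON sidecar and are
required for decoding. Degenerate extents (a constant buffer) and an
empty confidence gate raise rather than produce NaNs.

**Left-completion.** Each tour-ordered row patches sub-threshold
positions with the full (x, y, c) of the nearest valid position to
their left, cascading so a patched position serves later ones. Rows
that start missing borrow from the nearest valid position to the right;
an entirely missing row becomes zeros. The operation is idempotent.

Alternative whole-buffer normalizations (z-score, zero-mean, RMS, unit
norm) are exposed as named strategies for experimentation but the
pipeline uses min-max only.

## Encoding and decoding

Encode: sample 49 row-frames (uniform-random sampling preserves
acceleration/deceleration; stratified sampling — one frame per equal
segment — smooths it), normalize jointly, expand 25 joints to 49
columns, left-complete, stack rows in time order. Channels are R = x̂,
G = ŷ, B = confidence. Optional edit windows (half-open [start, end),
0-based, from a `video_id,start_frame,end_frame` CSV) trim lead-in and
lead-out frames first.

Decode collapses each joint's duplicate columns — arithmetic mean by
default, first-instance mode available; the mean is preferred because
generated images show slight divergence between duplicates — and
inverts the min-max map through the sidecar. On clean input the round
trip recovers gated keypoints to float precision; the 8-bit PNG path is
bounded by half a quantization step (1/510 per channel). Lossless
storage is a float `.npz` plus the JSON sidecar; PNG is for
visualization and interchange.

## VAE and the duplicate-keypoint penalty

Because the tour duplicates joints, a generated image is anatomically
coherent only if duplicate columns agree. KPMSE sums, over rows and
duplicate groups, the squared 3-channel differences of all unordered
column pairs in the group. The training loss is

    loss = MSE + β·D_KL + α·KPMSE,   0 ≤ α, β ≤ 1  (defaults 0.5, 0.5)

with D_KL the closed-form divergence of the encoder's diagonal Gaussian
from N(0, I). So the weights trade off comparable magnitudes, each term
enters as a per-element mean: MSE over pixels, D_KL divided by the
flattened input dimension, KPMSE divided by rows × pairs × 3. The
public `kpmse` function returns the raw sum. The KPMSE gradient uses
the identity Σ_{i<j}(x_i − x_j)² = d·Σx² − (Σx)² per group.

The reference backbone is a fully connected encoder/decoder (input
7203 → 256 → 256 → latent 16, mirrored decoder with a sigmoid output),
trained with Adam and hand-written backpropagation; log-variances are
clipped to [-8, 8] for stability. The architecture is a contract, not a
mandate: anything exposing `encode`/`decode` with the same signatures
can stand in. Training is fully seeded — parameter initialization,
shuffling and the reparameterization draws all derive from the config
seed — so runs are bit-reproducible on one machine.

Movement synthesis: each class's encoded latents form a cloud; fitting
a per-dimension Gaussian to that cloud and decoding draws from it
yields new movements of that class. Averaging two latents merges two
movements. A t-SNE helper (scikit-learn) maps latent clouds to 2D for
inspection.

## Classification and scoring

The classifier contract is a probability vector over the six classes
summing to one; the reference implementation is a compact scikit-learn
MLP over the raw 49×49×3 pixels. Data splits are stratified by label
with a deterministic seed; the train side receives
floor(n · fraction) items apportioned by largest remainder, so 2004
images at 80% split 1603/401.

Scoring embeds reference and subject with one shared backbone and maps
their Euclidean distance D to s = min(α·100/D, 100), α = 30: an
inverse-distance score capped at 100, with D = 0 scoring 100 by
convention. The companion similarity S = 1 − ‖T1 − T2‖/‖T2‖ normalizes
by the reference norm and equals 1 exactly at a perfect match. The
contrastive pair loss uses Y = 0 for similar and Y = 1 for dissimilar
pairs — the convention under which the (1 − Y) term penalizes distance.

Two embedders ship: a flatten (identity) embedder, and a linear Siamese
projection trained with the contrastive loss. For discriminative
scoring the margin is set at 100, the same scale as the score rule's
threshold distance (α·100/D < 100 iff D > 30), so dissimilar-class
distances are pushed toward the region that scores low while same-class
distances collapse toward zero. A sigmoid dense head over concatenated
pair embeddings is provided as an alternative similarity output; the
distance path is what scoring uses.

## The exercise simulator

The simulator stands in for recorded video. Each exercise is a set of
sinusoidal joint-offset trajectories around a fixed standing pose
(exactly mirror-symmetric about the body midline), cycled ten times
over the active span, with idle base-pose padding (default 30 frames)
at both ends, at 30 fps and 1000–3000 frames per recording. The two
arm exercises run the right side for the first half and the mirrored
left side for the second, which produces the central contrast line
visible in their encoded images. LBE and SLL both move predominantly
the leg (backward vs. sideways), intentionally forming the confusable
pair of the set. The noise model adds Gaussian coordinate jitter
(default σ = 2 px), confidence dropout (default 5% of keypoints fall
below the gate), and a visible-confidence mean of 0.9. Dataset assembly
randomizes phase, amplitude (±20%), subject scale (±15%) and sampler
draws per image, all deterministically derived from one master seed.

What the simulator does *not* emulate: perspective and camera motion,
occlusion-correlated confidence structure, biomechanical coupling
between joints, inter-subject style variation beyond scale/amplitude,
or detector-specific error patterns. Tests passing on this data show
the pipeline's operations are correct and that the method separates
genuinely distinct cyclic movements; they do not certify accuracy on
recorded human video.

## Problem sizes and numerical choices

The test suite trains on scaled synthetic corpora chosen as the
package's own study conditions: 200 images per class for the
classification check (held-out accuracy ≥ 90%), 600 images for the VAE
pair (30 epochs, batch 32, learning rate 1e-3, seeds fixed; the α = 0.5
twin must beat the α = 0 twin on reconstruction KPMSE), 60 epochs for
the movement-generation check, and a 2004-image assembly for the split
counts. Ties in stratified splitting are broken by class order;
samplers return indices in ascending time order; all randomness flows
through `numpy.random.default_rng` seeds.

## Known limitations

- The encoder assumes one subject per frame (first detection wins).
- Orientation detection needs a confident neck and mid-hip somewhere in
  the buffer and assumes the trunk points roughly down when upright.
- The empirical score's α = 30 is tied to the embedding scale; a new
  backbone generally needs a recalibrated α or margin.
- Left-completion propagates stale coordinates through long dropouts
  rather than interpolating.
- The linear contrastive embedder separates classes that are linearly
  separable in pixel space; harder data would need a nonlinear backbone
  behind the same interface.
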