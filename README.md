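# tssci

Tools for analyzing human movement by re-representing a time series of
2D pose skeletons as a **single static color image** — a tree-structure
skeleton color image (TSSCI) — so that a whole physiotherapy exercise
becomes one object that ordinary image models can classify, regenerate
and compare.

The package is aimed at researchers and engineers working on
camera-based exercise assessment: it consumes per-frame OpenPose-style
keypoint detections (25 body joints, each `(x, y, confidence)`), and
provides the encoder/decoder, a six-class exercise classifier contract,
a variational autoencoder for movement synthesis, an empirical 0–100
exercise-quality score, and a parametric simulator of six cyclic
physiotherapy exercises so everything is testable without video data.

## The representation

The 25-joint body graph is a tree (24 limbs). A depth-first **Euler
tour** from the nose re-emits each joint every time the walk returns to
it, giving `2·24 + 1 = 49` positions in which adjacent entries are
always adjacent joints:

```
0 1 5 6 7 6 5 1 8 12 13 14 19 20 19 14 21 14 13 12 8 9 10 11 22 23 22
11 24 11 10 9 8 1 2 3 4 3 2 1 0 16 18 16 0 15 17 15 0
```

An exercise video is encoded by sampling 49 frames (uniform-random or
stratified), min-max normalizing all sampled skeletons **jointly** onto
[0, 1], expanding each frame's 25 joints to the 49 tour columns, and
patching low-confidence positions from their nearest valid neighbor on
the left ("completing from the left"). The result is a 49×49×3 image:
rows are frames, columns are tour positions, and the red/green/blue
channels hold x̂, ŷ and the detector confidence. A JSON parameter
sidecar makes the encoding invertible back to coordinate space.

Downstream:

- **Classification** — a compact network maps the image to a
  probability vector over the classes AFR, ARO, LBE, LFC, SLL, TRO.
- **Generation** — a VAE (latent dimension 16) trained with
  `loss = MSE + β·D_KL + α·KPMSE`, where KPMSE penalizes disagreement
  between columns that duplicate the same joint, so generated skeletons
  stay anatomically coherent. Class-conditional movements are drawn
  from the per-class Gaussian fitted in latent space; averaging two
  latents merges two movements.
- **Scoring** — reference and subject images are embedded by a shared
  (Siamese) backbone; with Euclidean distance `D` between embeddings,
  the score is `s = min(α·100/D, 100)` with `α = 30`.

## Worked example

```python
import numpy as np
from tssci import (NoiseModel, default_template, generate_motion,
                   encode, decode, empirical_score, FlattenEmbedder)

# simulate a trunk-rotation recording: 1000 frames at 30 fps
buffer = generate_motion(default_template("TRO"), n_frames=1000,
                         noise=NoiseModel(seed=3))
image = encode(buffer, seed=5, label="TRO")
print(image.pixels.shape)          # (49, 49, 3)

# the image decodes back to coordinate space
recovered = decode(image)
sampled = buffer.data[image.source_positions]
gate = sampled[..., 2] >= 0.3
print(float(np.abs(recovered.data[gate] - sampled[gate]).max()))  # 5.7e-14

# score a second recording of the same exercise against it
other = encode(generate_motion(default_template("TRO"), n_frames=1000,
                               noise=NoiseModel(seed=4)), seed=6)
emb = FlattenEmbedder()
d = float(np.linalg.norm(emb.embed(image) - emb.embed(other)))
print(round(d, 2), empirical_score(d))  # 4.88 100.0
```

The two TRO performances differ only by detector noise, so their
pixel-space distance (4.88) is far below the score threshold and the
subject scores the full 100. Discriminative scoring across different
exercises uses a contrastive-trained embedder (`ContrastiveEmbedder`),
which pushes cross-class distances toward the margin — see
`tssci.scoring.score_matrix`.

A command-line interface mirrors the library:

```bash
tssci simulate --exercise ARO --frames 3000 --seed 1 --out poses/
tssci encode --in poses/ --sampler stratified --seed 1 --out aro --png aro.png
tssci decode --in aro --out frames/
tssci train-vae --data images/ --latent 16 --alpha 0.5 --beta 0.5 --out vae.npz
tssci score --reference expert.npz --subject patient.npz --alpha 30
```

## Layout

- `tssci.skeleton` — body graph, Euler tour, OpenPose JSON I/O
- `tssci.preprocess` — confidence gating, orientation fix, normalizations,
  left-completion
- `tssci.codec` — frame samplers, edit windows, encode/decode, storage
- `tssci.generative` — VAE, KPMSE loss, latent merging, conditional sampling
- `tssci.scoring` — classifier, Siamese embedders, scores, score matrix
- `tssci.simulate` — the six-exercise motion simulator
- `docs/methods.md` — models, assumptions, parameter choices, limitations
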