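# osteoseg

Semantic segmentation of osteosarcoma in 2-D MRI slices with a multiscale
residual-fusion network.

Osteosarcoma is the most common primary malignant bone tumor, peaking in
adolescence. Its MRI appearance carries semantic information at several
resolutions at once, and tumor boundaries often blur into bone and soft
tissue. `osteoseg` implements a segmentation network built around three
ideas:

1. **Dual-resolution exchange blocks.** Two densely connected convolution
   routes process a high- and a low-resolution view of the same anatomy one
   octave apart. The n-th step of each route concatenates all earlier maps
   of its own route with the other route's previous map (resampled across
   the octave) and applies a 3x3 convolution whose width is the route's
   *growth factor*:

   `M_n^s = H([M_{n-1}^s, resample(M_{n-1}^s̄), M_{n-2}^s, ..., M_0^s])`

   The block output uses scaled residual learning, `O^s = w·M_5^s + M_0^s`
   with `w = 0.4`, keeping the deep path a stable perturbation of the
   shallow one.

2. **A four-scale fusion subnetwork.** Four layers, each pairing all six
   combinations of the four encoder scales into exchange blocks and fusing
   each scale's candidates; the first layer's output is added to the
   subnet's input. After four layers every output scale depends on every
   input scale.

3. **A gated shape stream and attention decoders.** A full-resolution
   boundary stream is gated step by step by attention maps
   `alpha = sigma(Conv1x1([S, D]))` computed against deep semantic features
   and supervised with the morphological boundary of the mask; decoders
   combine residual squeeze-excitation spatial/channel attention
   `A_SC = (SE + 1)(x) ⊙ M` with an additive attention gate on each skip
   connection.

Training optimizes Dice + BCE + edge-BCE with Adam; quality is reported as
IoU, DSC, precision, recall, F1 and accuracy from per-pixel confusion
counts.

The network, including its automatic differentiation, is implemented on a
NumPy backend contained in `osteoseg.nn` — the package has no deep-learning
framework dependency. Clinical osteosarcoma data is not redistributable, so
the package ships a phantom generator (`osteoseg.phantom`) producing
MRI-like slices with irregular bright tumors, bone-band backgrounds,
Gaussian acquisition noise and exact ground-truth masks; every experiment
below runs on phantoms.

## Worked example

```python
import numpy as np
from osteoseg import TumorSegmenter, PhantomSpec, generate_dataset

samples = generate_dataset(PhantomSpec(seed=1), 200)
X = np.stack([s.image for s in samples])   # (200, 64, 64) in [0, 1]
y = np.stack([s.mask for s in samples])    # binary tumor masks

est = TumorSegmenter(base_channels=8, fusion_layers=2, pairing="adjacent",
                     lr=2e-3, epochs=10, batch_size=2, max_steps=300,
                     validation_fraction=0.2, seed=1)
est.fit(X, y)
print(f"held-out mean DSC: {est.score(X[160:], y[160:]):.3f}")
```

This trains the desk-scale configuration (about 3.7 M parameters) for 300
optimizer steps and prints

```
held-out mean DSC: 0.964
```

meaning the predicted masks overlap the true phantom tumors at a Dice
coefficient of 0.964 averaged over 40 held-out slices — recovering the
known geometry almost exactly, far above the all-foreground baseline
(0.198 on this set: the score of declaring every pixel tumor).

The same pipeline is scriptable from the shell:

```bash
osteoseg synth --out data --n 200 --seed 1
osteoseg preprocess --in data --out prep
osteoseg train --data prep --out run --epochs 5
osteoseg predict --checkpoint run/checkpoint.npz --in data --out pred
osteoseg evaluate --pred pred --truth data/masks --out metrics.csv
```

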