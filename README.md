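# ctsnet

Retinal-layer segmentation of OCT B-scans with a cross-shaped-window
(CSWin) transformer U-net and a boundary-area Dice loss.

Glaucoma is diagnosed early from the thickness of the retinal nerve
fiber layer (RNFL), which requires tracing the retinal layer boundaries
in OCT cross-sections. This package implements, end to end and on plain
CPU numpy, a pixel-level segmentation pipeline for that task:

- **CTS-Net**, a U-shaped encoder-decoder whose blocks compute
  self-attention inside horizontal and vertical stripes of the token
  grid (cross-shaped windows) — a good match for tissue that is layered
  laterally and ordered axially;
- **BADice**, a Dice loss restricted to a band of width *d* around each
  class's ground-truth boundary, combined with plain Dice as
  `L = w1·L_Dice + w2·L_BADice` (defaults `w1 = w2 = 0.5`, `d = 10`) so
  the optimiser concentrates on the edge regions that decide boundary
  accuracy;
- geometry pre/post-processing (axial crop [63, 613) → 256×1024 resample
  → four 256×256 tiles, and the inverse restoration), boundary
  extraction from class maps with Savitzky–Golay smoothing (window 33),
  and the standard metrics: per-boundary MAD and RMSE in pixels
  (columnwise `mean|p_i − g_i|` and `sqrt(mean (p_i − g_i)^2)`) and
  per-layer DSC `2|P∩G| / (|P| + |G|) × 100`;
- a synthetic phantom generator (layered geometry, speckle-like noise,
  glaucomatous RNFL thinning) so everything — training included — runs
  without any external dataset;
- SGD training with the polynomial schedule
  `lr = lr0·(1 − it/it_max)^0.95` and a 5-fold cross-validation harness.

The network and its training run on a compact reverse-mode autodiff
engine over numpy included in the package (`ctsnet.tensor`, `ctsnet.nn`).

## Worked example

Train the reduced desk-scale network on eight noise-free synthetic
phantoms and score it on its training set:

```python
import numpy as np
from ctsnet import (PhantomSpec, generate_dataset, NetworkSpec, TrainSpec,
                    LossSpec, train, predict_mask, mask_to_boundaries,
                    SGFilterSpec, smooth_boundaries, evaluate)

phantoms = PhantomSpec(h=64, w=64, mean_depths=(10, 24, 36, 48, 60),
                       amplitude=2.0, smoothness=8.0, speckle_sigma=0.0)
samples = generate_dataset(8, phantoms, seed=1)
data = [(s.image, s.mask) for s in samples]

net = NetworkSpec(base_channels=16, heads=(2, 4, 8), stripe_widths=(1, 2, 4))
schedule = TrainSpec(epochs=300, batch=8, seed=0, lr0=0.2,
                     loss=LossSpec(d=10, w1=0.5, w2=0.5))
model, history = train(data, schedule, net, max_iterations=300)

masks = predict_mask(model(np.stack([img for img, _ in data])))
sg = SGFilterSpec(window=31, order=3)
preds = [(m, smooth_boundaries(mask_to_boundaries(m, repair=True), sg))
         for m in masks]
gts = [(s.mask, s.boundaries) for s in samples]
report = evaluate(preds, gts)
print(report.layer_table.round(2))
print(report.boundary_table.round(2))
```

Output (about a minute on one CPU):

```
         dsc_mean  dsc_std
RNFL        99.27     0.28
GCIPL       99.33     0.36
CL          96.04     1.38
Overall     98.22     0.67
            mad_mean  mad_std  rmse_mean  rmse_std
ILM             0.54     0.08       0.58      0.09
RNFL-GCIPL      0.47     0.09       0.50      0.09
GCIPL-INL       2.41     1.09       3.39      1.64
BM              1.00     0.39       1.20      0.49
CS              0.55     0.04       0.58      0.04
Overall         0.99     0.34       1.25      0.47
```

Each layer row is the Dice overlap (percent, mean and spread across the
eight phantoms) between the predicted and true class masks; each
boundary row is the columnwise distance (pixels) between the predicted
and true traces after Savitzky–Golay smoothing. Training DSC above 95%
per layer and sub-pixel errors on most boundaries show the assembled
network learns the layered geometry from scratch.

The same pipeline is scriptable from the shell:

```sh
ctsnet synth --n 8 --seed 0 --out data/synth
ctsnet run --stages synth,train,predict,evaluate --n 8 --out runs/demo \
           --max-iterations 300
ctsnet crossval --data data/synth --out runs/cv --k 2 --max-iterations 50
```

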