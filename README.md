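# meanet

Binary medical image segmentation with a multilayer edge-attention
encoder–decoder network (MEA-Net), implemented end to end on NumPy with
its own reverse-mode autodiff core — no deep-learning framework
required.

Medical segmentation targets (a tongue body, retinal vessels, lung
fields) are often separated from their surroundings chiefly by their
*edges*, and plain encoder–decoder networks progressively wash out this
low-level information on the way to deeper layers. MEA-Net counteracts
that with a dedicated edge module running alongside the encoder:

* **EFE (edge feature extraction)** maps the two shallow encoder stages
  E1, E2 to N = 16 channels with 3×3 convolutions and fuses them at E1
  resolution,

  A = Conv₃ₓ₃(X₁) + U[Conv₃ₓ₃(X₂)],

  where U is bilinear ×2 upsampling, yielding 16 edge attention maps.
* **MAG (multilayer attention guidance)** multiplies each attention map
  into the shallow features and sums, U_total = Σₘ (Aₘ ⊗ X₁), gates the
  channels with a squeeze-and-excitation block
  s = σ(W₁ δ(W₂ z)), z_k = mean of channel k, and emits decoder-bound
  edge features Y₁ plus a one-channel edge prediction Y₂ that receives
  early supervision.

The encoder uses residual blocks with asymmetric (3×1 and 1×3)
convolutions; the decoder is three cascaded blocks that fuse skip and
deep features through a sigmoid channel gate; the last decoder output
is combined with Y₁ and convolved into the segmentation map. Training
minimises the joint objective

L_total = α·L_Dice + (1 − α)·L_BCE,  α = 0.3,

with the Dice term on the edge head and binary cross-entropy on the
segmentation head, using Adam (lr 2e−3, betas (0.5, 0.999), batch 4).
Evaluation reports per-image Accuracy, Sensitivity, Dice, AUC and
boundary F1 (BF-Score), aggregated as mean ± standard deviation.

Because the real benchmark datasets cannot ship with the package, a
seeded phantom generator produces three regimes of paired image/mask
data (compact blobs on cluttered backgrounds, thin vessel trees,
mirrored lung-like regions with holes) on which the whole system —
network, losses, metrics, training loop — runs in minutes on a CPU.

## Worked example

```python
import numpy as np
from meanet import (NetworkConfig, TrainConfig, generate_dataset,
                    evaluate, train)

samples = generate_dataset("blob", 8, seed=42, size=(64, 64))
cfg = TrainConfig(global_seed=1, max_steps=200, target_dice=0.95,
                  val_interval=5, network=NetworkConfig(input_channels=1))
result = train(samples, cfg, "run/", val_samples=samples)
report = evaluate(result.model, samples)
print(f"steps: {result.history[-1]['step']}")
print(report.format_table())
```

prints

```
steps: 42
accuracy     0.9830 ± 0.0021
sensitivity  1.0000 ± 0.0000
dice         0.9693 ± 0.0044
auc          0.9999 ± 0.0000
bf_score     0.5123 ± 0.0547
```

i.e. the default-width network overfits the eight held-in phantoms to a
mean Dice of about 0.97 within 42 optimizer steps: the segmentation
overlaps the ground truth almost completely (accuracy and AUC near 1),
while the stricter boundary F1 shows the contour is still a pixel or
two off in places — exactly the behaviour the edge supervision is there
to improve with longer training.

The same workflow is available from the shell:

```bash
meanet synth --kind blob --n 8 --size 64 --out data/
meanet split --data data/ --out splits.json
meanet train --data data/ --splits splits.json --out run/
meanet eval  --checkpoint run/checkpoint.npz --data data/ --splits splits.json --out report/
meanet predict --checkpoint run/checkpoint.npz --images data/blob-*_image.png --out pred/
```

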