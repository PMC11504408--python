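# mrdb

Dual-branch ultrasound nodule segmentation in pure scientific Python. The
model couples a 2D-selective-scan state-space encoder (global context) with
a ResNet-34 encoder (local detail), decodes through two asymmetric decoder
branches (upsample→conv→conv on the left, conv→upsample→conv on the right),
and routes skip features crosswise: state-space features are *added* into
the right decoder, residual features are *concatenated* into the left one.
Training uses a hybrid BCE + Dice + 0.5·Smooth-L1 loss; evaluation covers
DSC, Jaccard, sensitivity, FNR, 95th-percentile Hausdorff distance and a
pooled pixel-level PR curve.

Because no GPU framework is assumed, the package ships its own compact
reverse-mode autodiff engine on numpy (`mrdb.autograd`): im2col
convolutions, exact transpose-conv adjoints, batch/layer norm, and a linear
first-order recurrence primitive that powers the selective scan. A
synthetic speckle-phantom generator provides image/mask pairs so every
training and evaluation path runs without external data.

## Layout

| module | contents |
| --- | --- |
| `mrdb.autograd` | Tensor + layers + Adam (numpy reverse-mode autodiff) |
| `mrdb.ssm2d` | scan expand/merge, selective scan (S6), VSS block |
| `mrdb.resnet_encoder` | headless ResNet-34 pyramid (block counts 3/4/6/3) |
| `mrdb.vss_encoder` | patch-embed stem + four VSS-block stages |
| `mrdb.decoders` | asymmetric decoder stages + resolution head |
| `mrdb.network` | full assembly, cross-skip fusion, ablation switches |
| `mrdb.losses` | BCE, soft Dice, Smooth L1, hybrid loss |
| `mrdb.metrics` | DSC/Jaccard/sensitivity/FNR/HD95/PR-AUC + CSV report |
| `mrdb.phantom` | speckle phantom generator + training augmentations |
| `mrdb.pipeline` | dataset IO, training loop, evaluation, ablation grid |

## CLI

```bash
mrdb phantom --n 100 --out data/ --seed 7          # synthetic dataset
mrdb train   --config cfg.yaml --data data/ --out run/
mrdb eval    --ckpt run/checkpoint.npz --data data/ --out report.csv
mrdb ablate  --config cfg.yaml --data data/ --out runs/   # six-config ladder
```

Datasets are `images/*.png` + `masks/*.png` folder pairs (8-bit grayscale,
masks {0,255}); configs are YAML mirrors of `TrainConfig` / `MRDBConfig`.
Defaults follow the published recipe (Adam, lr 1e-3, 256×256 inputs, batch
32, 200 epochs) — scale `base_channels`, `input_side`, `epochs` and
`max_steps` down for CPU-size experiments.

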