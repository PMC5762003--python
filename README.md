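# echoseg

Self-normalizing encoder–decoder segmentation of 2-D ultrasound images, in
pure NumPy, together with a complete evaluation framework: speckle phantoms
with simulated multi-operator annotations, seven segmentation metrics,
computer-to-observer / inter-observer agreement tables, the extended
Williams' index, paired t-tests, and per-stage area agreement.

The network family comprises a SELU-activated U-Net-style model (`sunet`),
the same model with alpha dropout (`sunet_dropout`), a batch-norm + ReLU
baseline (`unet`), and a variant with dilated final-block convolutions
(`unet_dc`). Forward and backward passes are hand-written NumPy (no deep
learning framework required); everything runs on one CPU.

## Layout

| module | role |
|---|---|
| `echoseg.phantom` | seeded speckle phantoms, ground truth, simulated operators |
| `echoseg.preprocess` | crop/pad to 214×262, resize to 107×131, 6-DOF affine augmentation, mini-batching |
| `echoseg.network` | SELU, alpha dropout, encoder-decoder variants, checkpoints |
| `echoseg.training` | soft-Dice + L2 loss, Adam loop, leave-one-patient-out harness |
| `echoseg.postprocess` | threshold → hole fill → largest component |
| `echoseg.metrics` | Dice, Jaccard, FPD, FND, Hausdorff, MAD, SMAD (mm) |
| `echoseg.agreement` | COD/IOD tables, Williams' index + 95% CI, t-tests, area agreement |
| `echoseg.dataio` / `echoseg.cli` | PNG+JSON sidecar / MetaImage I/O, `echoseg` command |

## CLI

```sh
echoseg phantom --n-patients 5 --seed 1 --out-dir runs/ds     # synthetic dataset + manifest
echoseg train   --manifest runs/ds/manifest.csv --out-dir runs/fit
echoseg lopo    --manifest runs/ds/manifest.csv --out-dir runs/cv
echoseg segment runs/fit/checkpoints/model.npz image.png out.png
echoseg evaluate maskA.png maskB.png                          # seven-metric CSV row
echoseg agree cod.csv iod.csv --out agreement.json            # medians/IQR + Williams' index
echoseg bench --seed 1 --out-dir runs/bench                   # SU-Net vs U-Net convergence CSVs
```

All subcommands accept `--config config.yaml` (strict keys; see
`echoseg.config.RunConfig`), `--seed`, and `--variant
{sunet,sunet_dropout,unet,unet_dc}`. Runs echo their configuration into the
output directory and write a manifest with content hashes.

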