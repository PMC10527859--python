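# dermoseg

Semantic segmentation of **dermoscopic attributes** — pigment network,
globules, streaks, negative network and milia-like cysts — in skin-lesion
images, in the style of ISIC 2018 Task 2.  The package implements the
Dermo-Seg approach: one binary encoder–decoder model per attribute, a
ResNet-50 residual encoder feeding a UNet decoder with four skip
connections, trained under a **hybrid focal-Tversky + soft-IoU loss** that
targets the extreme pixel-level class imbalance of these structures (a
positive mask typically covers well under 5% of the lesion).

It is aimed at researchers who want a fully inspectable, CPU-runnable
reference of every stage of such a pipeline — loss mathematics, network
assembly, dataset handling, training protocol, evaluation — with a bundled
synthetic dermoscopy generator so that everything is testable without any
dataset download.  The network and its training run on a compact numpy
layer core included in the package (`dermoseg.nn`), with hand-derived,
finite-difference-validated backward passes.

## The model and loss

For predicted per-pixel foreground probabilities `p_i` and binary ground
truth `g_i`, the Tversky index with false-negative weight α and
false-positive weight β is

    TI = (Σ p_i g_i + ε) / (Σ p_i g_i + α Σ (1−p_i) g_i + β Σ p_i (1−g_i) + ε)

and the focal Tversky loss is `FTL = (1 − TI)^(1/γ)` with focal exponent
γ = 4/3.  The soft IoU loss is the differentiable Jaccard surrogate

    L_IoU = 1 − I(X)/U(X),  I(X) = Σ x_v y_v,  U(X) = Σ (x_v + y_v − x_v y_v)

with the analytic gradient `∂L_IoU/∂x_v = −1/U` where `y_v = 1` and
`I/U²` elsewhere.  Training minimises the unweighted sum `FTL + L_IoU`
with Adam (512×512 inputs, batch 8, ≤60 epochs, patience-20 early stopping
with best-weight restoration in the full protocol; defaults α = 0.7,
β = 0.3, ε = 1e−6).  Evaluation is count-based: per-class
`IoU = TP/(TP+FP+FN)`, the mean over foreground and background classes,
and a full ROC sweep.

## Worked example (CPU, ~1 minute)

Generate 120 synthetic "easy mode" lesion images (high-contrast
globule-style structures, foreground ≈ 1–2% of each image) and train the
reduced desk-profile model for that attribute:

```bash
dermoseg synth scratch/demo --easy --n-images 120 --side 96 --seed 3
dermoseg train scratch/demo scratch/demo_run --attribute globules --profile desk --seed 0
dermoseg eval  scratch/demo --checkpoint scratch/demo_run/weights.npz \
               --attribute globules --profile desk --input-size 96 \
               --report scratch/demo_run/report.json
```

which prints (abridged):

```
epoch   1  train 1.9425  val 1.9324  fg-IoU 0.060
epoch   5  train 1.9020  val 1.8973  fg-IoU 0.324
epoch  10  train 1.8385  val 1.8239  fg-IoU 0.618
stopped at epoch 10 (best 10); weights -> scratch/demo_run/weights.npz
{
  "mean_iou": 0.8101287188652871,
  "foreground": 0.626379752480767,
  "background": 0.9938776852498072,
  "auc": 0.9999235781797461
}
```

The training loss is the hybrid loss pooled over each batch; `fg-IoU` is
the held-out foreground Jaccard index at threshold 0.5.  Starting from
random weights, ten epochs of hybrid-loss training lift the foreground
IoU from 0.06 to ≈0.62 on structures occupying ~1% of the pixels — the
regime in which an identically configured per-pixel cross-entropy run
collapses to the background class (see
`tests/test_acceptance.py::test_hybrid_training_recovers_sparse_foreground_and_beats_bce`).

The canonical full-size model is summarised with:

```bash
$ dermoseg summary --profile paper
Total parameters:         32,520,977
Trainable parameters:     9,012,945
Non-trainable parameters: 23,508,032
```

(the frozen ResNet-50 encoder is the non-trainable part; decoder and 1×1
sigmoid head are trained).

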