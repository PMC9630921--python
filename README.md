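# wheatformer

A self-contained detection toolkit for dense elongated objects (wheat
spikes), built around three pieces:

* **MW-Swin backbone** (`wheatformer.backbone`) — a hierarchical vision
  transformer whose attention runs three parallel shifted-window branches
  with window sizes 7/9/11, concatenated and projected back per block.
  Four stages at strides [4, 8, 16, 32]; S/B/L variants (depths
  [2,2,2,2] / [2,2,6,2] / [2,2,18,2] at channels [96,192,384,768]) plus a
  reduced `tiny` variant for CPU-scale runs.  Variant definitions ship in
  `src/wheatformer/configs/variants.yaml`.
* **WIoU box-regression loss** (`wheatformer.boxes`) — IoU/GIoU/CIoU plus an
  aspect-consistency-weighted squared-center-distance loss
  (`loss = 1 - IoU + psi * ||c_p - c_g||^2`), with ltrb distance
  encoding/decoding and FCOS centerness.
* **Anchor-free one-stage detector** (`wheatformer.detector`) — FPN P3–P7,
  per-location assignment with level regression ranges and min-area
  tie-breaking, focal + centerness + selectable IoU-family losses, NMS
  decoding — with COCO-style evaluation (`wheatformer.evaluation`: mAP,
  AP50, AP75, APm, APl, 101-point interpolation, area-range ignore
  semantics).

Everything runs on a small numpy reverse-mode autodiff engine
(`wheatformer.nn`); there is no GPU or deep-learning-framework dependency.
A seeded synthetic scene generator (`wheatformer.synth`) provides dense
striped-ellipse "spike" scenes with exact ground-truth boxes, and
`wheatformer.annotations` reads/writes LabelImg/Pascal-VOC XML and COCO JSON.

## CLI

```sh
# generate a seeded synthetic dataset (images + VOC XML + COCO JSON + manifest)
wheatformer synth --tiny-test --seed 7 --data-dir data/demo --n-images 16

# train (per-iteration loss log + checkpoint); --tiny-test selects the
# CPU-scale variant, otherwise defaults follow the published settings
# (AdamW, lr 1e-4, weight decay 0.05, 24 epochs)
wheatformer train --tiny-test --seed 7 --data-dir data/demo \
    --out runs/demo --iterations 200

# COCO metrics on the validation split
wheatformer eval --tiny-test --data-dir data/demo --out runs/demo \
    --checkpoint runs/demo/checkpoint.npz

# detect on arbitrary images, with box overlays
wheatformer predict --tiny-test --checkpoint runs/demo/checkpoint.npz \
    --out runs/demo --overlay data/demo/images/*.png
```

All commands accept `--config <yaml>` plus `--seed/--out` overrides; reruns
with the same seed are reproducible (bitwise for `synth`).

## Notes

* The WIoU distance term is implemented as published (raw squared center
  distance weighted only by psi).  Because psi multiplies the distance, the
  penalty vanishes whenever the aspect ratios are equal; an optional
  DIoU-style normalized mode (`wiou_normalize_distance`) is used as the
  training default for stability.
* Parameter counting (`wheatformer.detector.count_parameters`) has a closed
  form that matches the instantiated models exactly, and includes the
  FPN/head by default.
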