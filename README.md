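# mammoscale

Multi-scale, patch-based whole-image classification for 2D mammograms.

Breast lesions span sizes from a few millimetres to several centimetres, so
any patch-based mammogram classifier is tied to the scale of its patches:
small patches resolve small calcifications but cannot contain a large mass,
large patches do the opposite. `mammoscale` implements the full pipeline for
studying and exploiting that trade-off:

* a **5-class patch classifier** (background, benign/malignant
  calcification, benign/malignant mass) over a convolutional feature
  extractor (DenseNet-121 in production; ResNet-34 and a `tinycnn` test
  backbone are included), trained with SGD, cosine-annealed learning rate,
  flip/rotation augmentation and inverse-frequency oversampling;
* its **whole-image extension**: drop the GAP/FC head, apply the extractor
  fully convolutionally to the entire mammogram (a H×W input yields a
  ⌊H/32⌋′×⌊W/32⌋′×1024 feature map), aggregate with a strided bottleneck
  residual block that preserves channels, and finish with GAP + a sigmoid
  cancer score;
* **multi-patch-size** (256/512/768 px), **multi-resolution**
  (100/150/200 μm) and **FPN** fusion classifiers that combine three
  branches by concatenating pooled feature vectors into an MLP;
* the **evaluation protocol**: lesions stratified into small / medium /
  large groups at 25.6 mm and 51.2 mm of maximal dimension; per-group
  normal-vs-abnormal and benign-vs-malignant AUCs on seeded balanced
  subsets; specificity/accuracy at the operating point with sensitivity
  fixed at 0.75; one-sided Welch t-tests across repeated training runs;
* **grad-CAM** explanations of the ground-truth class from the last
  convolutional layer;
* a **phantom generator** producing breast-shaped, textured synthetic
  images with controlled masses and calcification clusters, so the entire
  pipeline is testable end to end on a single CPU without clinical data.

Because no deep-learning framework is assumed, the package ships its own
compact reverse-mode autodiff engine on numpy (`mammoscale.nn`) with the
conv/pool/batch-norm/linear operators the models need; DenseNet-121 and
ResNet-34 are built on it layer for layer (6.95M and 21.3M extractor
parameters respectively).

## Worked example

```python
import numpy as np
from mammoscale import models
from mammoscale.phantom import PhantomConfig, generate_dataset
from mammoscale.patch_extraction import ExtractionConfig, build_patch_dataset

# shape and size contracts of the production backbone
print("DenseNet-121 feature map for a 512x512 patch:",
      models.feature_map_shape(512, 512, "densenet121"))
print("DenseNet-121 feature map for a 2850x2394 mammogram:",
      models.feature_map_shape(2850, 2394, "densenet121"))
print("extractor parameters (millions):",
      round(models.count_backbone_params("densenet121") / 1e6, 2))

# a small phantom dataset and its 5-class patch dataset
cfg = PhantomConfig(image_height_px=512, image_width_px=416, pixel_spacing_um=400.0)
mix = {"normal": 0.4, "benign_mass_small": 0.2, "malignant_mass_small": 0.2,
       "malignant_calc_large": 0.2}
manifest = generate_dataset(cfg, n_images=10, class_mix=mix, seed=7, out_dir="demo")
patches, histogram = build_patch_dataset(manifest, ExtractionConfig(patch_size_px=96, seed=7))
print("patch class histogram:", histogram)
```

prints

```
DenseNet-121 feature map for a 512x512 patch: (16, 16, 1024)
DenseNet-121 feature map for a 2850x2394 mammogram: (89, 74, 1024)
extractor parameters (millions): 6.95
patch class histogram: {'background': 101, 'benign_calc': 0, 'malignant_calc': 19, 'benign_mass': 4, 'malignant_mass': 2}
```

The feature map scales with the input (16×16 for a patch, 89×74 for a full
mammogram at the same reduction factor of 32), which is what lets a trained
patch classifier be reused as a whole-image feature extractor. Each of the
ten phantoms contributes exactly ten background patches (the extra
background-labelled entry is a grid tile that covers only a lesion-free
corner of a large lesion's bounding box); lesion patch counts vary because
the pairwise-IoU bound caps how many distinct patches a small lesion can
support.

A full desk-scale experiment — phantoms → patches → patch training →
whole-image training → fusion → evaluation table — runs from a YAML config:

```sh
mammoscale run --config experiment.yaml
```

(see `tests/test_cli.py::_demo_config` for a complete config example).

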