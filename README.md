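# glomseg

Glomeruli — the capillary tufts in the renal cortex that filter blood — are
the structures a nephropathologist examines first in a kidney biopsy, and
segmenting them automatically in whole-slide images (WSIs) is the entry point
to quantitative analysis of glomerular disease. `glomseg` implements an
end-to-end pipeline for this task around a **modified UNet**:

- an **RLE codec** for the run-length-encoded ground-truth masks that
  accompany WSI datasets (Kaggle dialect: 1-based, column-major
  `start length` pairs in a `id,encoding` CSV);
- **tiling** of arbitrarily large slides into 512×512 patches labeled by
  glomerulus presence, with train/test splitting (per tile or per slide);
- **class-balancing augmentation** of the minority glomerulus tiles
  (horizontal flip, horizontal shift, vertical shift applied jointly to
  image and mask), tripling the glomerulus class by default;
- the **modified UNet itself**, constructed programmatically with full
  architecture introspection, plus a training/evaluation harness and
  pixel-wise confusion-matrix metrics;
- a **synthetic-slide generator** producing PAS-like imagery with elliptical
  glomerulus-like structures and exact masks, so the whole pipeline runs and
  is tested with no external data or GPU.

The network engine (convolution, batch normalization, pooling, upsampling,
backpropagation, and the Adam/SGD/RMSprop/Adadelta optimizers) is a compact
numpy implementation included in the package.

## The model

The network is a five-block encoder–decoder with skip connections. Encoder
block $k$ ($k = 1..5$) is

$$\text{conv}_{3\times3}^{F_1(k)}(\text{linear}) \rightarrow \text{batchnorm} \rightarrow \text{conv}_{3\times3}^{F_2(k)}(\text{ReLU}) \rightarrow \text{maxpool}_{2\times2}$$

with the filter schedule $F_1(k) = 72 \cdot 2^{k-1}$, $F_2(k) = 144 \cdot
2^{k-1}$, so a 512×512 input contracts through feature maps of size
512 → 256 → 128 → 64 → 32 → 16, reaching a 16×16 bottleneck with 2304
channels. Each decoder block is

$$\text{upsample}_{2\times} \rightarrow \text{concat(skip)} \rightarrow \text{conv}_{3\times3}(\text{ReLU})$$

with widths halving per level (1152, 576, 288, 144); the topmost decoder
convolution maps to one channel through a sigmoid, emitting a per-pixel
glomerulus probability map at the input resolution. The layer inventory is
15 convolutional, 5 max-pooling, 5 upsampling, 5 normalization and
5 concatenate layers (the classic four-block UNet, available via
`NetworkSpec.baseline_unet()`, has 12/4/4/4/4).

Training minimizes per-pixel binary cross-entropy; evaluation derives
accuracy, precision, recall and F1 from the pixel-wise confusion matrix
(F1 of two binary masks is identically their Dice coefficient).

## Worked example

A desk-scale run of the whole pipeline — synthetic tiles, balancing
augmentation, training the 1/8-width network on 64×64 tiles, evaluation on
held-out tiles:

```python
import glomseg as g

tiles = g.generate_tileset(40, 40, tile_size=64, seed=7)
train_tiles, test_tiles = g.split_tiles(tiles, 0.75, seed=7)
glom = g.TileSet(t for t in train_tiles if t.label == g.GLOMERULUS)
background = g.TileSet(t for t in train_tiles if t.label != g.GLOMERULUS)
balanced, _ = g.balance_dataset(glom, g.AugmentConfig(seed=7))
balanced.extend(background)
print(f"train tiles after balancing: {len(balanced)}  held-out: {len(test_tiles)}")

net = g.build_modified_unet(g.NetworkSpec(width_scale=0.125, tile_size=64), seed=7)
history = g.train(net, balanced, test_tiles,
                  g.TrainConfig(optimizer="adam", batch_size=8, epochs=10, seed=7))
for r in (history.records[0], history.records[-1]):
    print(f"epoch {r.epoch:2d}: val loss {r.val_loss:.4f}, "
          f"val accuracy {r.val_accuracy:.2f}%")

total = g.PixelConfusion(0, 0, 0, 0)
for t in test_tiles:
    total = total + g.confusion(g.predict_mask(net, t.image), t.mask)
rep = g.metrics(total)
print(f"held-out pixels: accuracy {rep.accuracy:.1f}%, precision {rep.precision:.1f}%, "
      f"recall {rep.recall:.1f}%, F1 {rep.f1:.1f}%")
```

which prints (about half a minute on one CPU core):

```
train tiles after balancing: 114  held-out: 20
epoch  1: val loss 1.0260, val accuracy 90.03%
epoch 10: val loss 0.0048, val accuracy 99.81%
held-out pixels: accuracy 99.7%, precision 100.0%, recall 97.3%, F1 98.6%
```

Validation loss falls monotonically while pixel accuracy climbs, and the
trained network recovers the synthetic glomeruli almost perfectly — the
synthetic classes are deliberately separable, so this demonstrates that the
pipeline learns, not how it would score on real PAS-stained tissue.

The same pipeline is available from the shell:

```sh
glomseg inspect                      # layer inventory + feature trace (JSON)
glomseg simulate --n-glomeruli 8 --out sim/
glomseg tile --image sim/synth-000000.png --mask sim/synth-000000_mask.png \
             --tile-size 256 --out tiles/
glomseg train --config run.yaml --out run/
```

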