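# cdseg

Contrastive-distillation liver segmentation for 3D tomographic volumes,
implemented at desk scale: a frozen dense feature extractor, a dense
correspondence distillation loss with slice-position contrastive sampling, a
U-Net-style learnable upsampling decoder, a composite supervised objective,
and a 3D evaluation suite — everything exercisable end-to-end on synthetic
abdominal phantoms, with no downloads and no GPU.

## The problem and who this is for

Supervised liver segmentation models generalize poorly to scanners,
protocols and modalities unseen during training.  One remedy is to distill
the dense feature-similarity structure of a powerful frozen backbone into a
small student head under a contrastive scheme that exploits how volumes are
organized anatomically: a scan is a stack of axial slices along the
cranio-caudal z-axis, so **neighboring slices (`i−1`, `i+1`) are positives
and the slice half a scan away (`i + |I|/2`) is the negative** — no
intensity thresholds, no inter-volume alignment assumptions.  This package
is for researchers who want a fully inspectable, CPU-scale implementation of
that pipeline: every stage is a contract-tested module, and a synthetic
phantom generator stands in for clinical datasets.

## The model

For slices `x, y` and frozen extractor `F`, the dense correspondence tensor
is the cosine similarity between all feature-grid position pairs:

    X[h,w,i,j](F, x, y) = Σ_c F_chw(x)·F_cij(y) / (‖F_hw(x)‖ ‖F_ij(y)‖ + ε)

With spatial centering `S(X)[h,w,i,j] = X[h,w,i,j] − mean_{i'j'} X[h,w,i'j']`
and a trainable head `C` (two convolutions with a ReLU), the correspondence
loss and the three-term distillation loss are

    L_cr(x, y, b) = −mean_{hwij} ( S(X(F,x,y)) − b ) · max( X(C∘F, x, y), 0 )
    L_cd(x)       = L_cr(x, x, b_self) + L_cr(x, x⁺, b₊) + L_cr(x, x⁻, b₋)

The decoder upsamples the head features back to pixel resolution (five
upsample-then-convolution stages, skip connection to the raw slice, three
final convolutions) and the supervised objective adds Focal, Tversky,
log-IoU and entropy terms.  Metrics: volume DICE, ASSD and MSSD in
millimetres, paired t-tests.  See `docs/methods.md` for every formula,
default and design decision.

## Worked example

Generate a phantom cohort, train, infer and evaluate from the shell:

```bash
cdseg synth --n 10 --out data/ --seed 7
cdseg train --config examples/phantom.yaml --out run/
cdseg infer --checkpoint run/checkpoint.npz --config examples/phantom.yaml \
            --input-volume data/phantom_009.nii.gz --output-mask pred.nii.gz
cdseg evaluate --pred-dir preds/ --ref-dir refs/ --out-csv report.csv
```

or drive the reference study from Python:

```python
from cdseg.experiments import run_phantom_study

study = run_phantom_study(seed=7)       # 10 phantoms, 8 train / 2 held out
print(study.report.per_volume)
print(study.report.aggregate)
print(study.histogram_masses)
```

which prints (about 10 minutes on one CPU):

```
     volume_id      dice   assd_mm    mssd_mm
0  phantom_000  0.877016  4.108453  44.547727
1  phantom_008  0.848382  4.839114  49.681485
{'dice_mean': 0.8626990754372235, 'dice_sd': 0.02024772139273481,
 'assd_mm_mean': 4.473783733067764, 'assd_mm_sd': 0.5166551106775465,
 'mssd_mm_mean': 47.11460634989504, 'mssd_mm_sd': 3.6301152858911094}
[0.061767578125, 0.379180908203125, 0.0335693359375]
```

Reading the output: the held-out phantoms are segmented with mean volume
DICE ≈ 0.86 (fraction of overlapping voxels), the predicted surface sits on
average ≈ 4.5 mm from the true liver surface (ASSD; the maximum deviation
MSSD is dominated by small spurious islands — enable
`infer_volume(..., largest_component=True)` to suppress them), and the
self-correspondence histogram masses show the bi-modal signature of a
distilled head: the windows near alignment (1) and near orthogonality (0)
each carry more mass (0.062 and 0.379) than the mid-range window
0.4–0.6 (0.034).

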