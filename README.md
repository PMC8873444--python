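# ki67pi

Automated estimation of the Ki-67 proliferation index (PI) from
immunohistochemistry (IHC) images of breast carcinoma.

Pathologists grade tumor proliferation by counting the fraction of tumor
nuclei stained brown by the DAB chromogen (Ki-67 positive) among all tumor
nuclei (the rest carry only the blue hematoxylin counterstain):

```
PI = N_Ki-67(+) / (N_Ki-67(+) + N_Ki-67(−))
```

Manual counting is slow and visual ("eyeballing") estimation is poorly
reproducible. This package implements a pipeline that

1. **tiles** a region-of-interest image with a square sliding window
   (48/96/192 px presets, 16 px evaluation stride),
2. **classifies** each fragment as tumor-cell-bearing or irrelevant — with a
   trainable compact CNN (three conv-relu blocks, global average pooling,
   Adam on binary cross-entropy, majority-vote ensembling of three models)
   or a deterministic stained-fraction heuristic,
3. **defuzzifies** the overlapping predictions: each pixel's tumor-cluster
   membership degree is the fraction of covering windows predicted positive
   (up to (96/16)² = 36 windows per pixel), and pixels with membership
   > 0.5 form the binary ROI mask,
4. **segments** stained nuclei inside the ROI by HED color deconvolution and
   per-channel Otsu thresholding (optionally *biased* by reference
   thresholds averaged over training slides), cleans the masks by binary
   closing and dilation, and estimates

```
PI ≈ area(DAB mask) / area(DAB mask ∪ hematoxylin mask)
```

i.e. an area ratio instead of instance counting, which is robust to
touching nuclei. Restricting segmentation to the detected ROI keeps
out-of-cluster artifacts, stroma and isolated lymphocytes from biasing the
thresholds and the final score.

Because real annotated slide collections are not freely redistributable,
the package ships a synthetic IHC slide generator (`ki67pi.synthetic`) that
renders clustered tumor nuclei, lymphocytes and stain artifacts through the
inverse HED transform with exact ground truth (point annotations, ROI mask,
true PI), so every stage is testable end to end.

## Worked example

```python
from ki67pi import synthetic as syn, segmentation as seg, roi as roi_mod, fragments as fr
from ki67pi.classifier import heuristic_classify

slide = syn.generate_slide(syn.SynthesisConfig(seed=7, target_pi=0.25))
grid = fr.build_grid(slide.image.height, slide.image.width, window=96, stride=16)
pred = heuristic_classify(slide.image, grid)
mask = roi_mod.defuzzify(roi_mod.accumulate(pred))
est = seg.segment_and_estimate(slide.image, mask)
gt = slide.true_pi
print(f"true PI (count-based): {gt.pi:.4f}  ({gt.n_positive}/{gt.n_positive + gt.n_negative} nuclei)")
print(f"detected ROI area:     {mask.area} px")
print(f"estimated PI (area):   {est.pi:.4f}  (DAB {est.dab_area} px / relevant {est.relevant_area} px)")
```

prints

```
true PI (count-based): 0.2556  (23/90 nuclei)
detected ROI area:     18944 px
estimated PI (area):   0.2618  (DAB 1735 px / relevant 6626 px)
```

The generated slide carries 90 annotated tumor nuclei of which 23 were
drawn DAB-positive (count-based PI 0.2556); the pipeline detects the tumor
clusters, segments 6626 px of relevant nuclear area of which 1735 px are
DAB-stained, and lands within 0.007 of the truth.

The same flow is available from the shell:

```sh
$ ki67pi pipeline --out demo --n 5 --seed 17
wrote 5 slides to demo/data
estimated 5 slides -> demo/estimates_roi.json
MAE 0.0287 (95% CI 0.0153-0.0413), RMSE 0.0323, invalid 0/5
```

`ki67pi --help` lists the individual stages (`synth`, `partition`, `train`,
`predict-roi`, `estimate`, `evaluate`), which exchange plain PNG / CSV /
JSON artifacts. `estimate --method base|roi|roi_bias` selects whole-image
segmentation, ROI-restricted segmentation, or ROI plus threshold biasing.

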