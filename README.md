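# interfish

Quantitative analysis of oncogene amplification in **interphase FISH**
microscopy. Focal amplifications come in two cytogenetic forms with very
different clinical behaviour: **ecDNA** (extrachromosomal DNA — many small,
randomly segregating particles, visible as dozens of tiny FISH puncta per
nucleus) and **HSR** (homogeneously staining region — intrachromosomal, visible
as a few large contiguous FISH blobs). Metaphase spreads make the distinction
easy but are laborious to acquire; interphase nuclei are abundant but diffuse.
`interfish` provides the deterministic building blocks for making this call on
interphase images: spot detection, nucleus instance splitting, quality gates,
classification scaffolding with sample-level aggregation, and a
maximum-likelihood estimator of fluorescent-tag accuracy in mixed populations.
A seeded synthetic-image generator with planted ground truth makes every stage
testable end to end.

Intended users: computational biologists and image-analysis engineers working
with multi-channel FISH data (DAPI + target probe, optionally a centromeric
control probe and an RFP/mCherry cell-line tag).

## What it computes

**Matched-filter foci detection.** An isolated hybridization spot is modelled
as an isotropic 2-D Gaussian of width σ on a locally constant background,
`I(x, y) = c·exp(−((x−x₀)² + (y−y₀)²)/2σ²) + d`. For each pixel, the flattened
n×n neighbourhood **v** is projected onto the orthonormal basis of
span{**g**, **1**} (Gram–Schmidt: **g**⊥ = normalized(**g** − mean(**g**)·**1**)).
The coefficient c = **v**·**g**⊥ measures spot-shaped local contrast and is
exactly zero on constant regions. Pixels with c ≥ c_min and raw brightness
≥ b_min form candidate foci; 8-connected components of ≥ s_min pixels are
reported with centroid and area. The per-nucleus **copy number signal** is the
percentage of nucleus area covered by foci.

**Min-cut instance splitting.** Touching nuclei inflate foci counts. Deep
local maxima (> 10 px) of the L1 distance transform mark nucleus centers;
oversized connected components (> 1.25 × median area) containing two or more
centers are split along the minimum edge cut of their 4-connectivity pixel
graph, provided the cut is at most 60 edges. Pixels are re-assigned, never
discarded.

**Quality gates.** Image level: the 50-bin intensity histogram of the target
channel must keep a dominant background peak (Q = h₁/h₂ ≥ 0.2); the
centromeric branch requires Pearson kurtosis ≤ 3 of per-nucleus mean
centromeric intensity. Nucleus level: mean rescaled target signal ≥ 0.05, and
maximum raw centromeric intensity ≥ 10 for the centromeric branch.

**Classification and aggregation.** A mean/variance heuristic on image-level
copy-number statistics (HSR-like iff mean < 10 and variance < 64), a trainable
patch classifier harness (cross-entropy, Adam, patience-7 early stopping,
balanced stratified sampling), a focal/no-focal gate combiner, bootstrapped
10-cell majority votes (100 iterations), fixed sample-call thresholds
(no-amp ≥ 80%, HSR-amp ≥ 80%, EC-amp ≥ 50%, else heterogeneous), and a Pearson
chi-square heterogeneity comparison.

**Tagging-accuracy MLE.** In a 1:1 mix of an RFP-tagged ecDNA line with an
untagged HSR line, the number x of truly EC-amplified nuclei that escaped
tagging maximizes

```
L(x) = Σ_{ah=0}^{x} C(x, ah) · C(Nh−x, ch−ah) · ph^ah · pe^(x−ah) · qh^(ch−ah) · qe^(ce+ah−x)
```

over 0 ≤ x ≤ Nh, where Nh/Ne are untagged/tagged counts, (ch, ce) the untagged
prediction counts, and (ph, pe)/(qh, qe) the classifier's prediction
probabilities on pure EC/HSR lines. Evaluation is in log space with log-gamma
binomials; tagging accuracy is 1 − x̂/(Ne + x̂), and a df = 3 chi-square over
the four (tag status × prediction) categories checks the fit.

## Worked example

```bash
python examples/tagging_accuracy.py
```

```
MLE untagged true-EC nuclei x_hat = 28
untagged fraction = 6.14%
tagging accuracy  = 93.86%
```

Of 765 nuclei, 428 carried the RFP tag; among the 337 untagged nuclei the
classifier called 309 HSR-amp and 28 EC-amp. Because the pure-EC line is
misclassified as HSR 26.4% of the time while the pure-HSR line is called EC
only 2.4% of the time, the 28 untagged EC calls are best explained by x̂ = 28
truly ecDNA-amplified nuclei that escaped tagging — i.e. 6.14% of true EC
nuclei were untagged, a tagging accuracy of 93.86%.

The other scripts in `examples/` each demonstrate one capability (foci
detection on a synthetic ecDNA nucleus, min-cut splitting of touching nuclei,
quality gates, sample classification, distortion robustness) and print the
numbers they compute with a short interpretation.

There is also a thin CLI:

```bash
interfish simulate --seed 1 --n-nuclei 10 --out scratch/demo
interfish statfish --image scratch/demo/image.tiff --mask scratch/demo/mask.tiff \
    --channel-map scratch/demo/channel_map.json --out scratch/demo/foci.csv
interfish tagging-mle --counts counts.json --out fit.json
```

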