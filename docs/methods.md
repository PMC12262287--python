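# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `interfish`. Everything stated here is computed by the
test suite or the example scripts; nothing is quoted from external runs.

## Image model and preprocessing

Images are 8-bit multi-channel grids (rows × cols × channels) with named
channels from {dapi, target, centromere, rfp}; grids are 0-based and
row-major, bounding boxes half-open. Nucleus segmentation is consumed, not
produced: any instance label mask of matching extent works (a naive
Otsu-threshold baseline is included, clearly labelled as a stand-in, for
running the pipeline without an external segmenter).

Each nucleus is cropped to its bounding box and resized bilinearly to a
256×256 patch; label masks are resized nearest-neighbour so instance
membership stays crisp. Boxes larger than 256×256 are tiled with
non-overlapping stride-256 windows, the final window anchored to the box edge
so the whole box is covered — the stride is our convention; only the use of a
sliding window is prescribed. Per-window predictions are merged into one
nucleus call by mean posterior, another convention we expose explicitly
(`merge_window_predictions`). Nuclei touching the image border are flagged
`boundary` rather than dropped: only the tagging analysis excludes them,
because a clipped nucleus has an unreliable maximum intensity.

Rescaling: DAPI is divided by its own patch maximum; target and centromere by
their **shared** maximum (preserving their relative brightness, which the
centromeric branch depends on); the RFP channel keeps its raw 0–255 scale
because the tag threshold is defined there. All-zero channels are left at
zero and flagged instead of dividing by zero.

The distortion protocol is fixed: shrink to 0.8×, enlarge to 1.2×, rotate
45°, contrast ±40%. Contrast is linear scaling about the 8-bit midpoint,
`v′ = 127.5 + (1 ± 0.4)(v − 127.5)` with clipping — the operator itself was a
free choice; midpoint scaling is the common definition and makes magnitude 0
the identity. Rotation resamples bilinearly with edge replication, so constant
images are exactly invariant.

## Spot detection

The detector assumes an isolated spot is an isotropic Gaussian of width σ on
a locally constant background. With g(i,j) = exp(−((i−c)² + (j−c)²)/2σ²) on
an n×n window and g⊥ its unit-norm Gram–Schmidt residual against the constant
vector, the response c = v·g⊥ at a pixel is the spot-contrast coefficient of
the local neighbourhood and vanishes identically on constant regions. The
response is computed as a same-size zero-padded correlation; pixels within
⌊n/2⌋ of the border are excluded from candidacy because zero padding makes
their projection partial (this reconciles "valid" and "zero-padding"
readings on all interior pixels). Candidates must clear both the projection
threshold c_min and the raw-brightness threshold b_min; 8-connected candidate
components of at least s_min pixels become foci. 4-connectivity is reserved
for the min-cut pixel graph, where it is prescribed; the connectivity of the
focus components was unspecified and we chose 8.

Defaults (exposed, on the raw 0–255 scale): σ = 1.5 px, window n = 9 (the
smallest odd integer ≥ 6σ), c_min = 15, b_min = 50, s_min = 2 px. σ matches
the puncta width of typical 63× FISH spots at our patch scale; b_min ≈ 20% of
full scale suppresses background texture; s_min = 2 removes single-pixel
noise. c_min can instead be calibrated as 3× the response SD over
background-only patches (`calibrate_c_min`); with unit-norm g⊥ the response
SD on i.i.d. noise equals the pixel noise SD, so the default corresponds to
~5-unit background noise. When a channel has been rescaled to [0, 1], the
thresholds are interpreted on that same scale.

Degenerate inputs: an empty nucleus mask is an error; a σ so large that g is
numerically constant over the window raises a degenerate-kernel error
(residual norm < 1e-9); b_min above the intensity range simply yields zero
foci.

## Instance splitting

Foreground components are 4-connected, matching the pixel graph. The L1
(Manhattan) distance transform treats the image border as background — nuclei
clipped there are boundary-flagged anyway. Centers are plateau-tolerant
8-neighbourhood local maxima with distance value strictly greater than 10 px;
a plateau collapses to its lexicographically smallest pixel. Because the L1
metric produces clusters of near-equal maxima inside a single convex nucleus,
maxima within the same 10 px radius of a deeper (or, on ties,
lexicographically earlier) maximum are suppressed; without this, two fused
disks present four centers and would be over-split.

A component qualifies for splitting only if its area exceeds 1.25× the median
component area **and** it contains at least two centers. The cut terminals
are not the center pixels themselves: with unit edge capacities, the four
edges around any single pixel always isolate it, so single-pixel terminals
would cap every cut at 4 and make the 60-edge flow limit meaningless.
Instead, each center's *core* — the connected region of pixels deeper than
10 px containing it — is contracted to a supernode, and the minimum edge cut
between the two cores is computed by max-flow (networkx). Centers sharing one
core cannot be isolated and are skipped. If the cut has at most 60 edges, the
cut edges are removed and the two sides relabelled; components with more than
two centers are split recursively, pairs tried in decreasing-depth order. The
flow limit is read as a cap on cut size (the alternative reading, an
iteration bound, has no natural unit here). Foreground pixels are conserved
exactly — cuts remove adjacencies, not pixels.

On components up to ~2,000 px the reported cut equals an independent sparse
max-flow computation (scipy) in the test suite, exercising max-flow/min-cut
duality across two code bases.

## Quality gates

The target-channel quality score bins intensities into 50 equal-width buckets
on [0, 256) (so 255 falls in the last bin); a peak is a bin exceeding both
neighbours, end bins compare to their single neighbour, and a plateau bounded
by strictly smaller bins counts once at its left edge. Q = h₁/h₂ with h₁ the
highest peak among bins 0–24 and h₂ among bins 25–49; Q < 0.2 marks the image
low quality (Q = 0.2 passes, reading the cut literally). Heavily bled images
— most pixels bright — are the intended failure mode: the background peak
shrinks relative to the signal peak. If either side has no peak, Q is
undefined and the image fails with a recorded reason.

The centromeric image gate uses **Pearson** kurtosis (m₄/m₂², population
moments), chosen because the cut-off of exactly 3 is the normal reference
under this definition — a large simulated normal sample sits at 3.0 in the
tests. Kurtosis > 3 (or undefined, zero variance) disables the centromeric
branch and the pipeline falls back to target-only calls. Per-nucleus gates:
mean rescaled target signal ≥ 0.05 (boundary inclusive — "below 0.05" is
excluded), and maximum raw centromeric intensity ≥ 10.

## Classification and aggregation

The heuristic image call is HSR-like iff mean < 10 **and** variance < 64 of
the per-nucleus copy number signal (strict inequalities), with an exhaustive
grid search utility returning the accuracy-maximizing cut-offs (ties to the
smallest pair). The trainable classifier is a compact feed-forward softmax
network over block-pooled patch features, sized by the dense-block
configuration (hidden width = block × growth factor); it exists to prove the
training loop — cross-entropy, Adam, patience-7 early stopping on validation
loss (three-class) or AUC (binary), per-epoch balanced sampling at equal
total weight per stratum, seeded determinism — at toy scale. Reproducing any
full-scale DenseNet accuracy table is out of scope, and externally supplied
weights can be injected via the config.

Bootstrap aggregation draws 10 cells uniformly **with replacement** (the
draw's replacement policy was unspecified) and takes the modal label, ties
broken uniformly at random within the iteration's RNG stream; 100 iterations
yield the win-fraction distribution. On 70/30 two-class input the win
fraction matches the closed-form binomial value P(Bin(10, 0.7) ≥ 6) +
½P(= 5) ≈ 0.901. Sample calls apply the thresholds in the order no-amp ≥ 0.80
→ HSR-amp ≥ 0.80 → EC-amp ≥ 0.50 → heterogeneous, the stricter gates first.
The heterogeneity chi-square drops classes with zero counts in both samples
before computing df = k − 1.

## Tagging MLE

The likelihood, its log-space evaluation (log-gamma binomials, logsumexp,
invalid combinatorial terms contributing zero), the uniform prior and the
integer argmax are as stated in the README. Numerical conventions: 0·log 0 = 0;
a zero probability with a positive exponent annihilates the term; log-space
agrees with direct-space evaluation to 1e-9 relative for Nh ≤ 30, and the
likelihood sums to exactly 1 over all (ch, ce) outcomes on small populations
(exhaustive check). Argmax ties — which occur exactly when the pure-line
prediction profiles coincide (ph = qh), collapsing the sum by Vandermonde's
identity — resolve to the smallest x; values within 1e-9 in log space are
treated as tied so that analytically flat likelihoods tie despite float
rounding. The tag call itself is strict ("exceeds 10"), while the centromeric
QC gate excludes strictly below 10; both boundaries are deliberate and
documented in the config.

The chi-square fit check builds expected counts from x̂ (tagged nuclei all
true EC; untagged nuclei x̂ true EC + Nh − x̂ true HSR) and uses df = 3 over
the four categories. Because x̂ is fitted from the same counts, this check is
*conservative* under the model: simulated experiments give p-values
stochastically larger than uniform (no over-rejection at any level), which is
what the calibration test asserts. It is a goodness-of-fit gate, not a
calibrated test.

`simulate_tagging_experiment` generates count-level experiments for
parameter-recovery studies; the default study condition in the acceptance
suite is 500 nuclei split 250/250 between true EC and true HSR (mirroring a
1:1 line mix), 15 untagged true-EC nuclei, and the pure-line probabilities of
the worked example. Recovery bias across 100 seeds is below 3 nuclei.

## Synthetic data: what it emulates and what it does not

The generator plants elliptical DAPI nuclei with smooth texture; EC-amp
nuclei carry Poisson(30) Gaussian puncta (amplitude 200, σ = 1.5 px, pairwise
separation ≥ 4σ + 1 by rejection sampling), HSR-amp nuclei 1–2 contiguous
bright regions grown to 5–15% of nucleus area each, no-amp nuclei 2–4 puncta;
the centromeric channel gets 2 puncta per nucleus; the RFP channel fills
tagged nuclei (EC nuclei are tagged Bernoulli(0.95), matching a line sorted
to ~95% marker positivity). Additive Gaussian noise (SD 4 by default) and the
distortion protocol provide degradation. Field images place nuclei without
contact unless an overlap fraction is requested, in which case overlapping
placements create fused foreground for the instance splitter; mask labels map
1:1 to ground-truth records, overlap pixels belonging to the later nucleus.
Identical seeds give bit-identical images.

Not emulated: optics (no PSF, no chromatic shift), tissue-section texture and
autofluorescence, out-of-focus nuclei, probe bleed-through between channels,
and realistic absolute copy-number scales. In particular, with the stated
blob geometry a synthetic HSR *field's* image-level mean signal often exceeds
10%, so the absolute mean < 10 / variance < 64 separation reported for real
images does not transfer to synthetic fields; the heuristic and the grid
search are therefore validated on constructed statistics with known answers,
and detector correctness is validated by planted-truth recovery (≥ 95% of
clean EC nuclei recovered exactly, centroids within 1 px). Passing tests
demonstrate algorithmic correctness on the generator's geometry, not
field-readiness on any particular microscope's data.

## Problem sizes

Test and acceptance runs use deliberately small problem sizes — 256×256
patches, fields of ≤ 200 nuclei, two-lobe masks of ≤ 2,000 px for the
duality checks, 100-seed recovery studies, toy 32×32 patches for the training
harness — chosen so the full suite completes in minutes on one CPU while
still exercising every code path at the fidelity the oracles require.
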