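# tumorpipe

A small, fully seeded pipeline for detecting a hyperintense lesion in 2-D
8-bit grayscale images (axial MRI-slice stand-ins), built from four classic
ingredients:

1. **Contrast-limited adaptive histogram equalization (CLAHE).**  The image
   is divided into tiles; each tile's histogram is clipped at a per-bin
   ceiling, the clipped mass redistributed, and an equalization look-up
   table `f_i = round((n-1) · Σ_{k≤i} q_k / Q)` built from the result.
   Output pixels bilinearly blend the tables of the nearest tile centers.
   Clipping bounds the transfer-function slope and hence local noise
   amplification; entropy diagnostics (`E = -Σ p_i log2 p_i`) quantify how
   close the output histogram is to the 8-bit maximum of 8 bits.
2. **Otsu threshold selection.**  The segmentation threshold `t` maximizes
   the between-class variance `σ_b²(t) = ω₀ω₁(μ₀-μ₁)²`, equivalently
   minimizes the within-class variance, since `σ² = σ_ω²(t) + σ_b²(t)` at
   every split.  The pipeline iterates the split on the foreground until the
   candidate region is plausibly lesion-sized, then keeps the largest
   8-connected component.
3. **Region features.**  Each candidate is summarized by 8 normalized
   shape/position/intensity features (area, perimeter, circularity
   `4πA/P²`, eccentricity, centroid fractions, mean and s.d. of intensity).
4. **A max–min LVQ classifier with quantized weights.**  Per-class codebook
   vectors on `[0,1]^d` are matched with the fuzzy similarity
   `S(x,w) = Σ min(x_i,w_i) / Σ max(x_i,w_i)` (1 exactly at equality) and
   trained with LVQ1.  Codebook weights can be quantized to β bits with a
   uniform mid-rise quantizer; the signal-to-quantization-noise ratio obeys
   `10·log10(ε_w²/ε_{n_w}²) ≈ κ·β` with κ ≈ 6 dB/bit, which the package
   estimates empirically rather than assumes.

Because no public dataset accompanies this problem setting, the package
ships a seeded phantom generator (elliptical "brain" with low-contrast
tissue, smooth bias field, Gaussian noise, optional hyperintense tumor with
a ground-truth mask) so every stage — and the whole pipeline — is testable
without any download.

Intended audience: image-analysis practitioners who want a transparent,
dependency-light reference implementation of the CLAHE → Otsu → LVQ chain
with honest, reproducible validation, not a clinical tool.

## Worked example (CLI)

```bash
tumorpipe simulate --out cohort_train --n 100 --seed 11
tumorpipe features --cohort cohort_train --out features.csv
tumorpipe train    --features features.csv --out codebook.json
tumorpipe simulate --out cohort_test --n 50 --seed 12
tumorpipe pipeline --cohort cohort_test --codebook codebook.json --out predictions.csv
tumorpipe evaluate --predictions predictions.csv --cohort cohort_test --out report.json
```

`report.json` from exactly this run:

```json
{
  "accuracy": 0.96,
  "precision": 0.9259259259259259,
  "specificity": 0.92,
  "dice": 1.0
}
```

Reading: of 50 test phantoms (25 with tumors), 48 were labeled correctly;
2 tumor-free images produced a lesion-like bright region the classifier
mistook for a tumor (precision 0.93, specificity 0.92); every true tumor
that was detected was segmented essentially perfectly (mean Dice overlap
1.0 against the ground-truth masks).  Per-image labels, max–min
similarities and Dice scores are in `predictions.csv`:

```
name,label,similarity,dice
img_0000.png,tumor,0.9269470170637868,1.0
img_0001.png,tumor,0.8194475581599273,1.0
```

The same steps are available as library calls (`tumorpipe.synthetic`,
`tumorpipe.pipeline`); see `docs/methods.md` for the model details and
design choices.

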