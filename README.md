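# rhythm4c

Analysis toolkit for rhythmic chromatin contacts and circadian readouts:

- **`rhythm4c.synthgen`** — synthetic data with known ground truth:
  negative-binomial 4C-seq contact profiles with power-law decay around a
  bait and an optional rhythmic Gaussian "loop", smRNA-FISH nucleus
  populations (4-component diameter mixture, binomial allele bursting,
  optional rendered image stacks), and square-wave locomotor actograms.
- **`rhythm4c.fourc_prep`** — in-silico restriction digestion (DpnII by
  default), fragment scoring (mean of the two fragment-end counts),
  sample QC (fail at ≥75% empty fragments within ±1 Mb of the bait),
  bait masking (bait + 5 fragments per side) and cis-chromosome
  library-size normalization.
- **`rhythm4c.lwmr`** — the core statistic: locally weighted multilinear
  regression of `log10(c/500 + 1)` scores in a Gaussian window
  (σ_G = 2500 bp) with fragment effects `a_i` and condition effects
  `b_j`, weights `W_ij = w_g,i · w_s,j` (`w_s = n_nonzero_replicates +
  0.5`), regularized residual variance
  `σ̃² = σ̂² + σ_min²·exp(−b̄/log10 2)`, t-based differential-contact
  tests and a χ²(2) weighted harmonic-regression rhythm test.
- **`rhythm4c.track_rhythm`** — 500-bp binning, 7-bin running average,
  per-bin 24-h cosinor, and HSV phase colouring (hue = peak phase with
  blue at ZT0, saturation 1, value = min of Hill(amplitude; k=1, n=5)
  and Hill(−log10 p; k=4.5, n=5)).
- **`rhythm4c.smfish_burst`** — Laplacian spot detection on the maximum
  projection, 3×3-mask site intensities on the sum of the 9
  best-focused slices, watershed nucleus segmentation, 4-component
  Gaussian-mixture ploidy assignment (posterior > 0.7, broad component
  discarded as outliers), pooled burst fractions and genotype LRTs.
- **`rhythm4c.circadian_stats`** — Sokolove–Bushell χ² periodogram on
  5-min activity bins, group period comparison, per-gene expression
  phases with circular phase differences, sign/binomial phase-advance
  test and a replicate bootstrap for per-gene phase shifts.

## CLI

```sh
rhythm4c simulate 4c --config cfg.yaml --out sim/ --seed 1
rhythm4c prep --counts sim/fourc --bait chrS:200000 --out prep/
rhythm4c lwmr --counts prep/normalized --bait chrS:200000 \
    --contrast ZT20:ZT8 --rhythm --out profile.tsv
rhythm4c trackrhythm --bedgraphs t0.bg,t4.bg,... --times 0,4,8,12,16,20 --out bins.tsv
rhythm4c simulate fish --config fish.yaml --out fish/ --seed 1
rhythm4c fish --nuclei fish/nuclei.tsv --out burst/
rhythm4c simulate actogram --out act/ --seed 1
rhythm4c period --trace act/actogram.tsv
rhythm4c phases --expr tpm.tsv --meta meta.tsv --out phases.tsv
```

## Notes on conventions

- Genomic coordinates are 0-based half-open everywhere.
- Phase is the time of the fitted cosine maximum, hours in [0, 24),
  with ZT0 = lights-on; circular phase differences live in (−12, 12]
  and "advance" means a negative difference.
- The rhythm amplitude is the cosine amplitude |F| (peak-to-trough is
  2|F|).
- Standard errors of the local fits use the loess-style sandwich
  `σ̃²·B(XᵀW²X)B` (kernel weights are smoothing weights, not inverse
  variances); `σ_min` defaults to the square root of the 10th
  percentile of residual variances among above-median-signal fragments,
  recomputed per bait — the exact quantile is a tuning parameter.
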