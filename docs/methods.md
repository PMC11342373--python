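# Methods note

This note records what the package computes and why the non-obvious
choices were made. Units: concentrations in ng/kg, retention times in
minutes, areas in arbitrary counts.

## Panel and batch design

The default panel covers 20 PFAS analytes (C4–C14 carboxylates, four
sulfonates, one sulfonamide and three ether-PFAS), each monitored on a
quantifier and a qualifier MRM transition. PFPeA fragments to a single
abundant product ion; its second channel is a *pseudo transition*
(precursor monitored at low collision energy), confirmable but flagged.
PFOS is quantified on its *less* sensitive transition (499>99) because
the sensitive 499>80 channel is shared with taurodeoxycholic acid, a
co-eluting bile acid; the sensitive channel serves as qualifier.

Twelve isotopically labeled internal standards are spiked at 5 ng/kg
before preparation. Eight analytes without a matching isotopologue
(PFTrDA, PFTeDA, PFHpS, PFDS, PFOSA, DONA, 9Cl-PF3ONS, 11Cl-PF3OUdS)
borrow a structurally closest surrogate; this is the main mechanism by
which an analyte can fail validation, because a surrogate does not
perfectly cancel recovery and matrix effects. Two injection standards
added after cleanup separate preparation losses (absolute recovery) from
ionization effects (matrix effect).

One validation batch = 2 procedural blanks + 12 matrix-fortified
calibrants (0, 0.5, 1, 2.5, 5, 10, 25, 50, 100, 500, 1000, 2000 ng/kg) +
6 produce matrices, each unspiked and spiked at 2.5, 50 and 500 ng/kg:
38 samples, ~54 traces each. A campaign is five such batches, one per
produce category — 30 spiked samples per analyte and level.

## Synthetic data model

The generator is the ground truth the pipeline is tested against. A
quantifier area is

```
area = amount × slope × recovery(category) × matrix_effect(category)
       × bias × common × channel_noise
```

where `amount` includes the spike, any procedural-blank background and
endogenous levels. Noise is structured deliberately:

- **`common`** is one unit-mean lognormal factor per *sample* applied to
  every channel (injection volume, source drift). It cancels exactly in
  the analyte/IS response ratio — as it does on a real instrument.
- **`channel_noise`** is an independent unit-mean lognormal on analyte
  transitions only, with coefficient of variation `noise_cv`. Because
  the common mode cancels, the injected `noise_cv` is what the estimated
  RSD_RL should track; modeling both channels with independent noise
  would inflate the response-ratio CV by √2 and break that invariant.
- Unit-mean lognormals use σ² = ln(1+cv²), μ = −σ²/2, so averages of
  noisy areas converge to the noise-free value.
- Retention-time jitter is drawn once per *co-elution group* (an analyte
  and its labeled isotopologue share the draw), reflecting that an
  isotopologue co-elutes with its analyte; surrogate-IS pairs jitter
  independently, which is exactly why their RRT check is less robust.
- **`bias`** models calibration transfer error for surrogate-IS analytes.
  It is applied to test samples but *not* to MFS calibrants: a bias
  present identically in calibrants and samples would cancel through the
  matrix-fortified calibration and be unobservable.

Chromatograms are Gaussians (σ = 0.05 min, 5 ms sampling) on white
baseline noise; the synthesis refuses undersampled configurations.

## Peak integration

Apex search on a 5-point moving average; Gaussian σ estimated from the
full width at half maximum; integration of the *raw* trace above a
linear baseline between the bounds. Bounds are apex ± 4σ, not the more
conventional ± 3σ: ± 3σ covers only 99.73% of a Gaussian and the
baseline chord subtracts part of what remains, clipping ~3% of the area
— incompatible with a 1% accuracy requirement. S/N is apex height over
the standard deviation of the median-detrended window edges (15% each
side); a peak below 3 × noise is reported *not found* rather than as a
zero-area peak. Note that end-to-end accuracy is far better than
single-peak accuracy: analyte and IS are integrated identically, so
residual integration error cancels in the response ratio (observed
≲ 1e-9 relative on noise-free batches).

## Calibration and quantitation

Blank-corrected response ratios are regressed on fortification level
with **1/x weighting**; the 0 ng/kg calibrant enters with unit weight
(1/x is undefined there) and anchors the intercept. Unweighted least
squares over a 0.5–2000 ng/kg range would be dominated by the top
levels and bias the low end, which is where LOQs live.

Two overlapping segments, 0–100 and 50–2000 ng/kg, are fitted; a
provisional full-range fit picks the segment per sample (≤ 100 ng/kg →
low). The overlap guarantees every concentration is bracketed; results
above 2000 ng/kg are quantified on the high segment and flagged as
extrapolation. Negative blank-corrected responses and negative
concentrations are *retained* and flagged — clipping at zero would bias
validation statistics upward at the lowest levels.

Confirmation references (ion ratio, RRT) are the means over MFS
calibrants whose qualifier channel reached S/N ≥ 3; low calibrants with
an unmeasurable qualifier would otherwise corrupt the reference.

## Limits

- No substantial blank (blank ≤ 30% of the lowest non-zero level): LOQ =
  lowest calibration level with quantifier S/N ≥ 6.
- Substantial blank: LOQ = 3.3 × blank-equivalent concentration (mean
  blank response / low-segment slope), snapped *up* to the calibration
  grid, so reported LOQs are always demonstrable concentrations.
- LOC = lowest calibration level whose identity confirmation succeeds,
  floored at the LOQ.
- The determined LOQ can additionally be cross-checked against the
  spiked validation data and raised when the level just above it fails
  the performance criteria.
- Per-sample blank-contribution check: pass iff blank ≤ 30% of the
  sample level (inclusive).

## Validation conventions

Apparent recovery of a spiked sample = (calculated − baseline) / spike ×
100. The baseline is the unspiked result of the *same matrix* when that
result itself exceeds the category LOQ; otherwise zero — the
procedural-blank contribution has already been removed in response
space, and subtracting a sub-LOQ unspiked value would inject pure noise.

Spike levels *below* an analyte's category LOQ are excluded from its
evaluation (a 2.5 ng/kg addition on top of a 5 ng/kg blank background is
not quantifiable by definition); validation tables simply omit those
rows. RSD_r is computed per category (n = 6 matrices, so it mixes
matrices and overestimates same-matrix repeatability — deliberately, as
a breadth probe), RSD_RL pools all 30 samples per level. Classification:
**quan** iff every evaluated level has mean recovery in [65, 135]% and
RSD_RL ≤ 25% (boundaries inclusive); else **qual**. IS stability is
probed with a one-way ANOVA across compounds' signal RSDs.

## Occurrence

Detection requires a concentration strictly above the LOQ; at-LOQ values
report absence. A sample counts once per category regardless of how many
analytes confirm. Exposure sums over the EFSA-4 substitute 0 (lower
bound) or the LOQ (upper bound) for non-detects.

## Limitations

- The generator produces idealized Gaussian peaks; tailing, saturation
  and carryover are out of scope, as are vendor raw files (the CSV trace
  schema is the interchange format; mzML import would be an extra).
- Matrix effects and recoveries are per category, not per matrix;
  between-matrix variability within a category enters only through
  noise.
- The segmented calibration refits from the same calibrant pool; no
  fresh curve per day is modeled.
- Validation p-values (ANOVA) assume approximate normality of the RSD
  groups; with n = 8 per group this is adequate for screening, not for
  confirmatory inference.

## Problem sizes and runtimes (one CPU)

| Task | Size | Time |
|---|---|---|
| One batch, peak-table route | 38 × 54 channels | < 0.1 s |
| One batch, trace route | ~2000 traces, 201 pts each | ~0.5 s |
| Five-category campaign, CV 10% | 5 × 38 samples | ~2 s |
| Full test suite | unit + property + acceptance | < 1 min |
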