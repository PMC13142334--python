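# Methods

This note documents the models behind `musclekit`, the conventions chosen
where the underlying measurement procedures leave latitude, and what the
synthetic-data generators do and do not emulate.

## Contractile trace model

A single twitch is modelled as a difference of exponentials,

    f(t) = A · (e^(−t/τ_d) − e^(−t/τ_r)) / g_max,   t ≥ 0,

normalised so the maximum equals the active force A (mN). The peak occurs
at t* = (τ_r τ_d / (τ_d − τ_r)) · ln(τ_d/τ_r). This two-time-constant
shape is the standard phenomenological description of a muscle twitch and
is analytically tractable: the generator records per-event ground truth
(active force, time to peak, RT80%), with the RT80% reference obtained by
Brent root-finding on the kernel to ~1e−12 s (the difference of
exponentials has no closed-form relaxation time).

Tetani are linear superpositions of kernels at the pulse times of each
train, optionally passed through a soft saturation
F ↦ F_max (1 − e^(−F/F_max)) so the force–frequency curve rises
monotonically to a plateau, as fused tetanic contraction does. Noise is
additive i.i.d. Gaussian in force units. The generator emits *deflection*
(force divided by a linear post stiffness, default 1 mN/mm) because the
instrument's flux-to-deflection step is proprietary; the analysis pipeline
converts back with the same linear spring model. The post stiffness is a
free parameter throughout — no calibration value is published for the
measurement platform.

Defaults mirror the study conditions: twitch protocol 10 pulses at 0.2 Hz
(5 s apart); force–frequency protocol 2 s trains at 1, 2, 3, 5, 10, 15,
20, 30, 40, 60, 80, 100 Hz with 16 s rest; 100 Hz sampling; 5 ms / 100 mA
pulse metadata. Twitch parameters default to A = 1.2 mN, τ_r = 30 ms,
τ_d = 150 ms, passive baseline 0.5 mN — amplitudes and kinetics of the
order reported for iPSC-derived engineered muscle tissues. A 2 s lead-in
precedes the first stimulus so baseline estimation has a quiet window.

What the generator does **not** emulate: magnet/electrode physics, calcium
dynamics, force drift, fatigue, pacing-capture failures, or physiological
noise structure (the noise is white). Passing tests therefore demonstrate
correctness of the analysis contracts on idealised traces, not robustness
to instrument artefacts.

## Contractility analysis conventions

- **Baseline.** The standalone estimator returns the 10th percentile of
  the 2 s pre-stimulus window — deliberately conservative for records
  with residual activity or drift. Inside event/train analysis the
  per-event baseline defaults to the *median* of the same window: equally
  robust to spikes, but unbiased under symmetric noise (a low percentile
  is biased low by ≈1.28 σ, which at 2 % noise would consume most of a
  3 % amplitude-accuracy budget).
- **Peak detection.** One candidate window per stimulus [tᵢ, tᵢ₊₁). The
  peak is located on a 5-sample moving-median smoothed trace and refined
  within ±2 samples on a Savitzky–Golay (window 7, order 2) fit; the
  amplitude is the Savitzky–Golay value at the refined peak. Rationale:
  the moving median flattens a 100 Hz-sampled twitch crest by ~1 %, and
  the raw maximum carries a +1 σ order-statistic bias; the local quadratic
  fit preserves the crest to ~0.1 % while averaging noise. Measured
  performance at the default kinetics: noise-free amplitude recovery
  +0.14 %; at 2 % noise, bias +0.15 % and worst-case error < 1 % over 60
  seeds.
- **Acceptance threshold.** An event is kept when its prominence exceeds
  max(3 × robust noise SD, configurable floor), with the noise SD
  estimated as 1.4826 × MAD of the residual around the moving-median
  smooth. Zero accepted events is a result, not an error.
- **RT80%.** Time from the reference point (twitch peak, or end of
  stimulation for tetani) until force first falls to
  baseline + 0.2 × active force, linearly interpolated between the
  bracketing samples; never reaching the threshold before the record (or
  the next train) ends yields a censored result. "Relaxed by 80 % of the
  active amplitude" is the standard physiology reading of an "80 %
  relaxation time". Both anchors are computed and labelled since either
  convention appears in practice.
- **Tetanic plateau.** Mean force over the last 50 % of each train
  (configurable), excluding the fusion rise.

## Image scenes and morphometry

Cross-section scenes render non-overlapping filled ellipses (myotube
profiles) into a myosin channel, the same plus a diffuse smoothed random
field into an actin channel, and nuclei as small disks; culture scenes
render disk-stamped tubes (straight segments or circular arcs) of
analytically known centerline length, with nuclei placed on the
centerline (assigned) or in the background. Ground truth records exact
rasterised pixel areas, analytic arc lengths, and the full
nucleus-to-object assignment; with zero noise every rendered image is a
deterministic function of the seed. The default pixel size is 0.65 µm/px,
a typical 20× widefield scale. The scenes do not emulate out-of-focus
light, uneven illumination, marker bleed-through, or touching/overlapping
cells beyond deliberately placed tangent objects.

Analysis conventions:

- **Background subtraction**: a large-kernel median estimate (default
  radius 50 px) computed on a downsampled grid and resampled back (the
  full-resolution median would be needlessly slow at these kernel sizes),
  clipped at zero. The kernel radius must exceed the objects of interest,
  as with any rolling-background filter.
- **Segmentation**: Otsu threshold on the (lightly Gaussian-smoothed)
  fusion image → hole filling → watershed on the distance transform with
  h-maxima markers computed per connected component (h = 30 % of the
  component's maximal distance). The per-component h keeps elongated
  single objects intact (their distance ridge is nearly flat) while
  splitting objects joined by a narrow neck. Objects below 50 µm²
  (configurable) are dropped. This classical pipeline replaces a
  learned instance segmenter with the same output contract; the
  substitution is recorded in the result metadata.
- **Effective CSA** is the exact sum of member pixel areas (mm²);
  "mean myotube diameter" is the equivalent-circle diameter by default
  (minor-axis variant by flag), since no operational definition is
  published.
- **Lengths**: per connected object, the longest geodesic path through
  the 8-connected skeleton graph (two Dijkstra passes), measured along a
  polyline through every 4th path pixel — summing unit/√2 pixel steps
  would overestimate oblique smooth curves by up to ~8 %. For tubes with
  rounded caps the medial axis already spans the centerline, so no end
  correction is applied by default; an opt-in tip compensation (adding
  the local half-width at each path end) handles blunt-ended objects.
  This formalises a tip-to-tip freehand measurement along the cell's
  curvature.
- **Widths**: twice the mean distance-transform value over the skeleton
  (mean local tube width); minor-axis variant by flag. The measurement
  protocol behind reported myotube widths is not described, so this is a
  declared convention.
- **Conversion efficiency** divides desmin⁺ nuclei by *all* nuclei (the
  assay contrasts induced cultures against uninduced fibroblast
  populations, implying a per-cell fraction); the area-fraction variant
  is emitted alongside for screen-style readouts, where both
  positive-area and integrated-intensity conventions are reported.
- **Fusion index**: nuclei inside desmin⁺ objects containing ≥ 2 nuclei,
  over all nuclei — by construction never exceeding conversion
  efficiency on the same denominator.
- **Channel alignment**: integer-shift phase cross-correlation
  (translation only); synthetic fixtures are generated aligned, so this
  is minimal drift correction, not a general registration solution.

## Expression simulation and panel scores

Per-gene log2 expression is gene baseline + group shift (panel genes
only) + i.i.d. Gaussian noise; the emitted matrix is linear-scale. The
generator warns when fewer than 3 samples are requested because
across-sample z-scores are degenerate there. It does not model counts,
library size, mean–variance coupling or gene–gene correlation, so tests
certify the scoring contracts, not performance on real RNA-seq.

The panel score is the mean across-sample z of log2 expression over panel
members present (zero-variance members dropped with a warning; missing
members reported). This is the simplest reproducible module score; a
mean-log variant is available by flag. Score–marker association uses
Pearson correlation (rank variant by flag) with Benjamini–Hochberg
adjustment across markers. The inflammation panel ships as an editable,
explicitly non-authoritative default; the barrier panel membership is
fixed by the reported gene list.

## Promoter windows and motif enrichment

Coordinates are 0-based half-open. For a + strand gene the window is
[TSS−2000, TSS+200); for a − strand gene [TSS−200, TSS+2000), reverse
complemented, so the returned sequence always reads −2000…+200 in the
gene's direction (2200 bp for interior genes; contig-edge truncation is
flagged). Motifs are consensus strings (default CACCC and GGAA), counted
exactly on both strands with overlaps allowed and palindromes counted
once — position weight matrices are out of scope since only consensus
elements are analysed. Enrichment is presence/absence per promoter with a
one-sided hypergeometric test of foreground hits drawn from the pooled
foreground+background universe, plus a per-kb occurrence-rate ratio; the
background promoter set is user-supplied, as no canonical background is
defined for this analysis.

## Group statistics

The t statistic (pooled and Welch) and the balanced two-way ANOVA are
implemented from the textbook formulas — the ANOVA sums of squares
satisfy SS_total = SS_A + SS_B + SS_AB + SS_error to machine precision on
balanced designs, which the tests assert, and both are cross-checked
against scipy/statsmodels. Unbalanced designs and empty cells are
rejected by name rather than silently reweighted. Tukey HSD compares all
cell means with studentized-range quantiles at the residual degrees of
freedom, covering the within-genotype treated-vs-control contrasts of a
condition × genotype design. Fold-change reporting rounds ratios to one
decimal to mirror "1.6-fold"-style summaries while retaining full
precision, and scales deltas into requested units (e.g. ms).

## Numerical and degenerate-input choices

- Trace sample count is exactly duration × sampling rate (integer
  contract, validated).
- Noise-free generators are bit-for-bit reproducible under a fixed seed.
- Constant images: Otsu is undefined, so segmentation returns a
  zero-object result and the positive-fraction readout returns 0.
- Zero residual variance in ANOVA flags the result degenerate instead of
  dividing by zero; identical t-test groups return (0, 1).
- p-values are clamped into (0, 1].
- Hypergeometric p-values are monotone decreasing in the foreground hit
  count at fixed margins (property-tested).

## Problem sizes used in tests and the acceptance script

Simulation-based checks use sizes chosen to exercise the estimators well
inside their operating range while keeping the suite quick on one CPU:
512²–640² px scenes with 5–8 objects, 52 s twitch records, 200-replicate
recovery simulations, and a 2000-replicate null calibration of the
panel-score group test (16 samples, 60 genes per replicate). The
acceptance script reuses the published group means as inputs for the
fold-change worked examples and a single freshly simulated twitch trace
(5200 samples) for event detection.

## Known limitations

- The linear deflection→force model ignores any nonlinearity of the real
  post; stiffness must be supplied by the user.
- Watershed splitting relies on a distance-ridge prominence heuristic;
  heavily overlapping myotube profiles would require a learned segmenter.
- Skeleton-based lengths degrade on branched objects (the longest branch
  is reported) and on objects thinner than ~3 px.
- The panel score treats genes as exchangeable; no gene weighting or
  correlation structure is modelled.
- Motif enrichment ignores sequence composition bias between foreground
  and background; users should match backgrounds for GC content where
  that matters.
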