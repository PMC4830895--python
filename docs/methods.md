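# Methods

## Scope and data model

The package analyses four assay types from hepatocyte (HepG2 / primary
hepatocyte) stress-response studies: GFP-p65 nuclear-translocation movies
(nuclei + reporter channels, 6-min cadence over 6 h), Srxn1-GFP induction
movies (30-min cadence over 24 h), Annexin-V death movies (death +
transmission channels, 30-min cadence over 24 h), and per-(gene, treatment)
differential-expression tables with gene-set catalogs. Times are minutes
after TNFα (or drug) addition; images are 16-bit counts; fold changes are
log2.

All stages consume and emit plain formats: multi-page TIFF (frame-major,
channel-interleaved, JSON metadata in the image description), TSV tables,
GMT gene sets, JSON feature/truth/manifest files and YAML configs.

## Synthetic data generator

The generator exists so that every analysis stage can be validated against
exact ground truth; its defaults are fixed once and describe the control
condition of the assays it emulates.

**Ratio traces.** r(t) = 1 + Σ_k A·d^k·g((t − t₁ − kΔ − ε_k)/w) + η(t),
where g is a unit-FWHM Gaussian bump (so `peak_width_min` *is* the FWHM),
t₁ = 30 min, Δ = 120 min, A = 1, d = 0.7, w = 40 min,
ε_k ~ N(0, k·6 min) (the first translocation is synchronous, later ones
progressively desynchronise) and η is white noise with sd 0.05 — roughly a
5 % relative error on an O(1) ratio, typical of single-cell ratio
measurements. A treatment delay parameter shifts all peaks after the first;
per-cell jitter draws are re-sampled in the (practically never hit) event
of non-monotone peak times. The ground truth records each cell's exact
bump centres.

**Rendering.** Cells sit on a jittered grid with a hard minimum spacing, so
rendered nuclei never touch (touching-cell handling is exercised by
dedicated fixtures instead). The cytoplasmic ring is held at a fixed level
(400 counts over a 100-count background) and the nuclear reporter level is
scaled, so the background-corrected disk/ring intensity ratio equals the
trace value exactly; shot noise is Poisson on the expected counts.
Requesting more cells than fit raises an error rather than clipping.

**Srxn1-GFP.** Per-cell GFP follows plateau·σ((t − onset_i)/τ) with
onset_i ~ N(480 min, 60 min) and τ = plateau/(4·rate), i.e. `rate` is the
mid-rise slope in counts/min (defaults: plateau 1000, rate 2 → τ = 125
min). Fast- versus delayed-inducer conditions are modelled by moving the
onset; no drug-specific kinetic constants are assumed.

**Death.** Death times come from a piecewise-exponential hazard: h₀ =
0.002 h⁻¹ baseline, multiplied by 5 from the 480-min TNFα addition when
the co-exposure arm is simulated. These values are calibrated so the
defaults reproduce a strongly sensitised condition (~4.5 % death alone,
~14 % with TNFα at 24 h). Death is irreversible and the Annexin blob
persists, so positive area is cumulative by construction.

**Expression tables.** Genes carry planted labels (30 Nrf2-target, 40
NF-κB-target, 200 background). Mean log2FC: +3.5 for the matching model
treatment (oxidative model → Nrf2 block, inflammatory model → NF-κB
block), +2.5 / −2.5 for the severe-hepatotoxicant treatment on the Nrf2 /
NF-κB blocks, scaled by 0.35 for the mild treatment, 0 elsewhere; i.i.d.
N(0, 0.3) noise. Adjusted p-values are a deterministic monotone function
of |log2FC|/noise (two-sided normal tail) with mild lognormal jitter —
the package consumes differential-expression fits, it does not refit
replicate-level models, so simulating the fit's output distribution
directly is the honest level of detail. Average expression is N(8, 0.5)
for planted blocks and N(6, 1.5) for background.

What the generator does **not** model: photobleaching, stage drift, cell
division, segmentation-confounding cell contact, heavy-tailed noise, and
correlated gene–gene noise. Passing tests therefore demonstrate
correctness of the measurement and statistics code under the stated
generative assumptions, not robustness to every real-microscopy artifact.

## Image quantification

**Nuclei.** Global Otsu threshold (fixed override available for
reproducibility on known fixtures), distance-transform watershed seeded at
local maxima ≥ 8 px apart to split touching nuclei, components < 50 px
removed, labels relabelled sequentially. Blank/constant frames yield zero
labels, not errors.

**Cytoplasm.** Nearest-nucleus label expansion by the ring width minus the
nuclei themselves — a partition, so neighbouring rings are disjoint by
construction. Ring width 0 produces an empty cytoplasm and a missing
(NaN) ratio downstream.

**Background.** Per-frame median of pixels outside all nuclei dilated by
15 px (enough to exclude cytoplasm rings at default geometry).

**Tracking.** Greedy nearest-centroid linking in ascending distance order
with a 10-px gate and no gap closing (HepG2 nuclei move ~µm-scale between
6-min frames; a missed detection conservatively ends the track). Tracks
covering < 80 % of frames are excluded from oscillation statistics.

**Ratio.** Per frame, (mean nuclear reporter − background)/(mean ring
reporter − background); non-positive denominators mark the frame missing.

**Srxn1 score.** 8-connected components of pixels strictly above a
detection threshold; components < 45 px discarded; score = qualifying
pixel count × mean (image − background) over qualifying pixels / nucleus
count. The density baseline (`background`) and the detection threshold are
deliberately separate: on shot-noisy frames the pipeline thresholds at
median + 5·√median (a ~5σ Poisson bound that keeps false-positive pixels
to O(10⁻⁷) per pixel) while measuring density relative to the median, so
the score stays linear in true signal and fold induction is unbiased.
"Average density" is the pooled mean over all qualifying pixels; a
per-blob-mean variant sits behind a flag. Fold induction is evaluated at
the 24-h endpoint by default (endpoint, maximum and AUC readings differ
only in which time point is passed).

**Death curves.** Percent positive = 100 × (death-channel pixels above the
same 5σ threshold)/(cell area), capped at 100; cell area comes from a
local-variance texture threshold on the transmission image (5-px window,
Otsu on the local sd, erosion by half the window to undo border smearing).
AUC is the trapezoidal integral of percent over hours. Synergy is the
plain difference of percent-dead with and without TNFα, in percentage
points.

## Oscillation features

Traces are min–max normalised per cell (constant traces flagged
degenerate; interior NaNs linearly interpolated). Detection: 3-frame
moving-average smoothing, strict local maxima (plateaus resolve to their
earliest sample), exact topographic prominence ≥ 0.1, then greedy
suppression to a ≥ 30-min separation with higher peaks winning and ties
going to the earlier peak. These three defaults are not dictated by any
measurement standard; they are chosen so the canonical 30/150-min control
pattern is detected at the generator's default noise, and the brute-force
oracle test pins the selection rule exactly. Peak times are refined by a
parabola through the maximum and its neighbours (offset clamped to ±½
sample), motivated by published per-drug delays that are not multiples of
the 6-min frame interval.

Per-cell features: peak count; per-peak width at half prominence (the
"period" of an individual translocation); successive inter-peak delays,
the first being the peak 1 → 2 delay; nuclear entry/exit rates as the
extremal positive/negative first differences per minute within one peak
period of each peak, averaged over peaks. Entry/exit rates have no
published formula; this extremal-slope reading is one admissible
definition and is documented as such. Population level: 0–5+ peak-count
histogram (≥ 5 capped), fraction of cells with ≥ 3 translocations, and
the treated-minus-control difference of mean second-peak times over cells
with ≥ 2 peaks (an averaged-population-trace variant is available behind
a flag; the two agree on synthetic data to within a frame).

## Gene-set statistics

Catalog union keeps per-gene source tags. The responsiveness filter keeps
a gene iff at least one model-compound treatment satisfies adj-p ≤ 0.05,
average log2 expression ≥ 5 and |log2FC| ≥ 1.5 (oxidative) or 2.0
(inflammatory); all comparisons are inclusive, reading "minimum"/
"maximum" literally. DEG selection for enrichment uses |log2FC| ≥ 1.3,
adj-p ≤ 0.05, expression ≥ 7. Enrichment is the hypergeometric upper tail
P(X ≥ k); the universe defaults to all genes in the table (the original
analysis ran inside a proprietary tool whose universe is unstated), and
BH q-values are reported alongside raw −log10 p, which remains the
headline display. Arrow vectors are (mean |log2FC|, sign of mean signed
log2FC) over the contributing genes. Clustering applies Ward linkage to
Manhattan-distance matrices for both genes and treatments — faithful to
the published choice despite Ward's Euclidean derivation; a Euclidean
option exists. Missing fold changes are imputed as 0 for clustering only.
A threshold-sweep utility reports survivor counts across |log2FC| cutoffs
for matching gene-set sizes between categories.

## Numerical and design notes

- Determinism: every stochastic stage derives its generator from the
  config seed via `SeedSequence`; identical configs give byte-identical
  TIFF/TSV outputs, verified by manifest hashes.
- Problem sizes: validation uses 300-cell trace populations for timing
  statistics (sampling error ≈ 0.4 min on mean peak times, comfortably
  inside the one-frame tolerance), 9–25 cell rendered movies for
  segmentation round-trips, and 270-gene expression tables; these sizes
  make the statistical checks decisive while keeping the suite quick.
- Degenerate inputs are contracts, not crashes: constant traces, blank
  frames, empty tables, zero ring widths and zero-hazard arms all have
  defined outputs.
- Known limitations: no gap-closing tracker (transient missed detections
  truncate tracks); the Otsu threshold assumes bimodal nuclei histograms;
  the death readout measures labelled *area*, a proxy for the dead-cell
  fraction that saturates for large blobs; enrichment treats genes as
  exchangeable (no expression-level bias correction).
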