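# toxsignal

Quantitative analysis of the interplay between the Nrf2 oxidative-stress
response and TNFα/NF-κB inflammatory signalling in hepatocyte models of
drug-induced liver injury (DILI). The package implements, as a tested and
reusable pipeline, the four measurement arms such a study rests on:

1. **NF-κB translocation dynamics** — single-cell GFP-p65 nuclear/cytoplasmic
   intensity-ratio traces from time-lapse movies (nuclei segmentation,
   greedy tracking, ring-based cytoplasm assignment), min–max normalisation,
   prominence-based peak detection with sub-frame quadratic refinement, and
   population summaries: peak-count histograms (0–5+ classes), the
   peak 1 → peak 2 delay, and the treated-minus-control shift of the second
   translocation maximum.
2. **Nrf2 reporter induction** — the Srxn1-GFP score: adjacent fluorescent
   pixels above background in components of ≥ 45 px, times their mean
   above-background density, normalised to the nucleus count; and fold
   induction at the 24-h endpoint.
3. **Cytotoxic synergy** — Annexin-V percent-positive death curves
   (positive pixel area over transmission-derived cell area), their AUC in
   %·hours, and the TNFα synergy statistic
   `Δ = %dead(drug + TNFα) − %dead(drug)`.
4. **Stress-gene-set transcriptomics** — gene-set union with source tags,
   responsiveness filtering (adjusted p ≤ 0.05, average log2 expression ≥ 5,
   |log2FC| ≥ 1.5 oxidative / 2.0 inflammatory within model-compound
   treatments), Ward clustering on Manhattan distances, and right-tailed
   Fisher-exact (hypergeometric upper-tail) pathway enrichment reported as
   −log10 p with mean fold-change arrow vectors.

Because the original microscopy and transcriptomics inputs are not
distributable, a first-class synthetic-data module generates every input
with known ground truth: damped, progressively desynchronised ratio-trace
oscillations rendered into 16-bit TIFF stacks, sigmoidal Srxn1-GFP
accumulation, piecewise-exponential death hazards with a TNFα hazard
switch at 8 h, and differential-expression tables with planted
Nrf2-up / NF-κB-down gene blocks.

## Model sketch

A control cell's ratio trace is

    r(t) = 1 + Σ_k A·d^k · g((t − t₁ − k·Δ − ε_k)/w) + noise,

with Gaussian bump `g` of unit FWHM, first peak t₁ = 30 min, inter-peak
interval Δ = 120 min (so maxima at 30, 150, 270 min on a 6-min cadence over
6 h), damping d, and timing jitter ε_k ~ N(0, k·σ) that desynchronises later
peaks. A perturbing drug adds a constant delay to every peak after the
first; recovering that delay from the detected second-peak times is the
pipeline's central readout. Cell death follows hazard h₀ that switches to
m·h₀ when TNFα is added, so the 24-h dead fraction is
`1 − exp(−h₀·t_a − m·h₀·(T − t_a))`.

## Worked example

```python
from toxsignal import SimConfig
from toxsignal.oscillation import (detect_peaks, extract_features, normalize_trace,
                                   peak_count_histogram, population_delay_shift)
from toxsignal.synthetic import simulate_ratio_traces

control, _ = simulate_ratio_traces(SimConfig(seed=1, n_cells=300))
cfg = SimConfig(seed=2, n_cells=300)
cfg.oscillation.treatment_delay_min = 26.0       # drug-like perturbation
treated, _ = simulate_ratio_traces(cfg)

feats = []
for tr in control:
    nt = normalize_trace(tr)
    feats.append(extract_features(nt, detect_peaks(nt)))
s = peak_count_histogram(feats)
print("control peak-count histogram (0..5+):", list(s.histogram))
print(f"mean peak1->peak2 delay: {s.mean_delay_p1_p2_min:.1f} min")
print(f"mean second-peak time:   {s.mean_second_peak_min:.1f} min")
print(f"shift: {population_delay_shift(treated, control):.1f} min")
```

prints

```
control peak-count histogram (0..5+): [0, 0, 0, 299, 1, 0]
mean peak1->peak2 delay: 119.9 min
mean second-peak time:   149.9 min
shift: 26.1 min
```

i.e. almost every control cell shows the canonical three translocations in
6 h, the second maximum sits at ~150 min, and the planted 26-min delay is
recovered to within a tenth of the 6-min frame interval.

The same stages run from the shell: `toxsignal simulate` writes TIFF
stacks / DE tables with ground-truth JSON and a hash manifest,
`toxsignal analyze` produces feature JSON, population TSVs and figures,
and `toxsignal report` combines conditions into one summary table.

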