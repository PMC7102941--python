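# trnafret

Quantitative image analysis for **tRNA-FRET translation imaging** in
neuron/glia culture — for microscopists who label two tRNA populations
with a FRET donor/acceptor pair (Cy3/Cy5) so that energy transfer reports
ribosomes with adjacent A/P-site tRNAs, i.e. active mRNA translation, and
who complement this with widefield puncta analysis, single-molecule
localization microscopy (SMLM) and live-cell particle tracking.

The package bundles, as tested and reusable building blocks:

* **Corrected FRET (cFRET).** Crosstalk coefficients are estimated from
  single-label controls as the origin-constrained slope of raw-FRET
  vs. donor (bleed-through *a*) or acceptor (cross-excitation *b*)
  intensity; the Youvan correction `Fc = F_raw − a·I_donor − b·I_acceptor`
  is applied pixelwise, and per-punctum

  `cFRET(%) = Youvan / ((I_Cy3 + I_Cy5)/2) × 100`

  is summarized per cell compartment (soma / dendrite / glia), both as the
  mean over puncta and as summed corrected intensity per unit area.
* **Puncta analysis.** Top-hat detection with a robust relative threshold,
  signal-unit quantization (multiples of the smallest detectable punctum),
  binary-mask co-localization, log-normal size summaries (median,
  geometric SD), a 3000 nm² small/large classifier, and geodesic
  distance-from-soma profiles.
* **SMLM.** ThunderSTORM-style localization tables, histogram/Gaussian
  rendering, per-localization Voronoi density, clustered/diffuse
  partitioning at a configurable density threshold, the 2-/3-color
  fractional-overlap (Jaccard) formulas, ROI transfer onto thresholded
  channels, and bead-based localization precision (σ, FWHM = 2√(2 ln 2)·σ).
* **Tracking.** Deterministic greedy nearest-neighbor linking,
  mean-instantaneous-velocity statistics per compartment, kymographs along
  arbitrary paths, anterograde/retrograde/bidirectional classification,
  and the Rayleigh noise-floor bound σ_loc·√π/Δt on measured speeds.
* **Statistics.** Shapiro–Wilk/F/Bartlett gating that dispatches to
  t-test, Mann–Whitney, ANOVA+Tukey/Dunnett, Welch ANOVA or
  Kruskal–Wallis+Dunn; ROUT-style robust outlier flagging at FDR Q = 1%;
  two-way ANOVA for grouped designs.
* **Synthetic data.** Every analysis has a paired generator with full
  ground truth (geometry, crosstalk, density modes, planted overlap,
  velocities, puncta sizes, a puromycin-dissociation perturbation), so the
  whole pipeline is validated by parameter recovery.

## Worked example

```python
from trnafret import fretcalc, puncta
from trnafret.synthdata import (SimConfig, FretSimConfig,
                                make_neuron_geometry, simulate_fret_channels)

cfg = SimConfig(seed=1, photon_scale=2.0)          # shot noise on
masks = make_neuron_geometry(cfg)
truth = FretSimConfig(a_donor_bleed=0.25, b_acceptor_cross=0.10,
                      fret_fraction=0.30, n_puncta=50, min_separation_px=8)
sample, donor_only, acceptor_only, gt = simulate_fret_channels(masks, truth, cfg)

coeffs = fretcalc.estimate_correction_coefficient(donor_only, "donor-only").merged(
    fretcalc.estimate_correction_coefficient(acceptor_only, "acceptor-only"))
det = puncta.detect_puncta(sample.donor, background_radius=8, min_area=3)
res = fretcalc.cfret_by_compartment(sample, coeffs, masks, det)
for comp, d in res.per_compartment.items():
    print(comp, round(d["cfret_mean_percent"], 1))
```

prints

```
soma 30.3
dendrite 29.8
```

i.e. with a planted FRET fraction of 0.30 the calibrated, corrected
analysis reads back ≈ 30 % in both compartments — crosstalk alone would
have read ≈ 35 % before correction.  The scripts in `examples/` walk
through each capability the same way (SMLM density/overlap, transport
velocities, puromycin dissociation, statistical dispatch) and print what
the numbers mean.

End-to-end scenarios chaining simulation → analysis → statistics are
available as `trnafret.run_experiment({"scenario": "velocity", ...})`
(scenarios: `velocity`, `puromycin_puncta`, `smlm_overlap`,
`fret_development`, `clp_timecourse`).

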