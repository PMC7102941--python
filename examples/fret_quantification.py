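"""Calibrate FRET crosstalk from single-label controls and quantify cFRET.

Simulates a neuron with Cy3/Cy5-labeled tRNA puncta at a known FRET
fraction of 0.3, estimates the bleed-through (a) and cross-excitation (b)
coefficients from the donor-only / acceptor-only control stacks, applies
the Youvan correction and prints the per-compartment calculated-FRET
percentage.  With a planted fraction f, the corrected analysis should read
back cFRET close to 100*f.
"""

from trnafret import fretcalc, puncta
from trnafret.synthdata import (FretSimConfig, SimConfig,
                                make_neuron_geometry, simulate_fret_channels)

cfg = SimConfig(seed=1, photon_scale=2.0)   # shot noise on
masks = make_neuron_geometry(cfg)
truth = FretSimConfig(a_donor_bleed=0.25, b_acceptor_cross=0.10,
                      fret_fraction=0.30, n_puncta=50, min_separation_px=8)
sample, donor_only, acceptor_only, gt = simulate_fret_channels(masks, truth, cfg)

ca = fretcalc.estimate_correction_coefficient(donor_only, "donor-only")
cb = fretcalc.estimate_correction_coefficient(acceptor_only, "acceptor-only")
coeffs = ca.merged(cb)
print(f"planted a={gt.a_donor_bleed:.3f}  estimated a={coeffs.a_donor_bleed:.3f}")
print(f"planted b={gt.b_acceptor_cross:.3f}  estimated b={coeffs.b_acceptor_cross:.3f}")

detected = puncta.detect_puncta(sample.donor, background_radius=8, min_area=3,
                                pixel_size_nm=cfg.pixel_size_nm)
result = fretcalc.cfret_by_compartment(sample, coeffs, masks, detected)
for comp, d in result.per_compartment.items():
    print(f"{comp:9s} cFRET = {d['cfret_mean_percent']:5.1f}% "
          f"({d['n_puncta']} puncta)")
print("soma/dendrite ratio:", round(result.soma_dendrite_ratio, 2))
# cFRET near 30% in every compartment confirms the crosstalk correction:
# the planted FRET fraction was 0.30 and crosstalk alone would read ~35%.
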