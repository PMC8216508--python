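"""Entropy / non-triviality of the spatial ΔF/F pattern during release.

Simulates a bouton with one dominant release site, computes the
ordinal-pattern entropy H(t) and non-triviality C(t) of each ΔF/F frame
over the dilated bouton region, and prints the baseline-to-peak amplitudes.
Release concentrates signal near the site: the field becomes less random
(H falls) and more anisotropic (C rises).
"""

import numpy as np

from boutonquant.iglu_transients import compute_dff
from boutonquant.pattern_stats import entropy, nontriviality, pattern_timecourse
from boutonquant.synthetic_data import BoutonSimConfig, simulate_bouton_movie

# reference limits
rng = np.random.default_rng(0)
noise = rng.normal(size=(256, 256))
ramp = np.arange(64 * 64, dtype=float).reshape(64, 64)
print(f"i.i.d. noise:  H = {entropy(noise):.3f}  C = {nontriviality(noise):.4f}")
print(f"monotone ramp: H = {entropy(ramp):.3f}  C = {nontriviality(ramp):.4f}")

cfg = BoutonSimConfig(n_release_sites=1, site_release_prob=1.0,
                      glut_peak_conc=600.0, seed=7)
movie, _ = simulate_bouton_movie(cfg)
ps = pattern_timecourse(compute_dff(movie))

print(f"\nbaseline H = {ps.baseline_H:.3f}, at peak H = {ps.H[ps.peak_frame]:.3f}"
      f"  -> entropy amplitude {ps.entropy_amplitude:+.3f}")
print(f"baseline C = {ps.baseline_C:.4f}, at peak C = {ps.C[ps.peak_frame]:.4f}"
      f"  -> non-triviality amplitude {ps.nontriviality_amplitude:+.4f}")
print("\nPositive amplitudes mean the evoked pattern is less homogeneous and "
      "more oriented than the resting noise — the single-site signature.")
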