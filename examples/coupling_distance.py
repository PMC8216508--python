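"""Measure Cav2.1–Munc13-1 coupling distances on a simulated STED field.

Builds one three-channel field of synapse triads (40-nm Lorentzian PSF,
20-nm pixels, Poisson + read noise, distractor spots), runs the full
pipeline — Richardson–Lucy deconvolution, prominence-gated maxima,
Homer-gated triad detection, line-profile peak-to-peak distances — and
prints the per-synapse distances next to the generating truth.
"""

import numpy as np

from boutonquant.sted_coupling import aggregate_distances, measure_field
from boutonquant.synthetic_data import StedSimConfig, simulate_sted_field

cfg = StedSimConfig(field_size=(256, 256), n_triads=10, n_distractors=8,
                    separation_distribution=("truncnorm", 64.6, 35.0),
                    seed=21)
field, truths = simulate_sted_field(cfg)
field.condition = "ctrl"

df = measure_field(field, prominence=100.0)
print(f"recovered {len(df)} synapses from {cfg.n_triads} generated triads")
print("measured (nm):", np.sort(df["distance_nm"]).round(0).tolist())
print("true     (nm):", np.sort([t.separation_nm for t in truths]).round(0).tolist())

out = aggregate_distances(df, compare=False)
row = out.summary.iloc[0]
print(f"\nmean +/- SEM: {row['mean_nm']:.1f} +/- {row['sem_nm']:.1f} nm "
      f"(n = {row['n_synapses']})")
print("20-nm histogram counts:", out.histograms["ctrl"].tolist())
print("\nEach distance is the peak-to-peak separation of the calcium-channel "
      "and release-site cluster maxima along a 1-pixel line profile; ~65 nm "
      "is the loose-coupling regime of mossy fiber boutons.")
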