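"""Normality-gated comparison of two measurement groups.

Draws two per-bouton measurement samples (one with a shift), runs the
selection rule (normality screen → t / Welch / Mann–Whitney), and prints
the full report including per-animal means.
"""

import numpy as np

from boutonquant.group_stats import compare_groups, per_animal_summary

rng = np.random.default_rng(0)
ctrl = rng.normal(636.0, 110.0, 22)   # e.g. vesicle dispersion, nm/um^3
fsk = rng.normal(836.0, 120.0, 20)

c = compare_groups(ctrl, fsk)
print(f"test selected: {c.test_used}")
print(f"ctrl {c.mean_a:.1f} +/- {c.sem_a:.1f} (n={c.n_a})   "
      f"treated {c.mean_b:.1f} +/- {c.sem_b:.1f} (n={c.n_b})")
print(f"statistic = {c.statistic:.3f}, p = {c.p_value:.2e}  -> {c.stars}")

animals = np.repeat([f"m{i}" for i in range(4)], 6)[:22]
pa = per_animal_summary(ctrl, animals)
print(f"\nper-animal means: "
      f"{ {k: round(v, 1) for k, v in pa['animal_means'].items()} }")
print(f"animal-level mean +/- SEM: {pa['mean']:.1f} +/- {pa['sem']:.1f}  "
      f"(pooled SEM {pa['pooled_sem']:.1f})")
print("\nThe screen routes normal data to t tests (Welch under unequal "
      "variance) and everything else to Mann–Whitney; stars follow "
      "0.05/0.01/0.001/0.0001.")
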